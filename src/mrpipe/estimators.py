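"""Causal-effect estimators on a harmonized instrument set.

All estimators combine per-SNP Wald ratios r_j = βY_j / βX_j.  For a binary
outcome the result is a log odds ratio per SD of exposure; the exponentiated
OR and its 95 % interval are carried on every estimate.

* IVW — weighted regression of βY on βX through the origin with weights
  1/seY² (the NOME first-order weights).  The multiplicative random-effects
  model inflates the fixed-effect SE by max(1, sqrt(Q/(J−1))): over-dispersion
  widens the interval, under-dispersion is never allowed to shrink it.
* MR-Egger — same regression with a free intercept after orienting every
  instrument to βX > 0.  The slope is the pleiotropy-adjusted effect (valid
  under InSiDE), the intercept the average directional pleiotropy; both are
  tested on t with J−2 df, with the same multiplicative SE floor.
* Weighted median — the 0.5 point of the weight-CDF over sorted ratios with
  weights (βX/seY)²; consistent when valid instruments hold a majority of the
  weight.  Its SE comes from a seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .instruments import HarmonizedInstrument, InstrumentSet

__all__ = [
    "MREstimate",
    "EggerResult",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
]


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal-effect estimate with normal/t inference."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_ci_low: float
    or_ci_high: float
    n_snp: int


def _finish(method: str, beta: float, se: float, n_snp: int,
            df: int | None = None) -> MREstimate:
    """Attach CI / p / OR transform; normal inference unless ``df`` given."""
    if df is None:
        crit = stats.norm.ppf(0.975)
        pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    else:
        crit = stats.t.ppf(0.975, df)
        pval = 2.0 * stats.t.sf(abs(beta) / se, df) if se > 0 else (1.0 if beta == 0 else 0.0)
    pval = float(min(max(pval, np.nextafter(0, 1)), 1.0))
    lo, hi = beta - crit * se, beta + crit * se
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        pval=pval,
        or_=float(np.exp(beta)),
        or_ci_low=float(np.exp(lo)),
        or_ci_high=float(np.exp(hi)),
        n_snp=int(n_snp),
    )


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MREstimate:
    """Per-SNP ratio estimate βY/βX.

    Default SE is the first-order NOME approximation seY/|βX|; with
    ``second_order=True`` the delta-method term for exposure uncertainty is
    added: sqrt(seY²/βX² + βY²·seX²/βX⁴).
    """
    if inst.beta_exp == 0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    beta = inst.beta_out / inst.beta_exp
    if second_order:
        se = np.sqrt(
            inst.se_out**2 / inst.beta_exp**2
            + inst.beta_out**2 * inst.se_exp**2 / inst.beta_exp**4
        )
    else:
        se = inst.se_out / abs(inst.beta_exp)
    return _finish("WaldRatio", beta, se, 1)


# ---------------------------------------------------------------------------
# Array kernels — shared by the public API, the sensitivity module, and the
# simulation calibration loops (which skip object construction for speed).
# ---------------------------------------------------------------------------

def ivw_arrays(bx, by, sy, model: str = "random"):
    """Closed-form IVW on raw arrays.  Returns (beta, se, Q, df)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    w = 1.0 / (sy * sy)
    den = np.sum(w * bx * bx)
    beta = np.sum(w * bx * by) / den
    se_fixed = np.sqrt(1.0 / den)
    resid = by - beta * bx
    q = float(np.sum(w * resid * resid))
    J = bx.size
    se = se_fixed
    if model == "random" and J > 1:
        se = se_fixed * max(1.0, np.sqrt(q / (J - 1)))
    elif model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    return float(beta), float(se), q, J - 1


def egger_arrays(bx, by, sy):
    """Weighted Egger regression on arrays oriented to bx > 0.

    Returns (intercept, slope, se_intercept, se_slope, sigma): classical
    weighted-least-squares inference with sigma² the weighted residual mean
    square on J−2 df (the SEs scale with sigma, so over-dispersion widens
    them; paired with t(J−2) tests this is exactly calibrated under
    homogeneity).
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / (sy * sy)
    sw = w.sum()
    swx = np.sum(w * x)
    swx2 = np.sum(w * x * x)
    swy = np.sum(w * y)
    swxy = np.sum(w * x * y)
    det = sw * swx2 - swx * swx
    if det <= 0 or np.isclose(det / (sw * swx2), 0.0):
        raise ValueError("degenerate design: exposure effects identical after orientation")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swx2 * swy - swx * swxy) / det
    J = x.size
    resid = y - intercept - slope * x
    sigma2 = np.sum(w * resid * resid) / (J - 2)
    se_slope = np.sqrt(sw / det * sigma2)
    se_int = np.sqrt(swx2 / det * sigma2)
    return float(intercept), float(slope), float(se_int), float(se_slope), float(np.sqrt(sigma2))


def weighted_median_arrays(ratios, weights):
    """Weight-CDF interpolation at 0.5 over sorted ratios."""
    ratios = np.asarray(ratios, float)
    weights = np.asarray(weights, float)
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w)
    mid = cum - w / 2.0
    return float(np.interp(0.5, mid, r))


def weighted_median_bootstrap(bx, sx, by, sy, n_boot: int, rng: np.random.Generator):
    """Parametric-bootstrap SE of the weighted median (vectorised over draws)."""
    bx = np.asarray(bx, float)
    sx = np.asarray(sx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    J = bx.size
    bxs = bx + sx * rng.standard_normal((n_boot, J))
    bys = by + sy * rng.standard_normal((n_boot, J))
    ratios = bys / bxs
    weights = (bxs / sy) ** 2
    order = np.argsort(ratios, axis=1, kind="mergesort")
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    mid = cum - w / 2.0
    # interpolate each row at 0.5
    idx = np.sum(mid < 0.5, axis=1)
    idx = np.clip(idx, 1, J - 1)
    rows = np.arange(n_boot)
    m_lo = mid[rows, idx - 1]
    m_hi = mid[rows, idx]
    r_lo = r[rows, idx - 1]
    r_hi = r[rows, idx]
    frac = np.where(m_hi > m_lo, (0.5 - m_lo) / (m_hi - m_lo), 0.0)
    est = r_lo + frac * (r_hi - r_lo)
    # rows where 0.5 falls outside the midpoint range take the boundary ratio
    est = np.where(mid[:, 0] >= 0.5, r[:, 0], est)
    est = np.where(mid[:, -1] <= 0.5, r[:, -1], est)
    return float(np.std(est, ddof=1))


# ---------------------------------------------------------------------------
# Public estimators on InstrumentSet
# ---------------------------------------------------------------------------

def ivw(instruments: InstrumentSet, model: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate (regression through the origin).

    ``model="fixed"`` uses the closed-form fixed-effect SE; ``"random"``
    (default) applies the multiplicative random-effects inflation
    max(1, sqrt(Q/(J−1))).
    """
    if len(instruments) < 2:
        raise ValueError("IVW requires at least 2 instruments")
    beta, se, _, _ = ivw_arrays(
        instruments.beta_exp, instruments.beta_out, instruments.se_out, model
    )
    return _finish(f"IVW-{model}", beta, se, len(instruments))


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: MREstimate


def mr_egger(instruments: InstrumentSet) -> EggerResult:
    """MR-Egger slope (causal effect) and intercept (directional pleiotropy)."""
    if len(instruments) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    a, b, se_a, se_b, _ = egger_arrays(
        instruments.beta_exp, instruments.beta_out, instruments.se_out
    )
    J = len(instruments)
    return EggerResult(
        slope=_finish("Egger-slope", b, se_b, J, df=J - 2),
        intercept=_finish("Egger-intercept", a, se_a, J, df=J - 2),
    )


def weighted_median(
    instruments: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Weights are (βX/seY)², normalised; the estimate interpolates the sorted
    Wald ratios at cumulative weight 0.5.  The bootstrap redraws βX and βY
    from normals at their SEs (``n_boot`` replicates, seeded).
    """
    if len(instruments) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    bx = instruments.beta_exp
    by = instruments.beta_out
    sy = instruments.se_out
    sx = instruments.se_exp
    est = weighted_median_arrays(by / bx, (bx / sy) ** 2)
    rng = np.random.default_rng(seed)
    se = weighted_median_bootstrap(bx, sx, by, sy, n_boot, rng)
    return _finish("WeightedMedian", est, se, len(instruments))
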
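"""Heterogeneity, pleiotropy, outlier, and influence diagnostics.

* Cochran's Q — weighted squared deviation of the per-SNP Wald ratios from
  the IVW estimate, chi-square with J−1 df under homogeneity.
* Leave-one-out — the IVW estimate recomputed J times with one SNP held out,
  plus the all-SNP reference row; a single influential SNP shows up as a
  large shift.
* Funnel coordinates — (ratio, precision = 1/se(ratio)) pairs; under no
  pleiotropy the scatter is symmetric around the IVW estimate.  Coordinates
  only, no rendering.
* MR-PRESSO — a residual-sum-of-squares global test for horizontal
  pleiotropy with per-SNP outlier detection (Bonferroni-corrected empirical
  p-values) and a distortion test comparing the outlier-removed and full IVW
  estimates.  All empirical p-values carry an add-one pseudo-count so finite
  simulation never reports p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, _finish, ivw_arrays, mr_egger
from .instruments import InstrumentSet

__all__ = [
    "cochran_q",
    "leave_one_out",
    "funnel_coordinates",
    "mr_presso",
    "PressoResult",
    "SensitivityReport",
    "sensitivity_report",
]


def cochran_q(instruments: InstrumentSet | None = None, *, bx=None, by=None, sy=None) -> dict:
    """Cochran's Q over Wald ratios with inverse-variance weights (βX/seY)².

    Accepts either an :class:`InstrumentSet` or raw arrays.  Returns
    ``{"q": Q, "df": J-1, "pval": chi2 survival}``.
    """
    if instruments is not None:
        bx, by, sy = instruments.beta_exp, instruments.beta_out, instruments.se_out
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    if bx.size < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    beta, _, q, df = ivw_arrays(bx, by, sy, model="fixed")
    return {"q": float(q), "df": int(df), "pval": float(stats.chi2.sf(q, df))}


def leave_one_out(instruments: InstrumentSet, model: str = "random") -> pd.DataFrame:
    """Per-excluded-SNP IVW estimates plus the all-SNP reference row."""
    J = len(instruments)
    if J < 3:
        raise ValueError("leave-one-out requires at least 3 instruments")
    bx, by, sy = instruments.beta_exp, instruments.beta_out, instruments.se_out
    rows = []
    for j, rsid in enumerate(instruments.rsids):
        keep = np.arange(J) != j
        beta, se, _, _ = ivw_arrays(bx[keep], by[keep], sy[keep], model)
        est = _finish(f"IVW-{model}", beta, se, J - 1)
        rows.append({"excluded": rsid, "beta": est.beta, "se": est.se,
                     "pval": est.pval, "n_snp": J - 1})
    beta, se, _, _ = ivw_arrays(bx, by, sy, model)
    est = _finish(f"IVW-{model}", beta, se, J)
    rows.append({"excluded": "(none)", "beta": est.beta, "se": est.se,
                 "pval": est.pval, "n_snp": J})
    return pd.DataFrame(rows)


def funnel_coordinates(instruments: InstrumentSet) -> pd.DataFrame:
    """Per-SNP (Wald ratio, precision = |βX|/seY) pairs for funnel plots."""
    if len(instruments) < 1:
        raise ValueError("funnel coordinates need at least 1 instrument")
    bx, by, sy = instruments.beta_exp, instruments.beta_out, instruments.se_out
    return pd.DataFrame({
        "rsid": instruments.rsids,
        "ratio": by / bx,
        "precision": np.abs(bx) / sy,
    })


@dataclass
class PressoResult:
    """MR-PRESSO global / outlier / distortion results."""

    global_rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outlier_rsids: list[str]
    distortion_pval: float | None
    corrected_estimate: MREstimate | None
    n_sim: int
    seed: int


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes from running sums (length-J vector)."""
    num = np.sum(w * bx * by)
    den = np.sum(w * bx * bx)
    return (num - w * bx * by) / (den - w * bx * bx)


def presso_global_arrays(bx, by, sy, n_sim: int, rng: np.random.Generator):
    """Observed RSS, simulated RSS array, and per-SNP simulated residuals.

    The observed RSS is Σ_j w_j (βY_j − β̂(−j)·βX_j)² with β̂(−j) the
    leave-one-out IVW slope.  The null distribution regenerates βY_j* from
    Normal(β̂(−j)·βX_j, seY_j), recomputing leave-one-out slopes per draw.
    Returns (rss_obs, rss_sim (n_sim,), res2_obs (J,), res2_sim (n_sim, J)).
    """
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    J = bx.size
    w = 1.0 / (sy * sy)
    slopes = _loo_slopes(bx, by, w)
    resid_obs = by - slopes * bx
    res2_obs = w * resid_obs * resid_obs
    rss_obs = float(res2_obs.sum())

    expect = slopes * bx
    by_sim = expect[None, :] + sy[None, :] * rng.standard_normal((n_sim, J))
    num_tot = by_sim @ (w * bx)                       # (n_sim,)
    den_tot = np.sum(w * bx * bx)
    num_loo = num_tot[:, None] - by_sim * (w * bx)[None, :]
    den_loo = den_tot - (w * bx * bx)[None, :]
    slopes_sim = num_loo / den_loo
    resid_sim = by_sim - slopes_sim * bx[None, :]
    res2_sim = w[None, :] * resid_sim * resid_sim
    rss_sim = res2_sim.sum(axis=1)
    return rss_obs, rss_sim, res2_obs, res2_sim


def mr_presso(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    model: str = "random",
    distortion_sims: int = 1000,
) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    Empirical p-values use the add-one pseudo-count (1 + #exceedances) /
    (n_sim + 1).  Per-SNP outlier p-values are two-sided through the squared
    weighted residual and Bonferroni-corrected across the J instruments; the
    distortion test resamples pseudo-outlier sets from the unflagged SNPs
    (seed offset derived deterministically from ``seed``).  The corrected
    estimate is IVW on the unflagged SNPs, or None when no outlier is
    flagged or all SNPs are flagged.
    """
    J = len(instruments)
    if J < 4:
        raise ValueError("MR-PRESSO requires at least 4 instruments")
    bx, by, sy = instruments.beta_exp, instruments.beta_out, instruments.se_out
    rng = np.random.default_rng(seed)
    rss_obs, rss_sim, res2_obs, res2_sim = presso_global_arrays(bx, by, sy, n_sim, rng)
    global_pval = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)

    exceed = np.sum(res2_sim >= res2_obs[None, :], axis=0)
    pvals_raw = (1.0 + exceed) / (n_sim + 1.0)
    pvals_bonf = np.minimum(pvals_raw * J, 1.0)
    outlier_pvals = dict(zip(instruments.rsids, pvals_bonf))
    flagged = [r for r, p in outlier_pvals.items() if p < outlier_alpha]

    distortion_pval = None
    corrected = None
    if flagged and len(flagged) < J:
        keep_mask = np.array([r not in flagged for r in instruments.rsids])
        beta_all, _, _, _ = ivw_arrays(bx, by, sy, model)
        beta_in, se_in, _, _ = ivw_arrays(bx[keep_mask], by[keep_mask], sy[keep_mask], model)
        corrected = _finish(f"IVW-{model}", beta_in, se_in, int(keep_mask.sum()))
        d_obs = beta_all - beta_in
        # Null distortion: pseudo-outlier sets drawn from the unflagged pool.
        rng_d = np.random.default_rng(seed + 1_000_003)
        in_idx = np.flatnonzero(keep_mask)
        n_flag = len(flagged)
        d_null = np.empty(distortion_sims)
        for b in range(distortion_sims):
            pseudo = rng_d.choice(in_idx, size=n_flag, replace=True)
            idx = np.concatenate([in_idx, pseudo])
            beta_b, _, _, _ = ivw_arrays(bx[idx], by[idx], sy[idx], model)
            d_null[b] = beta_b - beta_in
        distortion_pval = float(
            (1.0 + np.sum(np.abs(d_null) >= abs(d_obs))) / (distortion_sims + 1.0)
        )
    return PressoResult(
        global_rss_obs=rss_obs,
        global_pval=float(global_pval),
        outlier_pvals={k: float(v) for k, v in outlier_pvals.items()},
        outlier_rsids=flagged,
        distortion_pval=distortion_pval,
        corrected_estimate=corrected,
        n_sim=n_sim,
        seed=seed,
    )


@dataclass
class SensitivityReport:
    """Bundle of all diagnostics for one exposure/outcome pair."""

    exposure_id: str
    outcome_id: str
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    presso: PressoResult | None
    loo: pd.DataFrame
    funnel: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def sensitivity_report(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    model: str = "random",
    outlier_alpha: float = 0.05,
) -> SensitivityReport:
    """Run the full diagnostic suite on one instrument set."""
    q = cochran_q(instruments)
    egger = mr_egger(instruments)
    notes: list[str] = []
    presso = None
    if len(instruments) >= 4:
        presso = mr_presso(instruments, n_sim=n_sim, seed=seed, model=model,
                           outlier_alpha=outlier_alpha)
    else:
        notes.append("MR-PRESSO skipped: fewer than 4 instruments")
    return SensitivityReport(
        exposure_id=instruments.exposure_id,
        outcome_id=instruments.outcome_id,
        q_stat=q["q"],
        q_df=q["df"],
        q_pval=q["pval"],
        egger_intercept=egger.intercept.beta,
        egger_intercept_se=egger.intercept.se,
        egger_intercept_pval=egger.intercept.pval,
        presso=presso,
        loo=leave_one_out(instruments, model=model),
        funnel=funnel_coordinates(instruments),
        notes=notes,
    )
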
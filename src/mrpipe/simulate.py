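"""Synthetic GWAS summary statistics with known ground truth.

The generator emulates the study's data constellation at the
summary-statistics level (no individual genotypes):

* a quantitative exposure GWAS of a microbiome feature in n = 1539
  individuals, whose instruments are the SNPs reaching p < 1e-5 — instrument
  effects are rejection-resampled until their *observed* association clears
  the threshold, so winner's-curse selection is reproduced rather than
  hidden;
* a rare-outcome case-control GWAS on the log-odds scale (489 cases /
  75,531 controls by default), with SEs from the effective sample size
  4/(1/cases + 1/controls);
* optionally a quantitative mediator (serum protein) GWAS with its own
  instruments, wired so the exposure's total effect decomposes as
  direct + beta1·beta2;
* block-structured LD (exchangeable within-block r²) sufficient to exercise
  clumping and proxy search;
* configurable horizontal pleiotropy and per-SNP contamination, both
  parameterised in units of the SNP's outcome SE.

Exposure SEs follow SE = 1/sqrt(2·N·f(1−f)) for standardised phenotypes;
outcome SEs follow SE = sqrt(2/(f(1−f)·N_eff)) on the log-OR scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDReference, SummaryStatsTable, CANONICAL_COLUMNS

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_study",
    "simulate_feature_panel",
    "panel_inputs",
    "calibration_report",
    "draw_summary_arrays",
]

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic exposure/outcome(/mediator) chain.

    ``theta`` is the *total* exposure→outcome effect (log-OR per SD);
    with a mediator, the direct effect is theta − beta1·beta2.
    Pleiotropy and contamination offsets are in units of each SNP's
    outcome SE.
    """

    seed: int
    n_snp: int = 20
    n_exposure_gwas: int = 1539
    n_cases: int = 489
    n_controls: int = 75_531
    outcome_type: str = "binary"          # or "quantitative"
    n_outcome_gwas: int = 241_112         # used for quantitative outcomes
    theta: float = 0.0
    gamma_sd: float = 0.08
    p_threshold: float = 1e-5
    eaf_range: tuple[float, float] = (0.05, 0.95)
    pleiotropy_mode: str = "none"         # none | balanced | directional | inside-violating
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0      # share of instruments carrying pleiotropy
    contaminate: tuple[tuple[int, float], ...] = ()
    block_size: int = 1
    block_r2: float = 0.0
    swap_rate: float = 0.3                # share of outcome rows stored allele-swapped
    palindromic_fraction: float = 0.0
    n_missing_outcome: int = 0            # index SNPs absent from the outcome table
    noise_free: bool = False
    # mediator chain
    with_mediator: bool = False
    beta1: float = 0.0                    # exposure -> mediator (SD per SD)
    beta2: float = 0.0                    # mediator -> outcome (log-OR per SD)
    n_mediator_gwas: int = 2000
    n_mediator_snp: int = 15

    def __post_init__(self):
        if self.n_snp < 1 or self.n_exposure_gwas < 3:
            raise ValueError("sizes must be positive (n_snp ≥ 1, exposure n ≥ 3)")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy sd must be ≥ 0")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside-violating"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.outcome_type not in ("binary", "quantitative"):
            raise ValueError("outcome_type must be binary or quantitative")
        if not 0 <= self.block_r2 <= 1 or self.block_size < 1:
            raise ValueError("invalid LD block settings")


@dataclass
class SimulatedStudy:
    """Generated tables plus the ground truth that produced them."""

    exposure: SummaryStatsTable
    outcome: SummaryStatsTable
    mediator: SummaryStatsTable | None
    ld: LDReference
    truth: dict


def _effective_n(n_cases: int, n_controls: int) -> float:
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def _outcome_se(eaf: np.ndarray, config: SimulationConfig) -> np.ndarray:
    if config.outcome_type == "binary":
        n_eff = _effective_n(config.n_cases, config.n_controls)
        return np.sqrt(2.0 / (eaf * (1.0 - eaf) * n_eff))
    return 1.0 / np.sqrt(2.0 * config.n_outcome_gwas * eaf * (1.0 - eaf))


def _draw_significant_instruments(
    rng: np.random.Generator,
    n_snp: int,
    n_gwas: int,
    gamma_sd: float,
    p_threshold: float,
    eaf_range: tuple[float, float],
    noise_free: bool,
    max_rounds: int = 2000,
):
    """Rejection-sample (gamma, eaf, se, beta_hat) until observed p < threshold."""
    z_thr = stats.norm.isf(p_threshold / 2.0)
    gamma = np.empty(n_snp)
    eaf = np.empty(n_snp)
    se = np.empty(n_snp)
    beta_hat = np.empty(n_snp)
    todo = np.ones(n_snp, dtype=bool)
    for _ in range(max_rounds):
        k = int(todo.sum())
        if k == 0:
            break
        g = gamma_sd * rng.standard_normal(k)
        f = rng.uniform(*eaf_range, size=k)
        s = 1.0 / np.sqrt(2.0 * n_gwas * f * (1.0 - f))
        bh = g if noise_free else g + s * rng.standard_normal(k)
        ok = np.abs(bh / s) > z_thr
        idx = np.flatnonzero(todo)[ok]
        gamma[idx] = g[ok]
        eaf[idx] = f[ok]
        se[idx] = s[ok]
        beta_hat[idx] = bh[ok]
        todo[idx] = False
    if todo.any():
        raise RuntimeError(
            "could not reach the instrument p-threshold by rejection sampling; "
            "increase gamma_sd or the exposure sample size"
        )
    pval = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
    return gamma, eaf, se, beta_hat, pval


def _pleiotropy(rng, config: SimulationConfig, gamma: np.ndarray, se_out: np.ndarray):
    """Per-SNP pleiotropic offsets alpha_j (outcome-beta scale).

    "Directional" is defined in the exposure-increasing orientation: the
    offset's sign follows sign(gamma_j), so every Wald ratio is pushed the
    same way — with symmetric allele coding a literally-constant offset
    would cancel in any regression through the origin.
    """
    J = gamma.size
    alpha = np.zeros(J)
    if config.pleiotropy_mode == "none":
        return alpha, np.zeros(J, dtype=bool)
    n_affected = int(round(config.pleiotropy_fraction * J))
    affected = np.zeros(J, dtype=bool)
    affected[rng.choice(J, size=n_affected, replace=False)] = True
    z = rng.standard_normal(J)
    sign = np.where(gamma < 0, -1.0, 1.0)
    if config.pleiotropy_mode == "balanced":
        raw = config.pleiotropy_sd * z
    elif config.pleiotropy_mode == "directional":
        raw = (config.pleiotropy_mean + config.pleiotropy_sd * z) * sign
    else:  # inside-violating: offset scales with instrument strength
        raw = (config.pleiotropy_mean * np.abs(gamma) / config.gamma_sd
               + config.pleiotropy_sd * z) * sign
    alpha[affected] = raw[affected] * se_out[affected]
    return alpha, affected


def draw_summary_arrays(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Fast array-level draw of one exposure/outcome instrument panel.

    This is the same generative process as :func:`simulate_study` restricted
    to the index SNPs, without table construction — used by the calibration
    loops where thousands of replicates are needed.
    """
    gamma, eaf, sx, bx, px = _draw_significant_instruments(
        rng, config.n_snp, config.n_exposure_gwas, config.gamma_sd,
        config.p_threshold, config.eaf_range, config.noise_free,
    )
    sy = _outcome_se(eaf, config)
    alpha, affected = _pleiotropy(rng, config, gamma, sy)
    eps = np.zeros(config.n_snp) if config.noise_free else sy * rng.standard_normal(config.n_snp)
    by = config.theta * gamma + alpha + eps
    contaminated = []
    for idx, offset in config.contaminate:
        # oriented like the pleiotropy modes: the offset pushes the SNP's
        # Wald ratio in a fixed direction regardless of allele coding
        by[idx] += offset * sy[idx] * (1.0 if gamma[idx] >= 0 else -1.0)
        contaminated.append(int(idx))
    return {
        "gamma": gamma, "eaf": eaf, "sx": sx, "bx": bx, "px": px,
        "sy": sy, "by": by, "alpha": alpha, "pleiotropic": affected,
        "contaminated": contaminated,
    }


def _draw_alleles(rng, J: int, palindromic_fraction: float):
    pairs = []
    for _ in range(J):
        if rng.uniform() < palindromic_fraction:
            pairs.append(_PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))])
        else:
            pairs.append(_NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))])
    ea = np.array([p[0] for p in pairs])
    oa = np.array([p[1] for p in pairs])
    return ea, oa


def _block_layout(j: int, k: int):
    """(chrom, pos) for member k of block j; blocks > 1000 kb apart."""
    chrom = str((j % 22) + 1)
    pos = 10_000_000 + (j // 22) * 5_000_000 + k * 10_000
    return chrom, pos


def _rows_for_trait(
    rsids, chroms, poss, ea, oa, eaf, beta, se, n, rng, swap_rate,
):
    """Canonical rows, a random share stored with swapped allele order."""
    swap = rng.uniform(size=len(rsids)) < swap_rate
    beta = np.where(swap, -beta, beta)
    eaf = np.where(swap, 1.0 - eaf, eaf)
    ea_out = np.where(swap, oa, ea)
    oa_out = np.where(swap, ea, oa)
    pval = 2.0 * stats.norm.sf(np.abs(beta / se))
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return pd.DataFrame({
        "rsid": rsids, "chrom": chroms, "pos": poss,
        "effect_allele": ea_out, "other_allele": oa_out,
        "eaf": eaf, "beta": beta, "se": se, "pval": pval, "n": float(n),
    })[CANONICAL_COLUMNS]


def simulate_study(config: SimulationConfig, trait_id: str = "feature") -> SimulatedStudy:
    """Generate one exposure/outcome(/mediator) study with ground truth.

    Every instrument occupies its own LD block; non-index block members carry
    the attenuated effect r·beta (r = sqrt(block_r2)) with independent
    estimation noise, and appear in the pairwise LD table at the block r².
    All randomness flows from the single seeded generator, so a fixed config
    reproduces byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snp
    base = draw_summary_arrays(config, rng)
    r = math.sqrt(config.block_r2)

    rsids, chroms, poss = [], [], []
    eaf_l, bx_l, sx_l, by_l, sy_l, is_index = [], [], [], [], [], []
    for j in range(J):
        for k in range(config.block_size):
            rsid = f"rs_{trait_id}_{j:03d}" + ("" if k == 0 else f"_{k}")
            chrom, pos = _block_layout(j, k)
            rsids.append(rsid)
            chroms.append(chrom)
            poss.append(pos)
            eaf_l.append(base["eaf"][j])
            is_index.append(k == 0)
            if k == 0:
                bx_l.append(base["bx"][j])
                sx_l.append(base["sx"][j])
                by_l.append(base["by"][j])
                sy_l.append(base["sy"][j])
            else:
                sx_l.append(base["sx"][j])
                sy_l.append(base["sy"][j])
                noise_x = 0.0 if config.noise_free else base["sx"][j] * rng.standard_normal()
                noise_y = 0.0 if config.noise_free else base["sy"][j] * rng.standard_normal()
                bx_l.append(r * base["gamma"][j] + noise_x)
                by_l.append(r * (config.theta * base["gamma"][j] + base["alpha"][j]) + noise_y)
    eaf_a = np.array(eaf_l)
    ea, oa = _draw_alleles(rng, len(rsids), config.palindromic_fraction)

    exposure_df = _rows_for_trait(
        rsids, chroms, poss, ea, oa, eaf_a, np.array(bx_l), np.array(sx_l),
        config.n_exposure_gwas, rng, swap_rate=0.0,
    )
    # Optionally drop the first few index SNPs from the outcome (proxy search).
    missing = {f"rs_{trait_id}_{j:03d}" for j in range(config.n_missing_outcome)}
    keep = [i for i, rs in enumerate(rsids) if rs not in missing]
    n_out = (config.n_cases + config.n_controls
             if config.outcome_type == "binary" else config.n_outcome_gwas)
    outcome_df = _rows_for_trait(
        [rsids[i] for i in keep], [chroms[i] for i in keep], [poss[i] for i in keep],
        ea[keep], oa[keep], eaf_a[keep], np.array(by_l)[keep], np.array(sy_l)[keep],
        n_out, rng, config.swap_rate,
    )

    ld = LDReference()
    if config.block_size > 1:
        for j in range(J):
            members = [f"rs_{trait_id}_{j:03d}" + ("" if k == 0 else f"_{k}")
                       for k in range(config.block_size)]
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    ld.add(members[a], members[b], config.block_r2)

    mediator_table = None
    truth_mediator: dict = {}
    if config.with_mediator:
        sm = 1.0 / np.sqrt(2.0 * config.n_mediator_gwas * eaf_a * (1.0 - eaf_a))
        noise_m = (np.zeros(len(rsids)) if config.noise_free
                   else sm * rng.standard_normal(len(rsids)))
        gamma_full = np.repeat(base["gamma"], config.block_size)
        scale = np.where(np.array(is_index), 1.0, r)
        bm = config.beta1 * gamma_full * scale + noise_m
        med_rows = [_rows_for_trait(rsids, chroms, poss, ea, oa, eaf_a, bm, sm,
                                    config.n_mediator_gwas, rng, config.swap_rate)]
        # the mediator's own instruments, absent from the exposure GWAS
        delta, eaf_m, sm_m, bm_m, _ = _draw_significant_instruments(
            rng, config.n_mediator_snp, config.n_mediator_gwas, config.gamma_sd,
            config.p_threshold, config.eaf_range, config.noise_free,
        )
        m_rsids = [f"rs_{trait_id}_med{k:03d}" for k in range(config.n_mediator_snp)]
        m_chroms, m_poss = zip(*[_block_layout(J + 7 + k2, 0) for k2 in range(config.n_mediator_snp)])
        m_ea, m_oa = _draw_alleles(rng, config.n_mediator_snp, config.palindromic_fraction)
        med_rows.append(_rows_for_trait(m_rsids, list(m_chroms), list(m_poss),
                                        m_ea, m_oa, eaf_m, bm_m, sm_m,
                                        config.n_mediator_gwas, rng, 0.0))
        mediator_df = pd.concat(med_rows, ignore_index=True)
        mediator_table = SummaryStatsTable(f"{trait_id}_mediator", "quantitative", mediator_df)
        # mediator SNPs act on the outcome through the mediator only
        sy_m = _outcome_se(eaf_m, config)
        noise_ym = (np.zeros(config.n_mediator_snp) if config.noise_free
                    else sy_m * rng.standard_normal(config.n_mediator_snp))
        by_m = config.beta2 * delta + noise_ym
        out_extra = _rows_for_trait(m_rsids, list(m_chroms), list(m_poss),
                                    m_ea, m_oa, eaf_m, by_m, sy_m,
                                    n_out, rng, config.swap_rate)
        outcome_df = pd.concat([outcome_df, out_extra], ignore_index=True)
        truth_mediator = {
            "beta1": config.beta1,
            "beta2": config.beta2,
            "direct": config.theta - config.beta1 * config.beta2,
            "proportion": (config.beta1 * config.beta2 / config.theta
                           if config.theta != 0 else float("nan")),
            "delta": delta.tolist(),
        }

    exposure = SummaryStatsTable(trait_id, "quantitative", exposure_df)
    outcome = SummaryStatsTable(
        f"{trait_id}_outcome",
        config.outcome_type,
        outcome_df,
        n_cases=config.n_cases if config.outcome_type == "binary" else None,
        n_controls=config.n_controls if config.outcome_type == "binary" else None,
    )
    truth = {
        "theta": config.theta,
        "gamma": base["gamma"].tolist(),
        "pleiotropy_alpha": base["alpha"].tolist(),
        "pleiotropic_indices": np.flatnonzero(base["pleiotropic"]).tolist(),
        "contaminated_indices": base["contaminated"],
        "contaminated_rsids": [f"rs_{trait_id}_{i:03d}" for i in base["contaminated"]],
        "missing_in_outcome": sorted(missing),
        "config": asdict(config),
        **truth_mediator,
    }
    return SimulatedStudy(exposure=exposure, outcome=outcome,
                          mediator=mediator_table, ld=ld, truth=truth)


def simulate_feature_panel(
    config: SimulationConfig,
    n_features: int = 500,
    n_causal: int = 0,
    causal_theta: float = 0.2,
) -> list[SimulatedStudy]:
    """A panel of features, the first ``n_causal`` with theta = causal_theta.

    Feature IDs (``feat0001`` ...) are unique and stable for a fixed seed;
    each feature draws from an independent child of the master seed.
    """
    if n_causal > n_features:
        raise ValueError("n_causal cannot exceed n_features")
    children = np.random.SeedSequence(config.seed).spawn(n_features)
    panel = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1, np.uint32)[0]) % (2**31)
        theta = causal_theta if i < n_causal else 0.0
        cfg_i = dataclass_replace(config, seed=sub_seed, theta=theta)
        panel.append(simulate_study(cfg_i, trait_id=f"feat{i + 1:04d}"))
    return panel


def dataclass_replace(config: SimulationConfig, **kw) -> SimulationConfig:
    d = asdict(config)
    d.update(kw)
    d["eaf_range"] = tuple(d["eaf_range"])
    d["contaminate"] = tuple(tuple(c) for c in d["contaminate"])
    return SimulationConfig(**d)


def panel_inputs(panel: list[SimulatedStudy]):
    """Merge a feature panel into pipeline inputs.

    Returns (exposures dict keyed by trait id, combined outcome table,
    combined LD reference).  Feature SNP IDs are disjoint by construction so
    outcome rows concatenate cleanly.
    """
    exposures = {s.exposure.trait_id: s.exposure for s in panel}
    out0 = panel[0].outcome
    outcome_df = pd.concat([s.outcome.df for s in panel], ignore_index=True)
    outcome = SummaryStatsTable(
        "outcome", out0.trait_type, outcome_df,
        n_cases=out0.n_cases, n_controls=out0.n_controls, validated=True,
    )
    ld = LDReference()
    for s in panel:
        for (a, b), r2 in s.ld._r2.items():
            ld.add(a, b, r2)
    return exposures, outcome, ld


def _binom_ci(k: int, n: int):
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return float(ci.low), float(ci.high)


def calibration_report(
    replicates: int,
    config: SimulationConfig,
    estimators: tuple[str, ...] = ("ivw_fixed", "ivw_random", "egger", "weighted_median", "presso_global"),
    alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
    presso_sims: int = 1000,
) -> dict:
    """Empirical operating characteristics over repeated simulate→estimate runs.

    For each requested estimator: rejection rate at ``alpha`` (type-I error
    when theta = 0, power otherwise) with its exact binomial 95 % interval,
    mean bias, RMSE, and 95 % CI coverage of the true theta.  The Egger
    entry reports the slope's characteristics plus the intercept test's
    rejection rate; ``presso_global`` reports the global-test rejection rate
    only.  Runs on the array fast path of the study generator.
    """
    from .estimators import (egger_arrays, ivw_arrays, weighted_median_arrays,
                             weighted_median_bootstrap)
    from .sensitivity import presso_global_arrays

    if replicates < 100:
        raise ValueError("need at least 100 replicates for stable rates")
    children = np.random.SeedSequence(seed).spawn(replicates)
    z975 = stats.norm.ppf(0.975)
    est_draws: dict[str, list] = {e: [] for e in estimators}
    rejects: dict[str, list] = {e: [] for e in estimators}
    covers: dict[str, list] = {e: [] for e in estimators if e != "presso_global"}
    rejects_egger_int: list[bool] = []

    for child in children:
        rng = np.random.default_rng(child)
        d = draw_summary_arrays(config, rng)
        bx, sx, by, sy = d["bx"], d["sx"], d["by"], d["sy"]
        J = bx.size
        for e in estimators:
            if e in ("ivw_fixed", "ivw_random"):
                model = "fixed" if e == "ivw_fixed" else "random"
                beta, se, _, _ = ivw_arrays(bx, by, sy, model)
            elif e == "egger":
                a, beta, se_a, se, _ = egger_arrays(bx, by, sy)
                tcrit = stats.t.ppf(0.975, J - 2)
                rejects_egger_int.append(abs(a) > tcrit * se_a)
                est_draws[e].append(beta)
                rejects[e].append(abs(beta) > tcrit * se)
                covers[e].append(abs(beta - config.theta) <= tcrit * se)
                continue
            elif e == "weighted_median":
                beta = weighted_median_arrays(by / bx, (bx / sy) ** 2)
                se = weighted_median_bootstrap(bx, sx, by, sy, n_boot, rng)
            elif e == "presso_global":
                rss_obs, rss_sim, _, _ = presso_global_arrays(bx, by, sy, presso_sims, rng)
                p = (1.0 + np.sum(rss_sim >= rss_obs)) / (presso_sims + 1.0)
                rejects[e].append(p < alpha)
                est_draws[e].append(rss_obs)
                continue
            else:
                raise ValueError(f"unknown estimator {e!r}")
            est_draws[e].append(beta)
            rejects[e].append(abs(beta) > z975 * se)
            covers[e].append(abs(beta - config.theta) <= z975 * se)

    out: dict = {"replicates": replicates, "alpha": alpha, "theta": config.theta}
    for e in estimators:
        rej = np.asarray(rejects[e], dtype=bool)
        k = int(rej.sum())
        lo, hi = _binom_ci(k, replicates)
        entry = {
            "rejection_rate": k / replicates,
            "rejection_ci": (lo, hi),
        }
        if e != "presso_global":
            est = np.asarray(est_draws[e], float)
            entry["bias"] = float(est.mean() - config.theta)
            entry["mc_se_of_mean"] = float(est.std(ddof=1) / math.sqrt(replicates))
            entry["sd"] = float(est.std(ddof=1))
            entry["rmse"] = float(np.sqrt(np.mean((est - config.theta) ** 2)))
            cov = np.asarray(covers[e], dtype=bool)
            kc = int(cov.sum())
            clo, chi = _binom_ci(kc, replicates)
            entry["coverage"] = kc / replicates
            entry["coverage_ci"] = (clo, chi)
        out[e] = entry
    if "egger" in estimators:
        k = int(np.sum(rejects_egger_int))
        lo, hi = _binom_ci(k, replicates)
        out["egger_intercept"] = {"rejection_rate": k / replicates,
                                  "rejection_ci": (lo, hi)}
    return out
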
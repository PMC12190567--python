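"""Two-step MR mediation through a serum-protein mediator.

Three IVW estimates enter: β1 (exposure → mediator), β2 (mediator →
outcome), and β3 (exposure → outcome, the total effect).  The indirect
effect is the product β1·β2 and the proportion mediated is β1·β2/β3.
Uncertainty comes from a parametric bootstrap: the three estimates are drawn
independently from normals at their point/SE (the three GWAS cohorts do not
overlap), the proportion recomputed per draw, and the 2.5/97.5 percentiles
reported.  Proportions outside [0,1] are reported as computed, flagged
qualitatively — inconsistent mediation is informative, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import MREstimate

__all__ = [
    "MediationResult",
    "two_step_mediation",
    "bootstrap_mediation",
    "mediation_screen",
]

#: |β3| below this is treated as an undefined denominator.
BETA3_TOL = 1e-12


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    beta2: float
    beta3: float
    indirect: float
    proportion: float          # nan when undefined
    defined: bool
    outside_unit_interval: bool
    prop_ci_low: float = np.nan
    prop_ci_high: float = np.nan
    prop_pval: float = np.nan
    n_boot: int = 0
    seed: int | None = None
    n_discarded: int = 0


def two_step_mediation(
    exp_med: MREstimate,
    med_out: MREstimate,
    exp_out: MREstimate,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Point estimates only: indirect = β1·β2, proportion = β1·β2/β3."""
    b1, b2, b3 = exp_med.beta, med_out.beta, exp_out.beta
    indirect = b1 * b2
    defined = abs(b3) >= BETA3_TOL
    proportion = indirect / b3 if defined else np.nan
    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta1=b1,
        beta2=b2,
        beta3=b3,
        indirect=indirect,
        proportion=proportion,
        defined=defined,
        outside_unit_interval=bool(defined and not (0.0 <= proportion <= 1.0)),
    )


def bootstrap_mediation(
    exp_med: MREstimate,
    med_out: MREstimate,
    exp_out: MREstimate,
    n_boot: int = 10_000,
    seed: int = 0,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Parametric bootstrap CI and p for the proportion mediated.

    β1*, β2*, β3* are drawn independently from Normal(point, SE); draws with
    |β3*| below tolerance are discarded and counted.  CI is the 2.5/97.5
    percentile pair; p is the two-sided proportion-of-draws test against 0
    with an add-one pseudo-count.  More than 50 % discarded draws is a hard
    error (unstable denominator).
    """
    for est, name in ((exp_med, "beta1"), (med_out, "beta2"), (exp_out, "beta3")):
        if not np.isfinite(est.se):
            raise ValueError(f"{name} needs a finite SE for the bootstrap")
    res = two_step_mediation(exp_med, med_out, exp_out,
                             exposure_id, mediator_id, outcome_id)
    rng = np.random.default_rng(seed)
    b1 = exp_med.beta + exp_med.se * rng.standard_normal(n_boot)
    b2 = med_out.beta + med_out.se * rng.standard_normal(n_boot)
    b3 = exp_out.beta + exp_out.se * rng.standard_normal(n_boot)
    ok = np.abs(b3) >= BETA3_TOL
    n_discarded = int(n_boot - ok.sum())
    if n_discarded > n_boot / 2:
        raise ValueError(
            f"{n_discarded}/{n_boot} bootstrap draws had |beta3| below tolerance; "
            "the total effect is too close to zero for a stable proportion"
        )
    prop = b1[ok] * b2[ok] / b3[ok]
    lo, hi = np.percentile(prop, [2.5, 97.5])
    n_ok = prop.size
    n_le = np.sum(prop <= 0.0)
    n_ge = np.sum(prop >= 0.0)
    pval = min(1.0, 2.0 * min(1.0 + n_le, 1.0 + n_ge) / (n_ok + 1.0))
    res.prop_ci_low = float(lo)
    res.prop_ci_high = float(hi)
    res.prop_pval = float(pval)
    res.n_boot = n_boot
    res.seed = seed
    res.n_discarded = n_discarded
    return res


def mediation_screen(
    exp_out: dict[str, MREstimate],
    exp_med: dict[tuple[str, str], MREstimate],
    med_out: dict[str, MREstimate],
    outcome_id: str = "outcome",
    alpha: float = 0.05,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[list[MediationResult], list[tuple[str, str, str]]]:
    """Mediation for every (exposure, mediator) pair passing all three screens.

    A pair qualifies when exposure→outcome, exposure→mediator, and
    mediator→outcome all have two-sided p < ``alpha``; other pairs are
    skipped with a logged reason.  Bootstrap seeds are derived
    deterministically per pair from the master ``seed``.
    Returns (results, skip log of (exposure, mediator, reason)).
    """
    results: list[MediationResult] = []
    skipped: list[tuple[str, str, str]] = []
    mediators = sorted(med_out)
    for k, exposure_id in enumerate(sorted(exp_out)):
        e_out = exp_out[exposure_id]
        for m, mediator_id in enumerate(mediators):
            pair = (exposure_id, mediator_id)
            if pair not in exp_med:
                skipped.append((*pair, "missing exposure→mediator estimate"))
                continue
            e_med = exp_med[pair]
            m_out = med_out[mediator_id]
            if e_out.pval >= alpha:
                skipped.append((*pair, "exposure→outcome not significant"))
                continue
            if e_med.pval >= alpha:
                skipped.append((*pair, "exposure→mediator not significant"))
                continue
            if m_out.pval >= alpha:
                skipped.append((*pair, "mediator→outcome not significant"))
                continue
            pair_seed = int(
                np.random.SeedSequence([seed, k, m]).generate_state(1, np.uint32)[0]
            ) % (2**31)
            results.append(
                bootstrap_mediation(
                    e_med, m_out, e_out,
                    n_boot=n_boot, seed=pair_seed,
                    exposure_id=exposure_id, mediator_id=mediator_id,
                    outcome_id=outcome_id,
                )
            )
    return results, skipped
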
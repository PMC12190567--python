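"""Three-phase study orchestration: screen, replicate, mediate.

Phase 1 screens every exposure (microbiome feature) against the primary
outcome: select instruments (p < 1e-5, MAF > 0.01), LD-clump (r² < 0.1,
±1000 kb), harmonize (palindrome handling, proxies at r² > 0.8), skip
exposures with fewer than 3 harmonized instruments, then estimate with IVW,
MR-Egger, and the weighted median; full sensitivity diagnostics run on
nominal IVW hits.  Phase 2 re-estimates each hit against replication
outcomes and flags direction-consistent, nominally significant
replications.  Phase 3 screens mediators (serum proteins) and decomposes
each qualifying pathway with the bootstrap.

Multiple testing defaults to the nominal two-sided alpha = 0.05 with no
correction (Bonferroni / Benjamini–Hochberg adjusted p-values are reported
alongside when requested).  Everything is deterministic given the config
including its master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import report as report_mod
from .estimators import MREstimate, ivw, mr_egger, weighted_median
from .instruments import InstrumentSet, harmonize, ld_clump, select_instruments, strength_summary
from .mediation import MediationResult, bootstrap_mediation
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats import LDReference, SummaryStatsTable

__all__ = [
    "RunConfig",
    "prepare_instruments",
    "estimate_all",
    "run_screen",
    "run_replication",
    "run_mediation",
    "run_full_study",
    "ScreenResult",
    "StudyBundle",
]


@dataclass(frozen=True)
class RunConfig:
    """All thresholds and run-level settings for one study."""

    p_threshold: float = 1e-5
    eaf_min: float = 0.01
    clump_r2: float = 0.1
    clump_kb: float = 1000.0
    proxy_r2: float = 0.8
    min_instruments: int = 3
    alpha: float = 0.05
    ivw_model: str = "random"
    palindrome_mode: str = "exclude-ambiguous"
    mt_correction: str = "none"          # none | bonferroni | bh
    n_boot_median: int = 1000
    presso_sims: int = 1000
    n_boot_mediation: int = 10_000
    seed: int = 13

    def __post_init__(self):
        for name in ("p_threshold", "eaf_min", "clump_r2", "clump_kb",
                     "proxy_r2", "alpha"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be positive")
        if self.mt_correction not in ("none", "bonferroni", "bh"):
            raise ValueError("mt_correction must be none, bonferroni, or bh")


def _sub_seed(master: int, *idx: int) -> int:
    return int(np.random.SeedSequence([master, *idx]).generate_state(1, np.uint32)[0]) % (2**31)


def prepare_instruments(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDReference,
    cfg: RunConfig,
) -> tuple[InstrumentSet | None, pd.DataFrame, str | None]:
    """Select → clump → harmonize one exposure against one outcome.

    Returns (instrument set or None, per-SNP disposition log, skip reason).
    """
    candidates = select_instruments(exposure, cfg.p_threshold, cfg.eaf_min)
    if candidates.empty:
        log = pd.DataFrame(columns=["rsid", "status", "detail"])
        return None, log, "no instruments at p threshold"
    kept, removed = ld_clump(candidates, ld, cfg.clump_r2, cfg.clump_kb)
    iset = harmonize(
        kept, outcome, exposure=exposure, ld=ld, proxy_r2=cfg.proxy_r2,
        palindrome_mode=cfg.palindrome_mode, exposure_id=exposure.trait_id,
    )
    for rsid, index_rsid in removed:
        iset.selection_log.append((rsid, "removed-by-clump", f"index {index_rsid}"))
    log = iset.log_frame()
    if len(iset) < cfg.min_instruments:
        return None, log, f"insufficient instruments ({len(iset)} < {cfg.min_instruments})"
    return iset, log, None


def estimate_all(iset: InstrumentSet, cfg: RunConfig, seed: int) -> dict[str, MREstimate]:
    """IVW (configured model), Egger slope/intercept, weighted median."""
    out = {"ivw": ivw(iset, model=cfg.ivw_model)}
    if len(iset) >= 3:
        egger = mr_egger(iset)
        out["egger_slope"] = egger.slope
        out["egger_intercept"] = egger.intercept
        out["weighted_median"] = weighted_median(iset, n_boot=cfg.n_boot_median, seed=seed)
    return out


def _adjust_pvals(pvals: pd.Series, method: str) -> pd.Series:
    m = len(pvals)
    if method == "bonferroni":
        return np.minimum(pvals * m, 1.0)
    if method == "bh":
        order = np.argsort(pvals.to_numpy())
        ranked = pvals.to_numpy()[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return pd.Series(out, index=pvals.index)
    return pvals


@dataclass
class ScreenResult:
    table: pd.DataFrame
    hits: list[str]
    sensitivity: dict[str, SensitivityReport]
    skip_log: pd.DataFrame
    instrument_sets: dict[str, InstrumentSet] = field(default_factory=dict)
    selection_logs: dict[str, pd.DataFrame] = field(default_factory=dict)
    strength: dict[str, dict] = field(default_factory=dict)


def run_screen(
    exposures: Mapping[str, SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDReference,
    cfg: RunConfig,
    run_sensitivity: bool = True,
) -> ScreenResult:
    """Phase 1: screen every exposure against the primary outcome.

    Every exposure ends up exactly once in either the estimate table or the
    skip log.  A hit is an exposure with IVW p < alpha (after the configured
    multiple-testing correction); hits get the full sensitivity suite.
    """
    rows: list[tuple[str, str, MREstimate]] = []
    skip_rows = []
    isets: dict[str, InstrumentSet] = {}
    logs: dict[str, pd.DataFrame] = {}
    strength: dict[str, dict] = {}
    ivw_pvals: dict[str, float] = {}

    for i, exp_id in enumerate(sorted(exposures)):
        iset, log, reason = prepare_instruments(exposures[exp_id], outcome, ld, cfg)
        logs[exp_id] = log
        if iset is None:
            skip_rows.append({"exposure": exp_id, "reason": reason})
            continue
        isets[exp_id] = iset
        strength[exp_id] = strength_summary(iset)
        ests = estimate_all(iset, cfg, seed=_sub_seed(cfg.seed, 0, i))
        for est in ests.values():
            rows.append((exp_id, outcome.trait_id, est))
        ivw_pvals[exp_id] = ests["ivw"].pval

    table = report_mod.estimates_frame(rows)
    if ivw_pvals:
        adj = _adjust_pvals(pd.Series(ivw_pvals), cfg.mt_correction)
        hits = sorted(adj.index[adj < cfg.alpha])
    else:
        hits = []

    sens: dict[str, SensitivityReport] = {}
    if run_sensitivity:
        for k, exp_id in enumerate(hits):
            if len(isets[exp_id]) >= 3:
                sens[exp_id] = sensitivity_report(
                    isets[exp_id], n_sim=cfg.presso_sims,
                    seed=_sub_seed(cfg.seed, 1, k), model=cfg.ivw_model,
                )
    skip_log = pd.DataFrame(skip_rows, columns=["exposure", "reason"])
    return ScreenResult(table=table, hits=list(hits), sensitivity=sens,
                        skip_log=skip_log, instrument_sets=isets,
                        selection_logs=logs, strength=strength)


def run_replication(
    hits: list[str],
    exposures: Mapping[str, SummaryStatsTable],
    replication_outcomes: Mapping[str, SummaryStatsTable],
    ld: LDReference,
    cfg: RunConfig,
    discovery_betas: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Phase 2: re-estimate each hit against each replication outcome.

    Harmonization is redone per outcome.  A row is ``replicated`` when the
    IVW direction matches discovery and p < alpha; ``not testable`` when
    fewer than ``min_instruments`` harmonized instruments survive.  The
    summary column labels hits replicating in some but not all testable
    outcomes ``partially replicated``.
    """
    rows = []
    for i, exp_id in enumerate(sorted(hits)):
        for out_id in sorted(replication_outcomes):
            outcome = replication_outcomes[out_id]
            iset, _, reason = prepare_instruments(exposures[exp_id], outcome, ld, cfg)
            if iset is None:
                rows.append({"exposure": exp_id, "outcome": out_id, "status": "not testable",
                             "n_snp": 0, "beta": np.nan, "se": np.nan, "pval": np.nan,
                             "direction_consistent": False, "detail": reason})
                continue
            est = ivw(iset, model=cfg.ivw_model)
            ref = discovery_betas.get(exp_id, np.nan) if discovery_betas else np.nan
            consistent = bool(np.sign(est.beta) == np.sign(ref)) if np.isfinite(ref) else True
            ok = consistent and est.pval < cfg.alpha
            rows.append({"exposure": exp_id, "outcome": out_id,
                         "status": "replicated" if ok else "not replicated",
                         "n_snp": est.n_snp, "beta": est.beta, "se": est.se,
                         "pval": est.pval, "direction_consistent": consistent,
                         "detail": ""})
    df = pd.DataFrame(rows, columns=["exposure", "outcome", "status", "n_snp", "beta",
                                     "se", "pval", "direction_consistent", "detail"])
    # per-hit summary label
    labels = {}
    for exp_id in hits:
        sub = df[df["exposure"] == exp_id]
        testable = sub[sub["status"] != "not testable"]
        n_rep = int((testable["status"] == "replicated").sum())
        if len(testable) == 0:
            labels[exp_id] = "not testable"
        elif n_rep == len(testable):
            labels[exp_id] = "replicated"
        elif n_rep > 0:
            labels[exp_id] = "partially replicated"
        else:
            labels[exp_id] = "not replicated"
    df["summary"] = df["exposure"].map(labels)
    return df.sort_values(["exposure", "outcome"], kind="mergesort").reset_index(drop=True)


def run_mediation(
    hits: list[str],
    exposures: Mapping[str, SummaryStatsTable],
    mediators: Mapping[str, SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDReference,
    cfg: RunConfig,
    exp_out_estimates: Mapping[str, MREstimate],
) -> tuple[list[MediationResult], pd.DataFrame]:
    """Phase 3: two-step MR mediation for hit exposures through mediators.

    Requires all three links nominally significant (exposure→outcome already
    established for hits; mediator→outcome and exposure→mediator estimated
    here with the same instrument rules).  Returns (results, skip log).
    """
    skip_rows = []
    # mediator -> outcome screen
    med_out: dict[str, MREstimate] = {}
    for m, med_id in enumerate(sorted(mediators)):
        iset, _, reason = prepare_instruments(mediators[med_id], outcome, ld, cfg)
        if iset is None:
            skip_rows.append({"exposure": "", "mediator": med_id,
                              "reason": f"mediator→outcome: {reason}"})
            continue
        est = ivw(iset, model=cfg.ivw_model)
        if est.pval >= cfg.alpha:
            skip_rows.append({"exposure": "", "mediator": med_id,
                              "reason": "mediator→outcome not significant"})
            continue
        med_out[med_id] = est

    results: list[MediationResult] = []
    for i, exp_id in enumerate(sorted(hits)):
        for m, med_id in enumerate(sorted(med_out)):
            iset, _, reason = prepare_instruments(
                exposures[exp_id], mediators[med_id], ld, cfg)
            if iset is None:
                skip_rows.append({"exposure": exp_id, "mediator": med_id,
                                  "reason": f"exposure→mediator: {reason}"})
                continue
            e_med = ivw(iset, model=cfg.ivw_model)
            if e_med.pval >= cfg.alpha:
                skip_rows.append({"exposure": exp_id, "mediator": med_id,
                                  "reason": "exposure→mediator not significant"})
                continue
            results.append(
                bootstrap_mediation(
                    e_med, med_out[med_id], exp_out_estimates[exp_id],
                    n_boot=cfg.n_boot_mediation,
                    seed=_sub_seed(cfg.seed, 2, i, m),
                    exposure_id=exp_id, mediator_id=med_id,
                    outcome_id=outcome.trait_id,
                )
            )
    skip_log = pd.DataFrame(skip_rows, columns=["exposure", "mediator", "reason"])
    return results, skip_log


@dataclass
class StudyBundle:
    screen: ScreenResult
    replication: pd.DataFrame | None
    mediation: list[MediationResult]
    mediation_skips: pd.DataFrame | None
    metadata: dict


def run_full_study(
    exposures: Mapping[str, SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDReference,
    cfg: RunConfig,
    replication_outcomes: Mapping[str, SummaryStatsTable] | None = None,
    mediators: Mapping[str, SummaryStatsTable] | None = None,
    out_dir: str | Path | None = None,
) -> StudyBundle:
    """Screen → replicate → mediate → write report tables.

    With ``out_dir`` set, writes the estimate/sensitivity/replication/
    mediation tables, per-SNP selection logs, and a JSON run-metadata file;
    on failure, partial outputs are preserved next to a FAILED marker.
    """
    metadata: dict = {"config": asdict(cfg), "n_exposures": len(exposures)}
    try:
        metadata["outcome"] = outcome.trait_id
        screen = run_screen(exposures, outcome, ld, cfg)
        metadata["n_skipped"] = len(screen.skip_log)
        metadata["n_hits"] = len(screen.hits)
        metadata["hits"] = screen.hits

        replication = None
        if replication_outcomes:
            ivw_rows = screen.table[screen.table["method"].str.startswith("IVW")]
            disc = dict(zip(ivw_rows["exposure"], ivw_rows["beta"]))
            replication = run_replication(screen.hits, exposures,
                                          replication_outcomes, ld, cfg, disc)

        mediation_results: list[MediationResult] = []
        mediation_skips = None
        if mediators:
            ivw_rows = screen.table[screen.table["method"].str.startswith("IVW")]
            exp_out = {}
            for exp_id in screen.hits:
                row = ivw_rows[ivw_rows["exposure"] == exp_id].iloc[0]
                iset = screen.instrument_sets[exp_id]
                exp_out[exp_id] = ivw(iset, model=cfg.ivw_model)
            mediation_results, mediation_skips = run_mediation(
                screen.hits, exposures, mediators, outcome, ld, cfg, exp_out)
        else:
            metadata["mediation"] = "skipped: no mediators configured"

        bundle = StudyBundle(screen=screen, replication=replication,
                             mediation=mediation_results,
                             mediation_skips=mediation_skips, metadata=metadata)
        if out_dir is not None:
            _write_bundle(bundle, Path(out_dir))
        return bundle
    except Exception:
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "FAILED").write_text("run failed; partial outputs preserved\n")
            report_mod.write_run_metadata(out, metadata)
        raise


def _write_bundle(bundle: StudyBundle, out_dir: Path) -> None:
    screen = bundle.screen
    sens_frame = report_mod.sensitivity_frame(list(screen.sensitivity.values()))
    med_frame = report_mod.mediation_frame(bundle.mediation)
    logs = []
    for exp_id, log in sorted(screen.selection_logs.items()):
        log = log.copy()
        log.insert(0, "exposure", exp_id)
        logs.append(log)
    selection = (pd.concat(logs, ignore_index=True) if logs
                 else pd.DataFrame(columns=["exposure", "rsid", "status", "detail"]))
    report_mod.write_report_tables(
        out_dir,
        estimates=screen.table,
        sensitivity=sens_frame,
        replication=bundle.replication,
        mediation=med_frame,
        selection_log=selection,
    )
    screen.skip_log.to_csv(out_dir / "skip_log.tsv", sep="\t", index=False,
                           lineterminator="\n")
    bundle.metadata["strength"] = bundle.screen.strength
    report_mod.write_run_metadata(out_dir, bundle.metadata)
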
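"""Deterministic, byte-stable result tables and run metadata.

All tables are tab-delimited with a fixed column order, %.6g float format,
and a fixed row sort (trait, then method), so re-running an identical
configuration reproduces identical bytes.  The tables are the tabular twin
of the study's forest/circular figures: estimates, sensitivity diagnostics,
replication status, and mediation decompositions.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .estimators import MREstimate
from .mediation import MediationResult
from .sensitivity import SensitivityReport

__all__ = [
    "estimates_frame",
    "sensitivity_frame",
    "mediation_frame",
    "write_report_tables",
    "write_run_metadata",
]

ESTIMATE_COLUMNS = ["exposure", "outcome", "method", "n_snp", "beta", "se",
                    "or", "or_lci95", "or_uci95", "pval"]
SENSITIVITY_COLUMNS = ["exposure", "outcome", "q_stat", "q_df", "q_pval",
                       "egger_intercept", "egger_intercept_se", "egger_intercept_pval",
                       "presso_global_rss", "presso_global_pval", "presso_n_outliers",
                       "presso_outlier_rsids", "presso_distortion_pval",
                       "presso_corrected_beta", "presso_corrected_se"]
MEDIATION_COLUMNS = ["exposure", "mediator", "outcome", "beta1", "beta2", "beta3",
                     "indirect", "proportion", "prop_lci95", "prop_uci95",
                     "prop_pval", "n_boot", "outside_unit_interval"]


def estimates_frame(rows: list[tuple[str, str, MREstimate]]) -> pd.DataFrame:
    """(exposure, outcome, estimate) triples to the canonical estimate table."""
    recs = [
        {
            "exposure": exp, "outcome": out, "method": e.method, "n_snp": e.n_snp,
            "beta": e.beta, "se": e.se, "or": e.or_,
            "or_lci95": e.or_ci_low, "or_uci95": e.or_ci_high, "pval": e.pval,
        }
        for exp, out, e in rows
    ]
    df = pd.DataFrame(recs, columns=ESTIMATE_COLUMNS)
    return df.sort_values(["exposure", "outcome", "method"], kind="mergesort").reset_index(drop=True)


def sensitivity_frame(reports: list[SensitivityReport]) -> pd.DataFrame:
    recs = []
    for r in reports:
        p = r.presso
        recs.append({
            "exposure": r.exposure_id, "outcome": r.outcome_id,
            "q_stat": r.q_stat, "q_df": r.q_df, "q_pval": r.q_pval,
            "egger_intercept": r.egger_intercept,
            "egger_intercept_se": r.egger_intercept_se,
            "egger_intercept_pval": r.egger_intercept_pval,
            "presso_global_rss": p.global_rss_obs if p else float("nan"),
            "presso_global_pval": p.global_pval if p else float("nan"),
            "presso_n_outliers": len(p.outlier_rsids) if p else 0,
            "presso_outlier_rsids": ";".join(p.outlier_rsids) if p else "",
            "presso_distortion_pval": (p.distortion_pval if p and p.distortion_pval is not None
                                       else float("nan")),
            "presso_corrected_beta": (p.corrected_estimate.beta
                                      if p and p.corrected_estimate else float("nan")),
            "presso_corrected_se": (p.corrected_estimate.se
                                    if p and p.corrected_estimate else float("nan")),
        })
    df = pd.DataFrame(recs, columns=SENSITIVITY_COLUMNS)
    return df.sort_values(["exposure", "outcome"], kind="mergesort").reset_index(drop=True)


def mediation_frame(results: list[MediationResult]) -> pd.DataFrame:
    recs = [
        {
            "exposure": m.exposure_id, "mediator": m.mediator_id, "outcome": m.outcome_id,
            "beta1": m.beta1, "beta2": m.beta2, "beta3": m.beta3,
            "indirect": m.indirect, "proportion": m.proportion,
            "prop_lci95": m.prop_ci_low, "prop_uci95": m.prop_ci_high,
            "prop_pval": m.prop_pval, "n_boot": m.n_boot,
            "outside_unit_interval": m.outside_unit_interval,
        }
        for m in results
    ]
    df = pd.DataFrame(recs, columns=MEDIATION_COLUMNS)
    return df.sort_values(["exposure", "mediator"], kind="mergesort").reset_index(drop=True)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def write_report_tables(
    out_dir: str | Path,
    estimates: pd.DataFrame | None = None,
    sensitivity: pd.DataFrame | None = None,
    replication: pd.DataFrame | None = None,
    mediation: pd.DataFrame | None = None,
    selection_log: pd.DataFrame | None = None,
) -> list[Path]:
    """Write whichever result tables are present; header-only when empty.

    Returns the list of written paths.  Unwritable locations raise.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    table_map = {
        "estimates.tsv": (estimates, ESTIMATE_COLUMNS),
        "sensitivity.tsv": (sensitivity, SENSITIVITY_COLUMNS),
        "replication.tsv": (replication, None),
        "mediation.tsv": (mediation, MEDIATION_COLUMNS),
        "selection_log.tsv": (selection_log, None),
    }
    for name, (df, cols) in table_map.items():
        if df is None:
            continue
        if df.empty and cols is not None:
            df = pd.DataFrame(columns=cols)
        path = out_dir / name
        _write(df, path)
        written.append(path)
    return written


def write_run_metadata(out_dir: str | Path, metadata: dict) -> Path:
    """JSON run metadata (thresholds, seeds, counts), sorted keys."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_metadata.json"
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
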
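"""GWAS summary-statistics containers, validation, and delimited-text I/O.

The canonical in-memory representation of one trait's summary statistics is a
:class:`SummaryStatsTable`, a thin wrapper around a pandas DataFrame with one
row per SNP and a fixed column set.  Per-variant access yields
:class:`VariantAssociation` records.  Linkage-disequilibrium information is
consumed precomputed, as a symmetric pairwise r-squared lookup
(:class:`LDReference`); this package never computes LD from genotypes.

Effect sizes are additive per copy of the effect allele: standard-deviation
units for quantitative traits (microbiome feature abundances, protein levels,
BUN/eGFR) and log odds ratios for binary traits (CKD case/control status).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANONICAL_COLUMNS",
    "VariantAssociation",
    "ValidationReport",
    "SummaryStatsTable",
    "LDReference",
    "read_sumstats",
    "validate_sumstats",
]

#: Canonical column order for summary-statistics frames.
CANONICAL_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Relative tolerance for the beta/se vs p-value consistency check (warning only).
_CONSISTENCY_RTOL = 0.10


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record for one trait.

    ``beta`` is per effect-allele copy; ``eaf`` is the effect-allele
    frequency; ``pos`` is 1-based.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float


@dataclass
class ValidationReport:
    """Outcome of row-level validation of a summary-statistics frame."""

    n_input: int = 0
    n_retained: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _complement_allele(a: str) -> str:
    return _COMPLEMENT[a]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G variants, whose strand is ambiguous from alleles."""
    return _COMPLEMENT.get(effect_allele) == other_allele


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Apply row-level invariants; return (clean frame, report).

    Rejected rows (with reasons keyed by rsid) are counted in the report.
    A beta/se vs p mismatch beyond 10% relative difference under the
    two-sided normal approximation is a warning, never a rejection.
    """
    report = ValidationReport(n_input=len(df))
    df = df.copy()

    numeric_cols = ["pos", "eaf", "beta", "se", "pval", "n"]
    for col in numeric_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("rsid", "chrom", "effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()

    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        newly = mask & (reasons == "")
        reasons[newly] = reason

    flag(df[numeric_cols].isna().any(axis=1), "unparsable or missing numeric field")
    flag(~df["effect_allele"].isin(_VALID_BASES), "effect allele not a single base")
    flag(~df["other_allele"].isin(_VALID_BASES), "other allele not a single base")
    flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    flag(~((df["eaf"] > 0) & (df["eaf"] < 1)), "eaf outside (0,1)")
    flag(~(df["se"] > 0), "non-positive se")
    flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval outside (0,1]")
    flag(~(df["n"] >= 2), "sample size below 2")
    flag(~(df["pos"] > 0), "non-positive position")

    rejected = reasons != ""
    for rsid, reason in zip(df.loc[rejected, "rsid"], reasons[rejected]):
        report.rejections.append((str(rsid), reason))

    clean = df.loc[~rejected].copy()
    clean["pos"] = clean["pos"].astype(np.int64)

    # Consistency warning: |beta/se| should match the p-value within 10 %
    # under a two-sided normal approximation.  Compared on the p scale.
    if len(clean):
        z = np.abs(clean["beta"] / clean["se"])
        p_implied = 2.0 * stats.norm.sf(z)
        p_obs = clean["pval"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p_implied > 0, p_obs / p_implied, np.inf)
        bad = (ratio > 1 + _CONSISTENCY_RTOL) | (ratio < 1 / (1 + _CONSISTENCY_RTOL))
        for rsid, pi, po in zip(clean.loc[bad, "rsid"], p_implied[bad], p_obs[bad]):
            report.warnings.append(
                (str(rsid), f"pval {po:.3g} inconsistent with |beta/se| (implies {pi:.3g})")
            )

    # Duplicate rsids: keep the first occurrence.
    dup = clean["rsid"].duplicated(keep="first")
    for rsid in clean.loc[dup, "rsid"]:
        report.rejections.append((str(rsid), "duplicate rsid"))
    clean = clean.loc[~dup]

    report.n_retained = len(clean)
    return clean.reset_index(drop=True), report


class SummaryStatsTable:
    """Validated summary statistics for one trait.

    Parameters
    ----------
    trait_id : str
        Identifier of the trait (e.g. a microbiome feature or protein name).
    trait_type : {"quantitative", "binary"}
        Scale of ``beta``: SD units or log odds ratio.
    df : pandas.DataFrame
        Frame with the canonical columns.  Validated unless
        ``validated=True``.
    n_cases, n_controls : int, optional
        Required for binary traits; the per-row ``n`` defaults to their sum.
    """

    def __init__(
        self,
        trait_id: str,
        trait_type: str,
        df: pd.DataFrame,
        n_cases: int | None = None,
        n_controls: int | None = None,
        validated: bool = False,
        validation: ValidationReport | None = None,
    ):
        if trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {trait_type!r}")
        if trait_type == "binary":
            if n_cases is None or n_controls is None:
                raise ValueError("binary traits require n_cases and n_controls")
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        df = df[CANONICAL_COLUMNS].copy()
        if trait_type == "binary":
            df["n"] = df["n"].fillna(float(n_cases + n_controls))
        if validated:
            self.validation = validation or ValidationReport(
                n_input=len(df), n_retained=len(df)
            )
        else:
            df, self.validation = validate_sumstats(df)
        self.trait_id = trait_id
        self.trait_type = trait_type
        self.n_cases = n_cases
        self.n_controls = n_controls
        self.df = df.reset_index(drop=True)
        self._index: Mapping[str, int] = {
            rsid: i for i, rsid in enumerate(self.df["rsid"])
        }

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    @property
    def rsids(self) -> list[str]:
        return list(self.df["rsid"])

    def get(self, rsid: str) -> VariantAssociation:
        row = self.df.iloc[self._index[rsid]]
        return VariantAssociation(
            rsid=row["rsid"],
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            n=float(row["n"]),
        )

    @property
    def records(self) -> Iterable[VariantAssociation]:
        for rsid in self.df["rsid"]:
            yield self.get(rsid)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        """Write the canonical table, byte-stable (%.6g floats, fixed order)."""
        self.df.to_csv(path, sep=sep, index=False, float_format="%.6g",
                       lineterminator="\n")


def read_sumstats(
    path: str | Path,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    column_map: Mapping[str, str] | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
    sep: str | None = None,
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical names to the file's column names
    (e.g. ``{"effect_allele": "A1", "pval": "p"}``); unmapped canonical names
    are looked up verbatim.  A required column that cannot be resolved is a
    hard error naming the column; rows failing invariants are dropped and
    counted in ``table.validation``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    column_map = dict(column_map or {})
    rename: dict[str, str] = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in df.columns:
            if canon == "n" and trait_type == "binary" and n_cases and n_controls:
                df[canon] = float(n_cases + n_controls)
                continue
            raise ValueError(
                f"required column {canon!r} (file column {src!r}) not found in {path}"
            )
        rename[src] = canon
    df = df.rename(columns=rename)
    return SummaryStatsTable(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        df=df,
        n_cases=n_cases,
        n_controls=n_controls,
    )


class LDReference:
    """Symmetric pairwise r-squared lookup between variants.

    A pair absent from the table is treated as unlinked (r² = 0); the
    diagonal is always 1.  Values come precomputed from a reference panel.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0,1], got {r2}")
        if a != b:
            self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def partners(self, rsid: str) -> dict[str, float]:
        """All variants with a recorded (non-zero-by-default) r² to ``rsid``."""
        out: dict[str, float] = {}
        for (a, b), r2 in self._r2.items():
            if a == rsid:
                out[b] = r2
            elif b == rsid:
                out[a] = r2
        return out

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LDReference":
        required = {"rsid_a", "rsid_b", "r2"}
        if not required.issubset(df.columns):
            raise ValueError(f"LD table needs columns {sorted(required)}")
        ref = cls()
        for a, b, r2 in zip(df["rsid_a"], df["rsid_b"], df["r2"]):
            ref.add(str(a), str(b), float(r2))
        return ref

    @classmethod
    def from_file(cls, path: str | Path, sep: str | None = None) -> "LDReference":
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
        return cls.from_dataframe(df)

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted((a, b, r2) for (a, b), r2 in self._r2.items())
        return pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"])

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False,
                                   float_format="%.6g", lineterminator="\n")
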
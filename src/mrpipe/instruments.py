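"""Instrument selection, LD clumping, proxy search, harmonization, strength.

An instrument is a SNP associated with the exposure below a locus-wide
p-value threshold (1e-5 by default, the convention for microbiome GWAS with
modest sample sizes), common enough to be reliable (minor-allele frequency
above 1 %), and LD-pruned so no retained pair has r² ≥ 0.1 within ±1000 kb.
Instrument strength is summarised by the per-SNP variance explained

    R² = 2β²f(1−f) / (2β²f(1−f) + 2·N·SE²·f(1−f))

and the F-statistic F = (N−2)·R²/(1−R²); F > 10 is the conventional bar for
low weak-instrument bias.

Harmonization aligns each exposure SNP with the outcome table so both effects
refer to the same allele: swapped allele order negates the outcome beta and
complements its frequency; strand flips are resolved by complementing
alleles; palindromic (A/T, C/G) SNPs are dropped when their frequency is too
close to 0.5 to resolve strand, or always under strict mode.  When an index
SNP is missing from the outcome, the instrument can be replaced by its best
LD proxy (r² > 0.8) present in both tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import (
    LDReference,
    SummaryStatsTable,
    _COMPLEMENT,
    is_palindromic,
)

__all__ = [
    "HarmonizedInstrument",
    "InstrumentSet",
    "select_instruments",
    "ld_clump",
    "find_proxy",
    "harmonize",
    "variance_explained",
    "f_statistic",
    "strength_summary",
]

#: min(eaf, 1-eaf) window within which a palindromic SNP's strand is ambiguous.
PALINDROME_AMBIGUOUS_BAND = (0.42, 0.50)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome-aligned SNP with strength statistics."""

    rsid: str
    beta_exp: float
    se_exp: float
    eaf_exp: float
    pval_exp: float
    n_exp: float
    beta_out: float
    se_out: float
    eaf_out: float
    f_stat: float
    r2_explained: float
    flipped: bool = False
    proxy_of: str | None = None


@dataclass
class InstrumentSet:
    """Ordered harmonized instruments for one exposure/outcome pair.

    ``selection_log`` records one disposition per candidate SNP:
    kept / removed-by-clump / palindromic-excluded / proxied /
    absent-in-outcome / irreconcilable-alleles.
    """

    exposure_id: str
    outcome_id: str
    snps: list[HarmonizedInstrument] = field(default_factory=list)
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snps)

    def _arr(self, attr: str) -> np.ndarray:
        return np.array([getattr(s, attr) for s in self.snps], dtype=float)

    @property
    def beta_exp(self) -> np.ndarray:
        return self._arr("beta_exp")

    @property
    def se_exp(self) -> np.ndarray:
        return self._arr("se_exp")

    @property
    def beta_out(self) -> np.ndarray:
        return self._arr("beta_out")

    @property
    def se_out(self) -> np.ndarray:
        return self._arr("se_out")

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def subset(self, keep: list[str]) -> "InstrumentSet":
        keep_set = set(keep)
        return InstrumentSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            snps=[s for s in self.snps if s.rsid in keep_set],
            selection_log=list(self.selection_log),
        )

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.selection_log, columns=["rsid", "status", "detail"])

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        exposure_id: str = "exposure",
        outcome_id: str = "outcome",
        eaf_exp=None,
        n_exp: float = 1539.0,
        rsids=None,
    ) -> "InstrumentSet":
        """Build a set directly from effect arrays (simulation / testing path)."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        se_exp = np.asarray(se_exp, dtype=float)
        beta_out = np.asarray(beta_out, dtype=float)
        se_out = np.asarray(se_out, dtype=float)
        J = beta_exp.size
        if eaf_exp is None:
            eaf_exp = np.full(J, 0.5)
        eaf_exp = np.asarray(eaf_exp, dtype=float)
        if rsids is None:
            rsids = [f"rs{j + 1}" for j in range(J)]
        snps = []
        for j in range(J):
            r2 = variance_explained(beta_exp[j], se_exp[j], eaf_exp[j], n_exp)
            snps.append(
                HarmonizedInstrument(
                    rsid=rsids[j],
                    beta_exp=float(beta_exp[j]),
                    se_exp=float(se_exp[j]),
                    eaf_exp=float(eaf_exp[j]),
                    pval_exp=np.nan,
                    n_exp=float(n_exp),
                    beta_out=float(beta_out[j]),
                    se_out=float(se_out[j]),
                    eaf_out=float(eaf_exp[j]),
                    f_stat=f_statistic(r2, n_exp),
                    r2_explained=r2,
                )
            )
        return cls(exposure_id, outcome_id, snps)


def variance_explained(beta: float, se: float, eaf: float, n: float) -> float:
    """Per-SNP proportion of exposure variance explained.

    R² = 2β²f(1−f) / (2β²f(1−f) + 2·N·SE²·f(1−f)); the 2f(1−f) factor cancels
    but is kept explicit to mirror the estimating equation.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not (0.0 < eaf < 1.0):
        raise ValueError("eaf must be in (0,1)")
    num = 2.0 * beta * beta * eaf * (1.0 - eaf)
    den = num + 2.0 * n * se * se * eaf * (1.0 - eaf)
    return num / den


def f_statistic(r2: float, n: float) -> float:
    """Instrument-strength F = (N−2)·R²/(1−R²)."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0,1)")
    if n <= 2:
        raise ValueError("n must exceed 2")
    return (n - 2.0) * r2 / (1.0 - r2)


def select_instruments(
    exposure: SummaryStatsTable,
    p_threshold: float = 1e-5,
    eaf_min: float = 0.01,
    minor_allele_sense: bool = True,
) -> pd.DataFrame:
    """Candidate instruments: p < threshold and common-enough allele.

    The frequency filter defaults to the minor-allele sense
    min(eaf, 1−eaf) > eaf_min; set ``minor_allele_sense=False`` for the
    literal effect-allele reading.  Result is sorted by ascending p, rsid as
    tiebreak.  An empty result is returned (not raised) so the caller can
    skip the exposure.
    """
    df = exposure.df
    mask = df["pval"] < p_threshold
    if minor_allele_sense:
        mask &= np.minimum(df["eaf"], 1.0 - df["eaf"]) > eaf_min
    else:
        mask &= df["eaf"] > eaf_min
    out = df.loc[mask].sort_values(["pval", "rsid"], kind="mergesort")
    return out.reset_index(drop=True)


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDReference,
    r2_max: float = 0.1,
    window_kb: float = 1000.0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Greedy LD clumping: smallest-p index SNP first.

    Repeatedly take the remaining SNP with the smallest p-value, then remove
    every remaining SNP with r² ≥ ``r2_max`` within ±``window_kb`` on the same
    chromosome.  Cross-chromosome or out-of-window pairs are always unlinked,
    as are pairs missing from the LD table.  Returns (index SNPs in original
    candidate order, list of (removed rsid, index rsid)).
    """
    df = candidates.sort_values(["pval", "rsid"], kind="mergesort").reset_index(drop=True)
    window_bp = window_kb * 1000.0
    alive = np.ones(len(df), dtype=bool)
    kept: list[int] = []
    removed: list[tuple[str, str]] = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept.append(i)
        row = df.iloc[i]
        for j in range(i + 1, len(df)):
            if not alive[j]:
                continue
            other = df.iloc[j]
            if str(other["chrom"]) != str(row["chrom"]):
                continue
            if abs(float(other["pos"]) - float(row["pos"])) > window_bp:
                continue
            if ld.r2(row["rsid"], other["rsid"]) >= r2_max:
                alive[j] = False
                removed.append((other["rsid"], row["rsid"]))
    kept_df = df.iloc[kept].reset_index(drop=True)
    return kept_df, removed


def find_proxy(
    rsid: str,
    outcome: SummaryStatsTable,
    ld: LDReference,
    r2_min: float = 0.8,
    exposure: SummaryStatsTable | None = None,
) -> str | None:
    """Best outcome-present proxy with r² > ``r2_min`` to ``rsid``.

    Ties on r² are broken by the smaller exposure p-value (when an exposure
    table is supplied), then lexicographic rsid.  Returns None when no
    partner clears the threshold.
    """
    best: tuple[float, float, str] | None = None
    for partner, r2 in ld.partners(rsid).items():
        if r2 <= r2_min or partner not in outcome:
            continue
        if exposure is not None and partner in exposure:
            p_exp = exposure.get(partner).pval
        else:
            p_exp = np.inf
        key = (-r2, p_exp, partner)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def _align(exp_rec, out_rec):
    """Align one outcome record to the exposure's allele orientation.

    Returns (beta_out, eaf_out, flipped) or None when allele sets cannot be
    reconciled even after a strand flip.  Palindromic SNPs are handled by the
    caller (allele matching alone cannot orient them).
    """
    ea_x, oa_x = exp_rec.effect_allele, exp_rec.other_allele
    ea_y, oa_y = out_rec.effect_allele, out_rec.other_allele
    for ea, oa in ((ea_y, oa_y), (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y])):
        if (ea, oa) == (ea_x, oa_x):
            return out_rec.beta, out_rec.eaf, False
        if (ea, oa) == (oa_x, ea_x):
            return -out_rec.beta, 1.0 - out_rec.eaf, True
    return None


def harmonize(
    exposure_snps: pd.DataFrame,
    outcome: SummaryStatsTable,
    exposure: SummaryStatsTable | None = None,
    ld: LDReference | None = None,
    proxy_r2: float = 0.8,
    palindrome_mode: str = "exclude-ambiguous",
    exposure_id: str | None = None,
) -> InstrumentSet:
    """Align candidate exposure SNPs with the outcome table.

    ``exposure_snps`` is a canonical-column frame (typically the output of
    :func:`ld_clump`).  When ``ld`` is given, SNPs absent from the outcome are
    replaced wholesale by their best proxy (r² > ``proxy_r2``): the proxy's
    own exposure and outcome records are used, flagged with ``proxy_of`` —
    cross-variant allele alignment is not possible from summary data, so the
    proxy must also be present in the exposure table.

    ``palindrome_mode``:

    - ``"exclude-ambiguous"`` (default): drop palindromic SNPs whose
      min(eaf, 1−eaf) falls in [0.42, 0.50] in either dataset; orient the
      rest by frequency agreement.
    - ``"strict"``: drop all palindromic SNPs.
    """
    if palindrome_mode not in ("exclude-ambiguous", "strict"):
        raise ValueError(f"unknown palindrome_mode {palindrome_mode!r}")
    exposure_id = exposure_id or (exposure.trait_id if exposure is not None else "exposure")
    iset = InstrumentSet(exposure_id=exposure_id, outcome_id=outcome.trait_id)
    lo, hi = PALINDROME_AMBIGUOUS_BAND

    for _, row in exposure_snps.iterrows():
        rsid = row["rsid"]
        exp_rec = _row_to_record(row)
        proxy_of = None
        if rsid not in outcome:
            if ld is not None:
                proxy = find_proxy(rsid, outcome, ld, r2_min=proxy_r2, exposure=exposure)
            else:
                proxy = None
            if proxy is None or exposure is None or proxy not in exposure:
                iset.selection_log.append((rsid, "absent-in-outcome", "no proxy found"))
                continue
            iset.selection_log.append((rsid, "proxied", f"replaced by {proxy}"))
            proxy_of = rsid
            exp_rec = exposure.get(proxy)
            rsid = proxy
        out_rec = outcome.get(rsid)

        if is_palindromic(exp_rec.effect_allele, exp_rec.other_allele):
            if palindrome_mode == "strict":
                iset.selection_log.append((rsid, "palindromic-excluded", "strict mode"))
                continue
            maf_x = min(exp_rec.eaf, 1.0 - exp_rec.eaf)
            maf_y = min(out_rec.eaf, 1.0 - out_rec.eaf)
            if lo <= maf_x <= hi or lo <= maf_y <= hi:
                iset.selection_log.append(
                    (rsid, "palindromic-excluded",
                     f"ambiguous frequency (maf exp {maf_x:.3f}, out {maf_y:.3f})")
                )
                continue
            # Nominal alignment by allele label, then frequency-based strand check.
            if out_rec.effect_allele == exp_rec.effect_allele:
                beta_out, eaf_out, flipped = out_rec.beta, out_rec.eaf, False
            else:
                beta_out, eaf_out, flipped = -out_rec.beta, 1.0 - out_rec.eaf, True
            if (exp_rec.eaf < 0.5) != (eaf_out < 0.5):
                beta_out, eaf_out, flipped = -beta_out, 1.0 - eaf_out, not flipped
        else:
            aligned = _align(exp_rec, out_rec)
            if aligned is None:
                iset.selection_log.append(
                    (rsid, "irreconcilable-alleles",
                     f"{exp_rec.effect_allele}/{exp_rec.other_allele} vs "
                     f"{out_rec.effect_allele}/{out_rec.other_allele}")
                )
                continue
            beta_out, eaf_out, flipped = aligned

        r2 = variance_explained(exp_rec.beta, exp_rec.se, exp_rec.eaf, exp_rec.n)
        iset.snps.append(
            HarmonizedInstrument(
                rsid=rsid,
                beta_exp=exp_rec.beta,
                se_exp=exp_rec.se,
                eaf_exp=exp_rec.eaf,
                pval_exp=exp_rec.pval,
                n_exp=exp_rec.n,
                beta_out=beta_out,
                se_out=out_rec.se,
                eaf_out=eaf_out,
                f_stat=f_statistic(r2, exp_rec.n),
                r2_explained=r2,
                flipped=flipped,
                proxy_of=proxy_of,
            )
        )
        if proxy_of is None:
            iset.selection_log.append((rsid, "kept", ""))
    return iset


def _row_to_record(row):
    from .sumstats import VariantAssociation

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


def strength_summary(instruments: InstrumentSet) -> dict:
    """Min/median F, total R², count, and a weak-instrument flag (min F < 10)."""
    if len(instruments) == 0:
        raise ValueError("strength_summary requires a non-empty instrument set")
    f = np.array([s.f_stat for s in instruments.snps])
    r2 = np.array([s.r2_explained for s in instruments.snps])
    return {
        "n_snp": len(instruments),
        "f_min": float(f.min()),
        "f_median": float(np.median(f)),
        "r2_total": float(r2.sum()),
        "weak_instrument_flag": bool(f.min() < 10.0),
    }
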
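import numpy as np
import pandas as pd
import pytest

from mrpipe import InstrumentSet, SummaryStatsTable
from mrpipe.sumstats import CANONICAL_COLUMNS


def make_frame(rows):
    """Rows of (rsid, chrom, pos, ea, oa, eaf, beta, se, pval, n)."""
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def consistent_row(rsid, chrom, pos, ea, oa, eaf, beta, se, n=1539):
    """A row whose p-value matches |beta/se| (avoids validation warnings)."""
    from scipy import stats

    p = float(np.clip(2 * stats.norm.sf(abs(beta / se)), np.nextafter(0, 1), 1.0))
    return (rsid, chrom, pos, ea, oa, eaf, beta, se, p, n)


@pytest.fixture
def small_exposure():
    rows = [
        consistent_row("rs1", "1", 1_000_000, "A", "G", 0.30, 0.20, 0.036),
        consistent_row("rs2", "1", 1_500_000, "C", "T", 0.40, -0.19, 0.037),
        consistent_row("rs3", "2", 5_000_000, "G", "A", 0.25, 0.22, 0.040),
        consistent_row("rs4", "3", 9_000_000, "T", "C", 0.10, 0.28, 0.060),
        consistent_row("rs5", "4", 2_000_000, "A", "C", 0.50, 0.18, 0.036),
    ]
    return SummaryStatsTable("exposure", "quantitative", make_frame(rows))


@pytest.fixture
def worked_instruments():
    """The 3-instrument hand-checkable set: ratios 0.2, 0.25, 0.2."""
    return InstrumentSet.from_arrays(
        beta_exp=[0.1, 0.2, 0.15],
        se_exp=[0.02, 0.02, 0.02],
        beta_out=[0.02, 0.05, 0.03],
        se_out=[0.01, 0.02, 0.015],
    )


@pytest.fixture
def consensus_instruments():
    """Five instruments with an identical Wald ratio of 0.2."""
    bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
    return InstrumentSet.from_arrays(
        beta_exp=bx, se_exp=np.full(5, 0.02),
        beta_out=0.2 * bx, se_out=np.array([0.01, 0.012, 0.02, 0.015, 0.011]),
    )
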
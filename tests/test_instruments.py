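import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrpipe import (
    LDReference,
    SummaryStatsTable,
    f_statistic,
    find_proxy,
    harmonize,
    ld_clump,
    select_instruments,
    strength_summary,
    variance_explained,
)
from mrpipe.instruments import InstrumentSet

from conftest import consistent_row, make_frame


def _table(rows, trait="exposure", trait_type="quantitative", **kw):
    return SummaryStatsTable(trait, trait_type, make_frame(rows), **kw)


class TestSelect:
    def test_p_threshold_is_strict(self):
        rows = [
            ("rs1", "1", 1000, "A", "G", 0.3, 0.2, 0.041, 1e-6, 1539),
            ("rs2", "1", 2000, "C", "T", 0.3, 0.2, 0.047, 2e-5, 1539),
            ("rs3", "2", 3000, "G", "A", 0.3, 0.2, 0.035, 1e-8, 1539),
        ]
        out = select_instruments(_table(rows), p_threshold=1e-5)
        assert list(out["rsid"]) == ["rs3", "rs1"]  # ascending p

    def test_rare_variant_excluded_minor_allele_sense(self):
        rows = [
            ("rs1", "1", 1000, "A", "G", 0.005, 0.5, 0.08, 1e-9, 1539),
            ("rs2", "1", 2000, "C", "T", 0.995, 0.5, 0.08, 1e-9, 1539),
            ("rs3", "1", 3000, "G", "A", 0.30, 0.2, 0.033, 1e-9, 1539),
        ]
        out = select_instruments(_table(rows))
        assert list(out["rsid"]) == ["rs3"]
        # literal effect-allele reading keeps the 0.995-frequency variant
        literal = select_instruments(_table(rows), minor_allele_sense=False)
        assert set(literal["rsid"]) == {"rs2", "rs3"}

    def test_empty_table_gives_empty_list(self):
        out = select_instruments(_table([]))
        assert out.empty


def _cand(rsid, chrom, pos, p):
    return (rsid, chrom, pos, "A", "G", 0.3, 0.2, 0.04, p, 1539)


class TestClump:
    def test_unlinked_candidates_all_retained(self):
        df = make_frame([_cand(f"rs{i}", "1", 10_000 * i, 1e-6) for i in range(5)])
        kept, removed = ld_clump(df, LDReference())
        assert len(kept) == 5 and not removed

    def test_linked_pair_keeps_smaller_p(self):
        df = make_frame([_cand("rs1", "1", 1_000_000, 1e-8),
                         _cand("rs2", "1", 1_500_000, 1e-6)])
        ld = LDReference({("rs1", "rs2"): 0.5})
        kept, removed = ld_clump(df, ld)
        assert list(kept["rsid"]) == ["rs1"]
        assert removed == [("rs2", "rs1")]

    def test_linked_pair_beyond_window_unaffected(self):
        df = make_frame([_cand("rs1", "1", 1_000_000, 1e-8),
                         _cand("rs2", "1", 3_000_000, 1e-6)])
        ld = LDReference({("rs1", "rs2"): 0.95})
        kept, _ = ld_clump(df, ld)
        assert len(kept) == 2

    def test_cross_chromosome_always_unlinked(self):
        df = make_frame([_cand("rs1", "1", 1_000_000, 1e-8),
                         _cand("rs2", "2", 1_000_100, 1e-6)])
        ld = LDReference({("rs1", "rs2"): 0.99})
        kept, _ = ld_clump(df, ld)
        assert len(kept) == 2

    def test_four_snp_greedy_enumeration(self):
        # the p=1e-9 index removes only its linked p=1e-8 partner
        df = make_frame([
            _cand("rsA", "1", 1_000_000, 1e-9),
            _cand("rsB", "1", 1_100_000, 1e-7),
            _cand("rsC", "1", 1_200_000, 1e-6),
            _cand("rsD", "1", 1_300_000, 1e-8),
        ])
        ld = LDReference({("rsA", "rsD"): 0.5})
        kept, removed = ld_clump(df, ld)
        assert set(kept["rsid"]) == {"rsA", "rsB", "rsC"}
        assert removed == [("rsD", "rsA")]

    def test_input_order_invariance(self):
        df = make_frame([_cand(f"rs{i}", "1", 50_000 * i, p)
                         for i, p in enumerate([3e-6, 1e-7, 5e-8, 2e-6, 9e-7])])
        ld = LDReference({("rs0", "rs1"): 0.3, ("rs2", "rs3"): 0.4,
                          ("rs1", "rs4"): 0.15})
        base = set(ld_clump(df, ld)[0]["rsid"])
        shuffled = df.sample(frac=1.0, random_state=3)
        assert set(ld_clump(shuffled, ld)[0]["rsid"]) == base

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.data())
    def test_greedy_result_is_a_maximal_valid_subset(self, data):
        """Brute-force oracle: every retained pair within the window has
        r2 below threshold, and no excluded SNP could be added back."""
        n = data.draw(st.integers(3, 7))
        pvals = data.draw(st.lists(
            st.floats(1e-12, 1e-6), min_size=n, max_size=n, unique=True))
        pos = data.draw(st.lists(
            st.integers(0, 3_000_000), min_size=n, max_size=n, unique=True))
        df = make_frame([_cand(f"rs{i}", "1", pos[i], pvals[i]) for i in range(n)])
        ld = LDReference()
        for i, j in itertools.combinations(range(n), 2):
            r2 = data.draw(st.sampled_from([0.0, 0.05, 0.3, 0.9]))
            if r2:
                ld.add(f"rs{i}", f"rs{j}", r2)

        kept = set(ld_clump(df, ld, r2_max=0.1, window_kb=1000)[0]["rsid"])

        def linked(a, b):
            pa = pos[int(a[2:])]
            pb = pos[int(b[2:])]
            return abs(pa - pb) <= 1_000_000 and ld.r2(a, b) >= 0.1

        # validity: no retained pair is linked
        for a, b in itertools.combinations(sorted(kept), 2):
            assert not linked(a, b)
        # maximality: every excluded SNP is linked to some retained SNP
        for i in range(n):
            rs = f"rs{i}"
            if rs not in kept:
                assert any(linked(rs, k) for k in kept)


class TestProxy:
    def _outcome(self, rsids):
        rows = [consistent_row(r, "1", 1000 + i, "A", "G", 0.3, 0.01, 0.06)
                for i, r in enumerate(rsids)]
        return _table(rows, trait="ckd")

    def test_highest_r2_above_threshold_wins(self):
        outcome = self._outcome(["rsP1", "rsP2"])
        ld = LDReference({("rsQ", "rsP1"): 0.85, ("rsQ", "rsP2"): 0.92})
        assert find_proxy("rsQ", outcome, ld) == "rsP2"

    def test_below_threshold_returns_none(self):
        outcome = self._outcome(["rsP1"])
        ld = LDReference({("rsQ", "rsP1"): 0.7})
        assert find_proxy("rsQ", outcome, ld) is None

    def test_tie_broken_by_exposure_p_then_rsid(self):
        outcome = self._outcome(["rsP1", "rsP2"])
        ld = LDReference({("rsQ", "rsP1"): 0.9, ("rsQ", "rsP2"): 0.9})
        exposure = _table([
            ("rsP1", "1", 1000, "A", "G", 0.3, 0.2, 0.04, 1e-6, 1539),
            ("rsP2", "1", 2000, "A", "G", 0.3, 0.2, 0.04, 1e-8, 1539),
        ])
        assert find_proxy("rsQ", outcome, ld, exposure=exposure) == "rsP2"
        assert find_proxy("rsQ", outcome, ld) == "rsP1"  # rsid fallback


class TestHarmonize:
    def _exposure_df(self, ea="A", oa="G", eaf=0.3):
        return make_frame([consistent_row("rs1", "1", 1000, ea, oa, eaf, 0.2, 0.04)])

    def _outcome(self, ea, oa, beta=0.05, eaf=0.3):
        return _table([consistent_row("rs1", "1", 1000, ea, oa, eaf, beta, 0.02,
                                      n=76_020)], trait="ckd")

    def test_same_order_unchanged(self):
        iset = harmonize(self._exposure_df(), self._outcome("A", "G"))
        s = iset.snps[0]
        assert s.beta_out == pytest.approx(0.05) and not s.flipped

    def test_swapped_alleles_negate_and_complement(self):
        iset = harmonize(self._exposure_df(), self._outcome("G", "A", eaf=0.7))
        s = iset.snps[0]
        assert s.beta_out == pytest.approx(-0.05)
        assert s.eaf_out == pytest.approx(0.3)
        assert s.flipped

    def test_strand_complement_resolved(self):
        # exposure A/G vs outcome T/C is the same variant on the other strand
        iset = harmonize(self._exposure_df(), self._outcome("T", "C"))
        s = iset.snps[0]
        assert s.beta_out == pytest.approx(0.05) and not s.flipped

    def test_strand_flip_plus_swap_resolved(self):
        # exposure A/G vs outcome C/T: other strand AND swapped order
        iset = harmonize(self._exposure_df(), self._outcome("C", "T", eaf=0.7))
        s = iset.snps[0]
        assert s.beta_out == pytest.approx(-0.05) and s.flipped
        assert s.eaf_out == pytest.approx(0.3)

    def test_irreconcilable_alleles_dropped(self):
        iset = harmonize(self._exposure_df(), self._outcome("A", "C"))
        assert len(iset) == 0
        assert iset.selection_log[0][1] == "irreconcilable-alleles"

    def test_ambiguous_palindrome_excluded(self):
        iset = harmonize(self._exposure_df(ea="A", oa="T", eaf=0.50),
                         self._outcome("A", "T", eaf=0.50))
        assert len(iset) == 0
        assert iset.selection_log[0][1] == "palindromic-excluded"

    def test_resolvable_palindrome_oriented_by_frequency(self):
        # maf 0.2 in both: frequencies disagree in orientation -> flip
        iset = harmonize(self._exposure_df(ea="A", oa="T", eaf=0.2),
                         self._outcome("A", "T", beta=0.05, eaf=0.8))
        s = iset.snps[0]
        assert s.beta_out == pytest.approx(-0.05)
        assert s.eaf_out == pytest.approx(0.2)

    def test_strict_mode_drops_all_palindromes(self):
        iset = harmonize(self._exposure_df(ea="A", oa="T", eaf=0.2),
                         self._outcome("A", "T", eaf=0.2),
                         palindrome_mode="strict")
        assert len(iset) == 0

    def test_absent_without_ld_logged(self):
        outcome = _table([consistent_row("rs9", "1", 5000, "A", "G", 0.3, 0.01, 0.02,
                                         n=76_020)], trait="ckd")
        iset = harmonize(self._exposure_df(), outcome)
        assert len(iset) == 0
        assert iset.selection_log[0][1] == "absent-in-outcome"

    def test_harmonization_is_idempotent(self):
        """Re-harmonizing an already-aligned pair changes nothing."""
        exposure_df = self._exposure_df()
        iset1 = harmonize(exposure_df, self._outcome("G", "A", eaf=0.7))
        s1 = iset1.snps[0]
        aligned_outcome = _table(
            [consistent_row("rs1", "1", 1000, "A", "G", s1.eaf_out, s1.beta_out,
                            s1.se_out, n=76_020)], trait="ckd")
        s2 = harmonize(exposure_df, aligned_outcome).snps[0]
        assert s2.beta_out == pytest.approx(s1.beta_out)
        assert s2.eaf_out == pytest.approx(s1.eaf_out)
        assert not s2.flipped


class TestStrength:
    def test_variance_explained_worked_value(self):
        # direct arithmetic: R2 = b^2 / (b^2 + N se^2) after the 2f(1-f) cancels
        assert variance_explained(0.1, 0.02, 0.5, 1539) == pytest.approx(0.015985, abs=5e-7)

    def test_zero_effect_zero_r2(self):
        assert variance_explained(0.0, 0.02, 0.3, 1539) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(beta=st.floats(0.01, 1.0), se=st.floats(0.005, 0.2),
           eaf=st.floats(0.01, 0.99))
    def test_r2_symmetric_in_eaf(self, beta, se, eaf):
        assert variance_explained(beta, se, eaf, 1539) == pytest.approx(
            variance_explained(beta, se, 1 - eaf, 1539))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(b1=st.floats(0.01, 0.5), b2=st.floats(0.01, 0.5))
    def test_r2_increases_with_abs_beta_and_f_with_r2(self, b1, b2):
        lo, hi = sorted([b1, b2])
        r_lo = variance_explained(lo, 0.03, 0.4, 1539)
        r_hi = variance_explained(hi, 0.03, 0.4, 1539)
        assert r_hi >= r_lo
        assert f_statistic(r_hi, 1539) >= f_statistic(r_lo, 1539)

    def test_f_statistic_worked_value(self):
        assert f_statistic(0.0159846547, 1539) == pytest.approx(24.9675, abs=1e-3)

    def test_f_zero_for_null_instrument(self):
        assert f_statistic(0.0, 1539) == 0.0

    def test_f_requires_valid_domain(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 1539)
        with pytest.raises(ValueError):
            f_statistic(0.1, 2)
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.0, 0.3, 1539)

    def test_strength_summary_flags_weak_sets(self):
        n = 1539

        def set_with_f(fs):
            # invert F -> R2 -> beta at se=0.03, eaf=0.5
            snps = []
            r2 = np.array(fs) / (np.array(fs) + n - 2)
            beta = np.sqrt(r2 * n * 0.03**2 / (1 - r2))
            return InstrumentSet.from_arrays(beta, np.full(len(fs), 0.03),
                                             beta * 0.1, np.full(len(fs), 0.02),
                                             n_exp=n)

        const = strength_summary(set_with_f([21, 21, 21]))
        assert const["f_min"] == pytest.approx(21, rel=1e-6)
        assert const["f_median"] == pytest.approx(21, rel=1e-6)
        assert not const["weak_instrument_flag"]
        weak = strength_summary(set_with_f([9, 30, 40]))
        assert weak["weak_instrument_flag"]
        single = strength_summary(set_with_f([15]))
        assert single["f_min"] == single["f_median"] == pytest.approx(15, rel=1e-6)

    def test_empty_set_is_hard_error(self):
        with pytest.raises(ValueError):
            strength_summary(InstrumentSet("x", "y"))
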
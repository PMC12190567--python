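import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrpipe import InstrumentSet, ivw, mr_egger, wald_ratio, weighted_median
from mrpipe.estimators import weighted_median_arrays
from mrpipe.instruments import HarmonizedInstrument


def _inst(beta_exp, beta_out, se_out, se_exp=0.02):
    return HarmonizedInstrument(
        rsid="rs1", beta_exp=beta_exp, se_exp=se_exp, eaf_exp=0.5,
        pval_exp=1e-6, n_exp=1539, beta_out=beta_out, se_out=se_out,
        eaf_out=0.5, f_stat=25.0, r2_explained=0.016)


def _random_set(rng, J):
    bx = rng.uniform(0.05, 0.4, J) * rng.choice([-1, 1], J)
    sy = rng.uniform(0.01, 0.1, J)
    by = 0.2 * bx + sy * rng.standard_normal(J)
    return InstrumentSet.from_arrays(bx, np.full(J, 0.03), by, sy)


class TestWaldRatio:
    def test_arithmetic_identity(self):
        e = wald_ratio(_inst(0.1, 0.02, 0.01))
        assert e.beta == pytest.approx(0.2)
        assert e.se == pytest.approx(0.1)

    def test_null_outcome_effect(self):
        assert wald_ratio(_inst(0.1, 0.0, 0.01)).beta == 0.0

    def test_orientation_invariance(self):
        a = wald_ratio(_inst(0.1, 0.02, 0.01))
        b = wald_ratio(_inst(-0.1, -0.02, 0.01))
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(ValueError):
            wald_ratio(_inst(0.0, 0.02, 0.01))

    def test_second_order_se_exceeds_first_order(self):
        first = wald_ratio(_inst(0.1, 0.05, 0.01))
        second = wald_ratio(_inst(0.1, 0.05, 0.01), second_order=True)
        assert second.se > first.se


class TestIVW:
    def test_consensus_ratio_recovered_exactly(self, consensus_instruments):
        for model in ("fixed", "random"):
            assert ivw(consensus_instruments, model).beta == pytest.approx(0.2)

    def test_closed_form_worked_example(self, worked_instruments):
        e = ivw(worked_instruments, model="fixed")
        assert e.beta == pytest.approx(0.216667, abs=1e-6)
        assert e.se == pytest.approx(0.057735, abs=1e-6)

    def test_fewer_than_two_instruments_error(self):
        iset = InstrumentSet.from_arrays([0.1], [0.02], [0.02], [0.01])
        with pytest.raises(ValueError):
            ivw(iset)

    def test_random_effects_never_deflates(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            iset = _random_set(rng, 8)
            assert ivw(iset, "random").se >= ivw(iset, "fixed").se - 1e-15

    def test_or_transform_consistency(self, worked_instruments):
        e = ivw(worked_instruments)
        assert e.or_ == pytest.approx(np.exp(e.beta))
        assert e.ci_low <= e.beta <= e.ci_high
        assert e.or_ci_low == pytest.approx(np.exp(e.ci_low))


class TestEgger:
    def test_exact_fit_recovers_line(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.01 + 0.3 * bx
        iset = InstrumentSet.from_arrays(bx, np.full(4, 0.02), by,
                                         [0.01, 0.02, 0.015, 0.012])
        res = mr_egger(iset)
        assert res.intercept.beta == pytest.approx(0.01, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.3, abs=1e-12)

    def test_orientation_applied_before_fit(self):
        # flipping an instrument's allele coding must not change the result
        bx = np.array([0.1, -0.2, 0.3, 0.4])
        by = np.array([0.03, -0.05, 0.10, 0.13])
        sy = np.array([0.01, 0.02, 0.015, 0.012])
        a = mr_egger(InstrumentSet.from_arrays(bx, np.full(4, 0.02), by, sy))
        b = mr_egger(InstrumentSet.from_arrays(np.abs(bx), np.full(4, 0.02),
                                               by * np.sign(bx), sy))
        assert a.slope.beta == pytest.approx(b.slope.beta)
        assert a.intercept.beta == pytest.approx(b.intercept.beta)

    def test_degenerate_design_is_error(self):
        iset = InstrumentSet.from_arrays([0.2, 0.2, -0.2], [0.02] * 3,
                                         [0.05, 0.04, -0.05], [0.01] * 3)
        with pytest.raises(ValueError):
            mr_egger(iset)

    def test_fewer_than_three_instruments_error(self):
        iset = InstrumentSet.from_arrays([0.1, 0.2], [0.02] * 2,
                                         [0.02, 0.05], [0.01, 0.02])
        with pytest.raises(ValueError):
            mr_egger(iset)


class TestAgainstWLSOracle:
    """IVW and Egger must match generic weighted least squares exactly."""

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        J = int(rng.integers(3, 41))
        iset = _random_set(rng, J)
        bx, by, sy = iset.beta_exp, iset.beta_out, iset.se_out
        w = 1.0 / sy**2

        # IVW: through-origin weighted regression
        fit0 = sm.WLS(by, bx[:, None], weights=w).fit()
        e = ivw(iset, model="fixed")
        assert e.beta == pytest.approx(fit0.params[0], abs=1e-10)
        assert e.se == pytest.approx(
            float(np.sqrt(1.0 / np.sum(w * bx**2))), abs=1e-10)

        # Egger: free intercept on the oriented scale
        s = np.sign(bx)
        X = sm.add_constant(np.abs(bx))
        fit1 = sm.WLS(by * s, X, weights=w).fit()
        res = mr_egger(iset)
        assert res.intercept.beta == pytest.approx(fit1.params[0], abs=1e-10)
        assert res.slope.beta == pytest.approx(fit1.params[1], abs=1e-10)
        assert res.intercept.se == pytest.approx(fit1.bse[0], abs=1e-10)
        assert res.slope.se == pytest.approx(fit1.bse[1], abs=1e-10)

    def test_zero_intercept_wls_reproduces_ivw(self):
        rng = np.random.default_rng(7)
        iset = _random_set(rng, 12)
        s = np.sign(iset.beta_exp)
        fit = sm.WLS(iset.beta_out * s, np.abs(iset.beta_exp)[:, None],
                     weights=1 / iset.se_out**2).fit()
        assert ivw(iset, "fixed").beta == pytest.approx(fit.params[0], abs=1e-12)


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        est = weighted_median_arrays([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])
        assert est == pytest.approx(0.2)

    def test_interpolation_with_unequal_weights(self):
        # hand evaluation of the cumulative-midpoint rule
        est = weighted_median_arrays([0.1, 0.2, 0.3], [0.25, 0.25, 0.5])
        assert est == pytest.approx(0.23333333, abs=1e-8)

    def test_majority_weight_pins_estimate(self):
        bx = np.array([0.2, 0.2, 0.05, 0.05])
        by = np.array([0.04, 0.04, 0.02, 0.025])  # strong pair shares ratio 0.2
        sy = np.array([0.01, 0.01, 0.01, 0.01])
        est = weighted_median_arrays(by / bx, (bx / sy) ** 2)
        assert est == pytest.approx(0.2)

    def test_bootstrap_se_deterministic_given_seed(self, worked_instruments):
        a = weighted_median(worked_instruments, n_boot=200, seed=5)
        b = weighted_median(worked_instruments, n_boot=200, seed=5)
        c = weighted_median(worked_instruments, n_boot=200, seed=6)
        assert a.se == b.se
        assert a.se != c.se

    def test_fewer_than_three_instruments_error(self):
        iset = InstrumentSet.from_arrays([0.1, 0.2], [0.02] * 2,
                                         [0.02, 0.05], [0.01, 0.02])
        with pytest.raises(ValueError):
            weighted_median(iset)


class TestScaleInvariance:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(c=st.floats(0.1, 10.0), seed=st.integers(0, 50))
    def test_exposure_rescaling_rescales_estimates(self, c, seed):
        """betaX -> c*betaX rescales every causal estimate by 1/c."""
        rng = np.random.default_rng(seed)
        iset = _random_set(rng, 8)
        scaled = InstrumentSet.from_arrays(
            iset.beta_exp * c, iset.se_exp * c, iset.beta_out, iset.se_out)
        assert ivw(scaled).beta * c == pytest.approx(ivw(iset).beta)
        assert mr_egger(scaled).slope.beta * c == pytest.approx(
            mr_egger(iset).slope.beta)
        wm_a = weighted_median_arrays(iset.beta_out / iset.beta_exp,
                                      (iset.beta_exp / iset.se_out) ** 2)
        wm_b = weighted_median_arrays(scaled.beta_out / scaled.beta_exp,
                                      (scaled.beta_exp / scaled.se_out) ** 2)
        assert wm_b * c == pytest.approx(wm_a)
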
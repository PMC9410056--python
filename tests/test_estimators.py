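"""Estimator suite: Wald ratio, IVW, weighted median, MR-Egger, heterogeneity.

Regression-based oracles use statsmodels WLS: fixed-effect IVW equals
the weighted through-origin slope with unscaled coefficient variance,
the random-effects IVW standard error equals the sigma-scaled WLS one,
and MR-Egger equals WLS with an intercept.
"""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from mrkit.errors import EstimationError
from mrkit.estimators import (
    _weighted_median_value,
    egger,
    heterogeneity,
    ivw,
    wald_ratio,
    weighted_median,
)

from conftest import make_instruments


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(make_instruments([0.5], [0.1], [0.05])[0])
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.odds_ratio == pytest.approx(math.exp(0.2))

    def test_negative_exposure_effect(self):
        est = wald_ratio(make_instruments([-0.5], [0.1], [0.05])[0])
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome_effect(self):
        est = wald_ratio(make_instruments([0.5], [0.0], [0.05])[0])
        assert est.beta == 0.0
        assert est.pvalue == 1.0

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(EstimationError):
            wald_ratio(make_instruments([0.0], [0.1], [0.05])[0])

    def test_ci_brackets_estimate(self):
        est = wald_ratio(make_instruments([0.5], [0.1], [0.05])[0])
        assert est.ci_low <= est.beta <= est.ci_high


def random_instruments(rng, k=6):
    bx = rng.uniform(0.1, 0.5, k) * rng.choice([-1, 1], k)
    by = rng.normal(0.02, 0.05, k)
    sy = rng.uniform(0.005, 0.05, k)
    return make_instruments(bx, by, sy)


class TestIvw:
    def test_single_instrument_degenerates_to_wald(self):
        insts = make_instruments([0.5], [0.1], [0.05])
        est = ivw(insts, "fixed")
        wald = wald_ratio(insts[0])
        assert est.beta == wald.beta and est.se == wald.se
        assert est.method == "ivw_fixed"

    def test_two_equal_instruments_closed_form(self):
        insts = make_instruments([0.5, 0.5], [0.1, 0.1], [0.05, 0.05])
        est = ivw(insts, "fixed")
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1 / math.sqrt(2))

    def test_empty_list_raises(self):
        with pytest.raises(EstimationError):
            ivw([], "fixed")

    @pytest.mark.parametrize("seed", range(5))
    def test_fixed_equals_through_origin_wls_oracle(self, seed, rng=None):
        rng = np.random.default_rng(seed)
        insts = random_instruments(rng)
        est = ivw(insts, "fixed")
        bx = np.array([i.beta_exposure for i in insts])
        by = np.array([i.beta_outcome for i in insts])
        sy = np.array([i.se_outcome for i in insts])
        fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[0], rel=1e-10)
        # unscaled variance: divide out the estimated residual scale
        assert est.se == pytest.approx(fit.bse[0] / np.sqrt(fit.scale), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_effects_se_equals_sigma_scaled_wls(self, seed):
        rng = np.random.default_rng(100 + seed)
        insts = random_instruments(rng)
        est = ivw(insts, "random")
        bx = np.array([i.beta_exposure for i in insts])
        by = np.array([i.beta_outcome for i in insts])
        sy = np.array([i.se_outcome for i in insts])
        fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[0], rel=1e-10)
        assert est.se == pytest.approx(fit.bse[0], rel=1e-10)

    def test_underdispersion_shrinks_random_se_unless_floored(self):
        # nearly identical ratios: Q/(k-1) << 1
        insts = make_instruments([0.5, 0.5, 0.5], [0.1, 0.1001, 0.0999],
                                 [0.05, 0.05, 0.05])
        fixed = ivw(insts, "fixed")
        random = ivw(insts, "random")
        floored = ivw(insts, "random", floor_dispersion=True)
        assert random.se < fixed.se
        assert floored.se == fixed.se


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        insts = make_instruments([1, 1, 1], [1, 2, 3], [1, 1, 1])
        est = weighted_median(insts, n_boot=50, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_interpolated_percentile_resists_outlier(self):
        insts = make_instruments([1, 1, 1, 1], [0, 0, 0, 10], [1, 1, 1, 1])
        est = weighted_median(insts, n_boot=50, seed=0)
        # hand evaluation: s = (.125,.375,.625,.875); interpolate 0.5
        # between ratios 0 and 0 -> 0
        assert est.beta == pytest.approx(0.0, abs=1e-12)

    def test_seeded_bootstrap_reproducible(self):
        rng = np.random.default_rng(7)
        insts = random_instruments(rng)
        a = weighted_median(insts, n_boot=200, seed=11)
        b = weighted_median(insts, n_boot=200, seed=11)
        assert a.se == b.se

    def test_requires_three_instruments(self):
        with pytest.raises(EstimationError):
            weighted_median(make_instruments([1, 1], [1, 2], [1, 1]))

    @given(ratios=st.lists(st.floats(-5, 5), min_size=3, max_size=9)
           .filter(lambda r: len(r) % 2 == 1))
    def test_equal_weights_odd_k_is_sample_median(self, ratios):
        r = np.array(ratios)
        w = np.ones_like(r)
        assert _weighted_median_value(r, w) == pytest.approx(float(np.median(r)))


class TestEgger:
    def test_exact_linear_fit_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        insts = make_instruments(bx, 2 * bx, np.full(5, 0.01))
        slope, intercept = egger(insts)
        assert slope.beta == pytest.approx(2.0)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        insts = random_instruments(rng)
        slope, intercept = egger(insts)
        bx = np.array([abs(i.beta_exposure) for i in insts])
        by = np.array([i.beta_outcome * (1 if i.beta_exposure > 0 else -1) for i in insts])
        sy = np.array([i.se_outcome for i in insts])
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert intercept.beta == pytest.approx(fit.params[0], rel=1e-9)
        assert slope.beta == pytest.approx(fit.params[1], rel=1e-9)
        assert intercept.se == pytest.approx(fit.bse[0], rel=1e-9)
        assert slope.se == pytest.approx(fit.bse[1], rel=1e-9)
        assert slope.pvalue == pytest.approx(fit.pvalues[1], rel=1e-9)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(3)
        insts = random_instruments(rng)
        flipped = make_instruments(
            [-i.beta_exposure for i in insts],
            [-i.beta_outcome for i in insts],
            [i.se_outcome for i in insts],
        )
        s1, i1 = egger(insts)
        s2, i2 = egger(flipped)
        assert s1.beta == pytest.approx(s2.beta)
        assert i1.beta == pytest.approx(i2.beta)

    def test_slope_equals_ivw_when_intercept_constrained(self):
        """Dropping the intercept from the Egger design reproduces fixed IVW."""
        rng = np.random.default_rng(4)
        insts = random_instruments(rng)
        bx = np.array([abs(i.beta_exposure) for i in insts])
        by = np.array([i.beta_outcome * np.sign(i.beta_exposure) for i in insts])
        sy = np.array([i.se_outcome for i in insts])
        constrained = sm.WLS(by, bx, weights=1 / sy**2).fit()
        assert ivw(insts, "fixed").beta == pytest.approx(constrained.params[0], rel=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(EstimationError):
            egger(make_instruments([0.1, 0.2], [0.1, 0.2], [0.01, 0.01]))

    def test_singular_design(self):
        with pytest.raises(EstimationError):
            egger(make_instruments([0.3, 0.3, 0.3], [0.1, 0.2, 0.3], [0.01, 0.01, 0.01]))


class TestHeterogeneity:
    def test_identical_ratios_no_dispersion(self):
        insts = make_instruments([0.5, 0.5, 0.5], [0.1, 0.1, 0.1], [0.05, 0.04, 0.03])
        het = heterogeneity(insts)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.i2 == 0.0

    def test_two_instrument_hand_computation(self):
        # ratios 0 and 1 with unit SEs: weighted mean 0.5, Q = 0.25 + 0.25
        insts = make_instruments([1.0, 1.0], [0.0, 1.0], [1.0, 1.0])
        het = heterogeneity(insts)
        assert het.q == pytest.approx(0.5)
        assert het.df == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_q_decomposition_identity(self, seed):
        rng = np.random.default_rng(300 + seed)
        insts = random_instruments(rng)
        het = heterogeneity(insts)
        ratios = np.array([i.beta_outcome / i.beta_exposure for i in insts])
        w = np.array([(abs(i.beta_exposure) / i.se_outcome) ** 2 for i in insts])
        shortcut = np.sum(w * ratios**2) - np.sum(w * ratios) ** 2 / np.sum(w)
        assert het.q == pytest.approx(shortcut, rel=1e-10)

    def test_i2_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            insts = random_instruments(rng)
            het = heterogeneity(insts)
            assert 0 <= het.i2 < 100
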
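"""Causal-effect estimators: Wald ratio, IVW, Egger, weighted median, ML."""

import numpy as np
import pytest

from mrnet.estimators import (
    EstimationError,
    egger,
    ivw,
    max_likelihood,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from mrnet.sumstats import HarmonizedSet


def _hs(bx, by, sx=None, sy=None, orientation="increase"):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    sy = np.full_like(by, 0.02) if sy is None else np.asarray(sy, float)
    return HarmonizedSet.from_arrays(
        [f"rs{i}" for i in range(len(bx))], bx, sx, by, sy,
        orientation=orientation,
    )


class TestWaldRatio:
    def test_first_order_from_oriented_instrument(self):
        # rs9420907 oriented per SD decrease: x=0.069, y=0.050, se_y=0.019
        est = wald_ratio(0.069, 0.010, 0.050, 0.019, order="first")
        assert est.ratio == pytest.approx(0.050 / 0.069, abs=1e-12)
        assert est.se_ratio == pytest.approx(0.019 / 0.069, abs=1e-12)
        assert est.ratio == pytest.approx(0.7246, abs=5e-4)
        assert est.se_ratio == pytest.approx(0.2754, abs=5e-4)

    def test_null_outcome_gives_zero_ratio(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02).ratio == 0.0

    def test_second_order_se_never_smaller(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            bx, by = rng.normal(size=2)
            if bx == 0:
                continue
            sx, sy = rng.uniform(0.01, 0.5, 2)
            first = wald_ratio(bx, sx, by, sy, "first").se_ratio
            second = wald_ratio(bx, sx, by, sy, "second").se_ratio
            assert second >= first

    def test_zero_exposure_effect_is_an_error(self):
        with pytest.raises(EstimationError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIVW:
    def test_fixture_matches_hand_computed_weighted_mean(self, ltl_als_decrease):
        """Weighted mean over the 7 published ratios, first-order weights."""
        est = ivw(ltl_als_decrease, mode="fixed", order="first")
        assert est.beta == pytest.approx(0.1093, abs=5e-4)
        assert est.se == pytest.approx(0.0928, abs=5e-4)
        or_, lo, hi = to_odds_ratio(est)
        assert or_ == pytest.approx(1.10, abs=0.02)

    def test_fixed_and_random_share_the_point_estimate(self, ltl_als_decrease):
        fixed = ivw(ltl_als_decrease, mode="fixed")
        random = ivw(ltl_als_decrease, mode="random")
        assert fixed.beta == random.beta
        assert random.se >= fixed.se

    def test_single_instrument_degenerates_to_wald_ratio(self):
        hs = _hs([0.1], [0.03])
        with pytest.warns(UserWarning, match="single instrument"):
            est = ivw(hs)
        w = wald_ratio(0.1, 0.01, 0.03, 0.02)
        assert est.beta == pytest.approx(w.ratio, abs=1e-12)
        assert est.se == pytest.approx(w.se_ratio, abs=1e-12)

    def test_invariant_to_record_order(self, ltl_als_decrease):
        k = len(ltl_als_decrease)
        shuffled = ltl_als_decrease.subset(list(reversed(range(k))))
        assert ivw(shuffled).beta == pytest.approx(
            ivw(ltl_als_decrease).beta, abs=1e-14
        )

    def test_random_effects_never_narrows_below_fixed(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = 8
            bx = rng.uniform(0.03, 0.1, k)
            by = rng.normal(0.1 * bx, 0.02)
            hs = _hs(bx, by)
            assert ivw(hs, "random").se >= ivw(hs, "fixed").se


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.03, 0.05, 0.07, 0.09, 0.11])
        by = 0.1 * bx + 0.02
        est = egger(_hs(bx, by))
        assert est.beta == pytest.approx(0.1, abs=1e-10)
        assert est.diagnostics["egger_intercept"] == pytest.approx(0.02, abs=1e-10)
        assert est.diagnostics["residual_scale"] == pytest.approx(1.0)

    def test_fixture_slope_and_intercept_match_wls_oracle(self, ltl_als_decrease):
        """Closed-form WLS on the published (rounded) inputs."""
        est = egger(ltl_als_decrease)
        assert est.beta == pytest.approx(0.144, abs=5e-4)
        assert est.diagnostics["egger_intercept"] == pytest.approx(-0.0025, abs=5e-4)

    def test_fixture_intercept_not_significant(self, ltl_als_decrease):
        """No detectable directional pleiotropy among the 7 instruments."""
        est = egger(ltl_als_decrease)
        assert est.diagnostics["intercept_p"] > 0.05

    def test_zero_intercept_constraint_equals_ivw(self):
        """Weighted regression through the origin with 1/se_y^2 weights is
        algebraically identical to first-order IVW."""
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.02, 0.1, 10)
        sy = rng.uniform(0.01, 0.05, 10)
        by = rng.normal(0.2 * bx, sy)
        hs = _hs(bx, by, sy=sy)
        w = 1 / sy**2
        slope_origin = np.sum(w * bx * by) / np.sum(w * bx * bx)
        assert ivw(hs, order="first").beta == pytest.approx(slope_origin, abs=1e-10)

    def test_identical_exposure_effects_unidentified(self):
        with pytest.raises(EstimationError, match="unidentified"):
            egger(_hs([0.05] * 4, [0.01, 0.02, 0.0, 0.015]))

    def test_needs_three_instruments(self):
        with pytest.raises(EstimationError):
            egger(_hs([0.1, 0.2], [0.01, 0.02]))


class TestWeightedMedian:
    def test_fixture_matches_interpolation_oracle(self, ltl_als_decrease):
        est = weighted_median(ltl_als_decrease, n_boot=2000, seed=42)
        assert est.beta == pytest.approx(0.0815, abs=5e-4)

    def test_equal_weights_odd_count_is_plain_median(self):
        ratios = np.array([-1.0, 0.5, 2.0, 3.0, 10.0])
        assert weighted_median_point(ratios, np.ones(5)) == pytest.approx(2.0)

    def test_dominant_weight_returns_that_ratio(self):
        ratios = np.array([0.1, 5.0, -3.0])
        weights = np.array([1e8, 1e-8, 1e-8])
        assert weighted_median_point(ratios, weights) == pytest.approx(0.1, abs=1e-4)

    def test_resists_minority_contamination(self):
        """Symmetric contamination carrying < 50% of weight about the true
        ratio leaves the estimate at the valid instruments' ratio."""
        bx = np.full(10, 0.1)
        by = 0.3 * bx
        by[:2] += 0.5   # two contaminated instruments, equal weights
        by[2:4] -= 0.5
        est = weighted_median(_hs(bx, by), n_boot=1000, seed=0)
        assert est.beta == pytest.approx(0.3, abs=1e-6)

    def test_deterministic_given_seed(self, ltl_als_decrease):
        a = weighted_median(ltl_als_decrease, n_boot=500, seed=9)
        b = weighted_median(ltl_als_decrease, n_boot=500, seed=9)
        assert a.beta == b.beta and a.se == b.se


class TestMaxLikelihood:
    def test_fixture_estimate_close_to_ivw(self, ltl_als_decrease):
        ml = max_likelihood(ltl_als_decrease)
        assert np.exp(ml.beta) == pytest.approx(1.10, abs=0.02)

    def test_noiseless_exposure_limit_is_wald_ratio(self):
        hs = _hs([0.1], [0.03], sx=[1e-10], sy=[0.02])
        assert max_likelihood(hs).beta == pytest.approx(0.3, abs=1e-8)

    def test_exact_line_recovered_to_six_decimals(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.2, 12)
        hs = _hs(bx, 0.3 * bx, sx=np.full(12, 1e-8), sy=np.full(12, 1e-8))
        assert max_likelihood(hs).beta == pytest.approx(0.3, abs=1e-6)

    def test_invariant_to_record_order(self, ltl_als_decrease):
        k = len(ltl_als_decrease)
        shuffled = ltl_als_decrease.subset(list(reversed(range(k))))
        assert max_likelihood(shuffled).beta == pytest.approx(
            max_likelihood(ltl_als_decrease).beta, abs=1e-8
        )


class TestOddsRatioConversion:
    def test_null_effect_maps_to_unit_odds(self):
        from mrnet.estimators import MREstimate

        est = MREstimate("ivw-fixed", 0.0, 0.1, 1.0, 5)
        or_, lo, hi = to_odds_ratio(est)
        assert or_ == 1.0 and lo < 1.0 < hi

    @pytest.mark.parametrize(
        "beta,se,expected",
        [
            (0.097, 0.089, (1.10, 0.93, 1.31)),   # European total effect
            (-0.284, 0.180, (0.75, 0.53, 1.07)),  # Asian total effect
        ],
    )
    def test_published_total_effects_round_trip(self, beta, se, expected):
        from mrnet.estimators import MREstimate

        or_, lo, hi = to_odds_ratio(MREstimate("ivw-fixed", beta, se, 0.5, 7))
        assert (round(or_, 2), round(lo, 2), round(hi, 2)) == expected

    def test_ci_ordering_preserved(self, ltl_als_decrease):
        est = ivw(ltl_als_decrease)
        or_, lo, hi = to_odds_ratio(est)
        assert lo <= or_ <= hi
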
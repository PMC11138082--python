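"""Univariable estimators: exact cases, oracle equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tsmr import (
    HarmonizedSet,
    ivw,
    mode_estimate,
    mr_egger,
    to_odds_scale,
    wald_ratios,
    weighted_median,
)
from tsmr.exceptions import (
    ConfigurationError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from tsmr.uvmr import MODE_GRID_SIZE, point_estimates, weighted_median_point

from conftest import calibration_config, harmonized_from, toy_harmonized


def random_instance(seed, k=12):
    rng = np.random.default_rng(seed)
    return toy_harmonized(
        bx=rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k),
        by=rng.normal(0, 0.05, k),
        sy=rng.uniform(0.005, 0.03, k),
        sx=rng.uniform(0.002, 0.01, k),
    )


class TestWaldRatios:
    def test_direct_formula_and_signs(self):
        h = toy_harmonized(bx=[0.2, -0.1], by=[0.1, -0.05], sy=[0.02, 0.02])
        theta, sigma = wald_ratios(h)
        np.testing.assert_allclose(theta, [0.5, 0.5])
        np.testing.assert_allclose(sigma, [0.1, 0.2])

    def test_zero_exposure_effect_rejected(self):
        h = toy_harmonized(bx=[0.2, 0.0], by=[0.1, 0.1], sy=[0.02, 0.02])
        with pytest.raises(DegenerateInstrumentError):
            wald_ratios(h)

    def test_first_order_se_matches_simulated_sd(self):
        """sigma_j should match the sd of beta_Y_j/beta_X_j under resampled
        outcome noise to within Monte-Carlo error."""
        rng = np.random.default_rng(5)
        h = random_instance(11, k=10)
        _, sigma = wald_ratios(h)
        draws = rng.normal(h.beta_Y, h.se_Y, size=(100_000, 10))
        emp = (draws / h.beta_X[:, 0]).std(axis=0, ddof=1)
        np.testing.assert_allclose(emp, sigma, rtol=0.02)


class TestIVW:
    def test_perfectly_proportional_effects(self, proportional_h):
        r = ivw(proportional_h)
        assert r.beta == pytest.approx(0.5)
        fixed = ivw(proportional_h, "fixed")
        assert r.se == pytest.approx(fixed.se)  # Q = 0: no overdispersion

    def test_equal_weights_reduce_to_ols_through_origin(self):
        h = toy_harmonized(
            bx=[0.1, 0.2, 0.3], by=[0.07, 0.11, 0.19], sy=[0.02, 0.02, 0.02]
        )
        r = ivw(h, "fixed")
        bx, by = h.beta_X[:, 0], h.beta_Y
        ols = np.sum(bx * by) / np.sum(bx * bx)
        assert r.beta == pytest.approx(ols)

    @given(st.integers(0, 300))
    def test_equals_weighted_mean_of_ratios(self, seed):
        """Oracle: IVW is the mean of Wald ratios weighted by beta_X^2/se_Y^2,
        accumulated by brute force."""
        h = random_instance(seed)
        theta, _ = wald_ratios(h)
        w = h.beta_X[:, 0] ** 2 / h.se_Y**2
        brute = sum(wi * ti for wi, ti in zip(w, theta)) / sum(w)
        assert ivw(h).beta == pytest.approx(brute, rel=1e-12)

    def test_requires_two_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(toy_harmonized(bx=[0.1], by=[0.05], sy=[0.01]))

    def test_parameter_recovery_no_pleiotropy(self):
        """Mean IVW estimate over 60 clean replicates stays within 2 MC SEs
        of the true effect."""
        est = [
            point_estimates(harmonized_from(calibration_config(seed=s, k=60)))["ivw"]
            for s in range(60)
        ]
        est = np.array(est)
        mcse = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.14) < 2 * mcse


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = toy_harmonized(bx=bx, by=0.03 + 0.5 * bx, sy=[0.01] * 4)
        r = mr_egger(h)
        assert r.beta == pytest.approx(0.5, abs=1e-10)
        assert r.intercept == pytest.approx(0.03, abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(toy_harmonized(bx=[0.1, 0.2], by=[0.1, 0.1], sy=[0.01] * 2))

    def test_null_intercept_rarely_rejected_without_pleiotropy(self):
        """Egger slope tracks IVW and the intercept test keeps its size under
        the no-pleiotropy scenario (50 replicates)."""
        rejections = 0
        gaps = []
        for s in range(50):
            h = harmonized_from(calibration_config(seed=1000 + s, k=80))
            e = mr_egger(h)
            gaps.append(e.beta - ivw(h).beta)
            rejections += e.intercept_p < 0.05
        assert rejections <= 7  # ~binomial(50, 0.05)
        assert abs(np.mean(gaps)) < 0.01


class TestWeightedMedian:
    def test_symmetric_cumulative_weights_hit_middle_ratio(self):
        # ratios (0.4, 0.5, 10) with equal weights: positions 1/6, 1/2, 5/6
        assert weighted_median_point(np.array([0.4, 0.5, 10.0]), np.ones(3)) == 0.5

    def test_identical_ratios(self):
        h = toy_harmonized(bx=[0.1, 0.2, 0.4], by=[0.05, 0.1, 0.2], sy=[0.01] * 3)
        r = weighted_median(h, n_boot=200, seed=1)
        assert r.beta == pytest.approx(0.5)
        assert r.se < 0.15

    @given(st.integers(0, 300))
    def test_matches_bruteforce_interpolation(self, seed):
        """Oracle: rebuild the cumulative-weight interpolation point by point."""
        rng = np.random.default_rng(seed)
        k = rng.integers(3, 12)
        theta = rng.normal(0, 1, k)
        w = rng.uniform(0.1, 2.0, k)
        order = np.argsort(theta)
        t, wn = theta[order], w[order] / w.sum()
        cum = 0.0
        pos = []
        for wi in wn:
            pos.append(cum + wi / 2)
            cum += wi
        pos = np.array(pos)
        j = np.searchsorted(pos, 0.5)
        if j == 0:
            expect = t[0]
        elif j == len(t):
            expect = t[-1]
        else:
            frac = (0.5 - pos[j - 1]) / (pos[j] - pos[j - 1])
            expect = t[j - 1] + frac * (t[j] - t[j - 1])
        assert weighted_median_point(theta, w) == pytest.approx(expect, rel=1e-12)

    def test_deterministic_given_seed(self, random_h):
        a = weighted_median(random_h, n_boot=100, seed=9)
        b = weighted_median(random_h, n_boot=100, seed=9)
        assert a.beta == b.beta and a.se == b.se


class TestMode:
    def test_dominant_cluster(self):
        h = toy_harmonized(
            bx=[0.1, 0.1, 0.1, 0.1],
            by=[0.05, 0.05, 0.05, 0.5],
            sy=[0.01] * 4,
        )
        r = mode_estimate(h, "simple", n_boot=50, seed=1)
        ratios = h.beta_Y / h.beta_X[:, 0]
        grid_step = (ratios.max() - ratios.min()) * 1.5 / MODE_GRID_SIZE
        assert abs(r.beta - 0.5) < max(3 * grid_step, 0.05)

    def test_weighted_mode_moves_toward_heavy_ratio(self):
        # weights concentrate on the outlying ratio: the weighted mode must
        # sit closer to it than the simple mode does
        h = toy_harmonized(
            bx=[0.1, 0.1, 0.1, 1.0],
            by=[0.05, 0.051, 0.049, 2.0],
            sy=[0.05, 0.05, 0.05, 0.001],
        )
        simple = mode_estimate(h, "simple", n_boot=10, seed=1).beta
        weighted = mode_estimate(h, "weighted", n_boot=10, seed=1).beta
        assert abs(weighted - 2.0) < abs(simple - 2.0)

    def test_identical_ratios_returned_directly(self):
        h = toy_harmonized(bx=[0.1, 0.2, 0.4], by=[0.05, 0.1, 0.2], sy=[0.01] * 3)
        assert mode_estimate(h, "simple", n_boot=20, seed=0).beta == pytest.approx(0.5)

    def test_plurality_valid_cluster_recovered(self):
        """45% valid instruments at theta=0.3 against two smaller invalid
        clusters: the mode should land on the valid plurality."""
        rng = np.random.default_rng(21)
        k = 60
        n_valid = 27
        bx = rng.uniform(0.05, 0.15, k)
        offsets = np.zeros(k)
        offsets[n_valid : n_valid + 18] = 0.03  # 30% cluster
        offsets[n_valid + 18 :] = -0.04  # 25% cluster
        sy = np.full(k, 0.002)
        by = 0.3 * bx + offsets + rng.normal(0, sy)
        h = toy_harmonized(bx=bx, by=by, sy=sy)
        r = mode_estimate(h, "simple", n_boot=10, seed=2)
        assert abs(r.beta - 0.3) < 0.05


class TestOddsScale:
    def test_identity_relations(self):
        or_, lo, hi = to_odds_scale(0.14, 0.029)
        assert or_ == pytest.approx(np.exp(0.14))
        assert lo < or_ < hi
        # log-symmetry of the interval
        assert np.log(or_) - np.log(lo) == pytest.approx(np.log(hi) - np.log(or_))

    def test_degenerate(self):
        assert to_odds_scale(0.0, 0.0) == (1.0, 1.0, 1.0)
        with pytest.raises(ConfigurationError):
            to_odds_scale(0.1, -0.01)


class TestEstimatorInvariances:
    @pytest.mark.parametrize("which", ["ivw", "mr_egger", "weighted_median", "simple_mode"])
    def test_sign_flip_of_any_snp_is_invisible(self, which):
        h = random_instance(77)
        flipped = HarmonizedSet(
            h.exposure_ids,
            h.outcome_id,
            h.snp_ids,
            h.beta_X * -1,
            h.se_X,
            h.beta_Y * -1,
            h.se_Y,
        )
        a = point_estimates(h)[which]
        b = point_estimates(flipped)[which]
        assert a == pytest.approx(b, rel=1e-9)

    def test_se_scaling_leaves_points_fixed_and_scales_fixed_se(self):
        h = random_instance(78)
        scaled = HarmonizedSet(
            h.exposure_ids, h.outcome_id, h.snp_ids,
            h.beta_X, h.se_X, h.beta_Y, h.se_Y * 3.0,
        )
        assert ivw(h, "fixed").beta == pytest.approx(ivw(scaled, "fixed").beta)
        assert ivw(scaled, "fixed").se == pytest.approx(3.0 * ivw(h, "fixed").se)
        a, b = point_estimates(h), point_estimates(scaled)
        for key in ("ivw", "mr_egger", "weighted_median"):
            assert a[key] == pytest.approx(b[key], rel=1e-9)
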
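"""KDE tail bounds and unreliable-feature calibration."""

import numpy as np
import pytest

from gaitfuse import (
    DegenerateDistributionError,
    FeatureBounds,
    calibrate_features,
    compute_bounds,
    estimate_density_cdf,
    fit_feature_bounds,
    silverman_bandwidth,
)


class TestBandwidth:
    def test_printed_formula(self, rng):
        # sigma=1, L=100 -> (4/300)^(1/5)
        v = rng.normal(size=100)
        v = (v - v.mean()) / v.std(ddof=1)  # exact unit sample sd
        assert silverman_bandwidth(v) == pytest.approx((4 / 300) ** 0.2)

    def test_linear_in_sigma(self, rng):
        v = rng.normal(size=200)
        assert silverman_bandwidth(2 * v) == pytest.approx(2 * silverman_bandwidth(v))

    def test_constant_input_signals_degeneracy(self):
        with pytest.raises(DegenerateDistributionError):
            silverman_bandwidth(np.full(50, 3.0))


class TestDensityCdf:
    def test_half_mass_at_center_of_symmetric_sample(self, rng):
        x = rng.normal(size=500)
        v = np.concatenate([x, -x])  # exactly symmetric about 0
        cdf = estimate_density_cdf(v, silverman_bandwidth(v))
        assert cdf(0.0) == pytest.approx(0.5, abs=1e-9)

    def test_monotone_with_proper_limits(self, rng):
        v = rng.normal(size=100)
        cdf = estimate_density_cdf(v, 0.3)
        grid = np.linspace(-6, 6, 200)
        vals = cdf(grid)
        assert np.all(np.diff(vals) >= 0)
        assert cdf(-1e6) == pytest.approx(0.0, abs=1e-12)
        assert cdf(1e6) == pytest.approx(1.0, abs=1e-12)

    def test_cluster_mass_fraction(self):
        # 99 points at 0, one at 10: mass below 5 is 99/100
        v = np.concatenate([np.zeros(99), [10.0]])
        cdf = estimate_density_cdf(v, 0.5)
        assert cdf(5.0) == pytest.approx(0.99, abs=1e-6)

    def test_matches_sklearn_kde_by_numeric_integration(self, rng):
        sklearn = pytest.importorskip("sklearn.neighbors")
        v = rng.normal(size=60)
        rho = 0.4
        kde = sklearn.KernelDensity(kernel="gaussian", bandwidth=rho).fit(v[:, None])
        grid = np.linspace(v.min() - 5 * rho, 1.0, 20001)
        dens = np.exp(kde.score_samples(grid[:, None]))
        oracle = np.trapezoid(dens, grid)
        cdf = estimate_density_cdf(v, rho)
        assert cdf(1.0) == pytest.approx(oracle, abs=1e-4)

    def test_parameter_validation(self, rng):
        with pytest.raises(ValueError):
            estimate_density_cdf(rng.normal(size=10), rho=0.0)


class TestBounds:
    def test_upper_bound_tracks_empirical_quantile(self, rng):
        v = rng.normal(size=10_000)
        lb, ub, rho = compute_bounds(v, p_th=0.999)
        empirical = np.quantile(v, 0.999)  # ~3.09 for a standard normal
        assert ub == pytest.approx(empirical, abs=3 * rho)
        assert lb <= ub

    def test_symmetric_sample_gives_symmetric_bounds(self, rng):
        half = rng.normal(size=2000)
        v = np.concatenate([half, -half])
        lb, ub, _ = compute_bounds(v, p_th=0.99)
        assert lb == pytest.approx(-ub, abs=1e-8)

    def test_bounds_collapse_to_median_as_p_th_approaches_half(self, rng):
        v = rng.normal(size=500)
        lb, ub, rho = compute_bounds(v, p_th=0.5 + 1e-9)
        assert ub - lb < 1e-5 * rho

    def test_p_th_domain(self, rng):
        v = rng.normal(size=100)
        for bad in (0.5, 1.0, 0.2):
            with pytest.raises(ValueError):
                compute_bounds(v, p_th=bad)


class TestCalibrate:
    @pytest.fixture
    def fitted(self, rng):
        X = rng.normal(size=(800, 4)) * np.array([1.0, 2.0, 0.5, 3.0])
        return X, fit_feature_bounds(X, p_th=0.95)

    def test_interior_values_untouched(self, fitted):
        X, bounds = fitted
        mid = np.tile((bounds.lower + bounds.upper) / 2, (5, 1))
        np.testing.assert_array_equal(calibrate_features(mid, bounds), mid)

    def test_clamps_to_violated_bound(self, fitted):
        _, bounds = fitted
        hot = bounds.upper[None, :] + 1.0
        np.testing.assert_allclose(calibrate_features(hot, bounds), bounds.upper[None, :])

    def test_idempotent_and_shape_preserving(self, fitted):
        X, bounds = fitted
        once = calibrate_features(X, bounds)
        assert once.shape == X.shape  # no row deleted
        np.testing.assert_array_equal(calibrate_features(once, bounds), once)
        assert np.all(once >= bounds.lower) and np.all(once <= bounds.upper)

    def test_mean_strategy_uses_training_center(self, fitted):
        X, bounds = fitted
        hot = bounds.upper[None, :] + 1.0
        out = calibrate_features(hot, bounds, strategy="mean")
        np.testing.assert_allclose(out, bounds.center[None, :])

    def test_off_strategy_is_identity(self, fitted):
        X, bounds = fitted
        np.testing.assert_array_equal(calibrate_features(X, bounds, "off"), X)

    def test_flagged_fraction_near_two_tails(self, rng):
        # smooth unimodal sample: flagged fraction ~ 2*(1-p_th) within KDE error
        X = rng.normal(size=(5000, 1))
        bounds = fit_feature_bounds(X, p_th=0.95)
        flagged = ((X < bounds.lower) | (X > bounds.upper)).mean()
        assert flagged == pytest.approx(0.10, abs=0.04)

    def test_high_p_th_approaches_identity_on_training_data(self, rng):
        X = rng.normal(size=(300, 3))
        bounds = fit_feature_bounds(X, p_th=0.9999)
        assert ((X < bounds.lower) | (X > bounds.upper)).mean() < 0.005

    def test_degenerate_column_is_left_alone(self, rng):
        X = np.column_stack([np.full(100, 2.0), rng.normal(size=100)])
        bounds = fit_feature_bounds(X, p_th=0.95)
        assert np.isinf(bounds.lower[0]) and np.isinf(bounds.upper[0])
        np.testing.assert_array_equal(calibrate_features(X, bounds)[:, 0], X[:, 0])

    def test_column_count_mismatch_rejected(self, fitted):
        _, bounds = fitted
        with pytest.raises(ValueError):
            calibrate_features(np.zeros((3, 7)), bounds)

    def test_json_round_trip(self, fitted):
        _, bounds = fitted
        back = FeatureBounds.from_json(bounds.to_json())
        np.testing.assert_allclose(back.lower, bounds.lower)
        np.testing.assert_allclose(back.upper, bounds.upper)
        np.testing.assert_allclose(back.center, bounds.center)
        assert back.p_th == bounds.p_th
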
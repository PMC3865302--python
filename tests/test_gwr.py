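import math

import numpy as np
import pytest

from firegwr.grid_data import pairwise_distances_km
from firegwr.gwr import (
    KernelSpec,
    SingularFitError,
    adaptive_bandwidth_distance,
    aicc,
    fit_gwr,
    fit_ols,
    kernel_weights,
    local_r2,
    local_wls,
    select_bandwidth,
)
from firegwr.synthetic import SyntheticScenario, simulate_gwr_world, simulate_stationary_world


def wls_normal_equations_oracle(X, y, w):
    """Independent solve of the weighted normal equations by explicit 2x2 inversion."""
    W = np.diag(w)
    A = X.T @ W @ X
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    Ainv = np.array([[A[1, 1], -A[0, 1]], [-A[1, 0], A[0, 0]]]) / det
    return Ainv @ (X.T @ W @ y)


class TestAdaptiveBandwidth:
    def test_collinear_equally_spaced(self):
        lon = np.array([0.0, 1.0, 2.0])
        lat = np.zeros(3)
        spacing = pairwise_distances_km(lon, lat)[0, 1]
        assert adaptive_bandwidth_distance((lon, lat), 1, 1) == pytest.approx(spacing)

    def test_k_max_is_max_distance(self):
        rng = np.random.default_rng(1)
        lon, lat = rng.uniform(-10, 10, 15), rng.uniform(-10, 10, 15)
        D = pairwise_distances_km(lon, lat)
        got = adaptive_bandwidth_distance((lon, lat), 3, 14)
        assert got == pytest.approx(np.delete(D[3], 3).max())

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(2)
        lon, lat = rng.uniform(-10, 10, 20), rng.uniform(-10, 10, 20)
        D = pairwise_distances_km(lon, lat)
        for i in (0, 7, 19):
            sorted_d = np.sort(np.delete(D[i], i))
            for k in (1, 5, 10):
                assert adaptive_bandwidth_distance((lon, lat), i, k) == pytest.approx(sorted_d[k - 1])

    def test_nondecreasing_in_k(self):
        rng = np.random.default_rng(3)
        lon, lat = rng.uniform(-5, 5, 12), rng.uniform(-5, 5, 12)
        bs = [adaptive_bandwidth_distance((lon, lat), 0, k) for k in range(1, 12)]
        assert np.all(np.diff(bs) >= 0)

    def test_duplicate_coordinates_fallback(self):
        lon = np.array([0.0, 0.0, 1.0])
        lat = np.zeros(3)
        b = adaptive_bandwidth_distance((lon, lat), 0, 1)
        assert b > 0  # falls back to smallest positive neighbour distance


class TestKernelWeights:
    def test_closed_form_values(self):
        lon = np.array([0.0, 0.0, 0.0])
        lat = np.array([0.0, 1.0, 2.0])
        b = pairwise_distances_km(lon, lat)[0, 1]  # one degree
        w = kernel_weights((lon, lat), 0, b)
        assert w[0] == pytest.approx(1.0)              # d = 0
        assert w[1] == pytest.approx(math.exp(-0.5))   # d = b
        assert w[2] == pytest.approx(math.exp(-2.0))   # d = 2b

    def test_strictly_decreasing_in_distance(self):
        lon = np.arange(8) * 1.0
        lat = np.zeros(8)
        w = kernel_weights((lon, lat), 0, 200.0)
        assert np.all(np.diff(w) < 0)


class TestLocalWLS:
    def test_uniform_weights_equal_ols(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = 1.0 + 2.0 * x + rng.normal(size=30) * 0.1
        X = np.column_stack([np.ones(30), x])
        beta, _, _ = local_wls(X, y, np.ones(30))
        ref = np.polyfit(x, y, 1)
        assert beta[1] == pytest.approx(ref[0], rel=1e-9)
        assert beta[0] == pytest.approx(ref[1], rel=1e-9)

    def test_two_points_interpolate(self):
        X = np.array([[1.0, 0.0], [1.0, 2.0]])
        y = np.array([1.0, 5.0])
        beta, _, _ = local_wls(X, y, np.array([0.3, 0.9]))
        np.testing.assert_allclose(X @ beta, y, atol=1e-12)

    def test_five_point_fixture_vs_normal_equations(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.5, 1.9, 4.1, 5.8, 8.2])
        w = np.array([1.0, 0.8, 0.5, 0.2, 0.1])
        X = np.column_stack([np.ones(5), x])
        beta, _, _ = local_wls(X, y, w)
        np.testing.assert_allclose(beta, wls_normal_equations_oracle(X, y, w), rtol=1e-12)

    def test_rank_deficiency_raises_with_index(self):
        X = np.ones((5, 2))  # constant predictor column
        y = np.arange(5.0)
        with pytest.raises(SingularFitError):
            local_wls(X, y, np.ones(5), i=3)

    def test_hat_row_reproduces_fitted(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        X = np.column_stack([np.ones(12), x])
        w = np.exp(-0.5 * (np.arange(12) / 4.0) ** 2)
        beta, hat_row, fitted0 = local_wls(X, y, w, i=0)
        assert hat_row @ y == pytest.approx(fitted0, rel=1e-10)


class TestFitGwr:
    def test_flat_kernel_equals_ols_everywhere(self):
        ds, _ = simulate_stationary_world(150, 0.5, 1.2, 0.3, seed=6)
        fit = fit_gwr(ds, KernelSpec(kind="flat"))
        ols = fit_ols(ds)
        assert np.max(np.abs(fit.beta0_hat - ols.beta0)) < 1e-8
        assert np.max(np.abs(fit.beta1_hat - ols.beta1)) < 1e-8
        assert fit.trS == pytest.approx(2.0, abs=1e-9)

    def test_zero_noise_constant_world_exact(self):
        ds, _ = simulate_stationary_world(100, 0.3, 1.5, 0.0, seed=7,
                                          pop_logmean=0.0, pop_logsd=0.3)
        fit = fit_gwr(ds, KernelSpec(k=20))
        np.testing.assert_allclose(fit.beta1_hat, 1.5, atol=1e-8)
        assert fit.rss < 1e-12

    def test_sign_recovery_zero_noise_nonstationary(self, small_world):
        # interior: off the grid edge and away from the zero-crossing of the
        # slope surface, where the sign is undefined and any estimate mixes
        # both flanks
        ds, truth = small_world
        fit = fit_gwr(ds, KernelSpec(k=8))
        interior = ((np.abs(ds.lon) <= 6.0) & (np.abs(ds.lat) <= 6.0)
                    & (np.abs(truth.beta1) > 0.75))
        agree = np.sign(fit.beta1_hat[interior]) == np.sign(truth.beta1[interior])
        assert agree.mean() >= 0.95

    def test_complexity_bounds(self, noisy_world):
        ds, _ = noisy_world
        fit = fit_gwr(ds, KernelSpec(fraction=0.1))
        assert 2.0 <= fit.trS <= ds.n
        assert fit.p_eff >= 2.0
        assert np.all(fit.local_r2[np.isfinite(fit.local_r2)] <= 1.0 + 1e-12)

    def test_deterministic(self, noisy_world):
        ds, _ = noisy_world
        f1 = fit_gwr(ds, KernelSpec(k=30))
        f2 = fit_gwr(ds, KernelSpec(k=30))
        np.testing.assert_array_equal(f1.beta1_hat, f2.beta1_hat)


class TestAicc:
    def test_ols_limit_reduces_to_classic_small_sample_form(self):
        # trS = p = 2: AICc = AIC + 2(p+1)(p+2)/(n - p - 2)
        n, sigma = 50, 0.7
        p = 2
        aic = 2 * n * math.log(sigma) + n * math.log(2 * math.pi) + n + 2 * (p + 1)
        expected = aic + 2 * (p + 1) * (p + 2) / (n - p - 2)
        assert aicc(n, sigma, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_penalty_monotone_in_trace(self):
        vals = [aicc(100, 0.5, t) for t in np.linspace(2, 60, 20)]
        assert np.all(np.diff(vals) > 0)

    def test_calculator_check(self):
        # independent hand evaluation: 200 ln .5 + 100 ln 2pi + 100*110/88
        expected = -138.62943611198907 + 183.78770664093454 + 125.0
        assert aicc(100, 0.5, 10.0) == pytest.approx(expected, abs=1e-8)

    def test_undefined_region_raises(self):
        with pytest.raises(ValueError):
            aicc(10, 0.5, 8.5)


class TestOls:
    def test_exact_line_adj_r2_one(self):
        ds, _ = simulate_stationary_world(50, 0.1, 2.0, 0.0, seed=8,
                                          pop_logmean=0.0, pop_logsd=0.3)
        assert fit_ols(ds).adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_null_world_adj_r2_near_zero(self):
        ds, _ = simulate_stationary_world(2000, 0.5, 0.0, 1.0, seed=9)
        assert abs(fit_ols(ds).adj_r2) < 0.02

    def test_five_point_slope_oracle(self):
        from firegwr.grid_data import build_dataset
        from conftest import make_raw
        x = np.array([1.0, 10.0, 100.0, 1000.0, 31.62])
        yb = np.array([2.0, 3.0, 10.0, 40.0, 6.0])
        ds = build_dataset(make_raw(np.arange(5) * 1.0, np.zeros(5), yb, x), resolution=1.0)
        ols = fit_ols(ds)
        lx, ly = ds.x, ds.y
        slope = np.cov(lx, ly, bias=True)[0, 1] / np.var(lx)
        assert ols.beta1 == pytest.approx(slope, rel=1e-9)

    def test_constant_predictor_rejected(self):
        from firegwr.grid_data import build_dataset
        from conftest import make_raw
        ds = build_dataset(make_raw(np.arange(5) * 1.0, np.zeros(5),
                                    [1, 2, 3, 4, 5], [10, 10, 10, 10, 10]), resolution=1.0)
        with pytest.raises(ValueError):
            fit_ols(ds)


class TestBandwidthSelection:
    def test_golden_matches_exhaustive(self):
        ds, _ = simulate_gwr_world(SyntheticScenario(n_lon=15, n_lat=14, seed=10))
        k_g, prof_g = select_bandwidth(ds, (10, 52), method="golden")
        k_e, prof_e = select_bandwidth(ds, (10, 52), method="exhaustive")
        assert abs(prof_e[k_g] - prof_e[k_e]) <= 2.0

    def test_stationary_world_prefers_largest_bandwidth(self):
        ds, _ = simulate_stationary_world(200, 0.5, 1.0, 0.3, seed=11)
        k_star, prof = select_bandwidth(ds, (10, 49), method="exhaustive")
        assert k_star >= 45

    def test_nonstationary_zero_noise_prefers_small_k(self, small_world):
        ds, _ = small_world
        _, prof = select_bandwidth(ds, (10, ds.n - 1), method="exhaustive")
        assert prof[10] < prof[ds.n - 1]

    def test_empty_range_rejected(self):
        ds, _ = simulate_stationary_world(50, 0.5, 1.0, 0.3, seed=12)
        with pytest.raises(ValueError):
            select_bandwidth(ds, (60, 70))


class TestLocalR2:
    def test_formula_oracle_on_fixture(self, noisy_world):
        ds, _ = noisy_world
        fit = fit_gwr(ds, KernelSpec(k=40))
        D = pairwise_distances_km(ds.lon, ds.lat)
        i = 17
        got = local_r2(ds, fit, i, dist_matrix=D)
        # direct spreadsheet-style evaluation
        from firegwr.gwr import _bandwidths
        b = _bandwidths(D, 40)
        w = np.exp(-0.5 * (D[i] / b[i]) ** 2)
        resid = ds.y - fit.fitted
        ybar = w @ ds.y / w.sum()
        expected = 1 - (w @ resid**2) / (w @ (ds.y - ybar) ** 2)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(fit.local_r2[i], rel=1e-9)

    def test_perfect_fit_gives_one(self):
        ds, _ = simulate_stationary_world(64, 0.3, 1.0, 0.0, seed=13,
                                          pop_logmean=0.0, pop_logsd=0.3)
        fit = fit_gwr(ds, KernelSpec(k=12))
        assert np.nanmin(fit.local_r2) == pytest.approx(1.0, abs=1e-9)
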
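"""Spatial weights, Moran's I, correlograms, OLS and SAR error models."""

import warnings

import numpy as np
import pytest

from traitgrid.spatial import (SpatialWeights, WeightsError,
                               _sar_grams, _sar_profile_loglik, build_design,
                               build_weights, correlogram, morans_i,
                               nagelkerke_r2, ols_fit,
                               predict_percentile_curves, sar_error_fit)
from traitgrid.synthetic import generate_sar_response


def brute_force_moran(values, W):
    z = values - values.mean()
    n = z.size
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
    return n / W.sum() * num / (z @ z).sum()


class TestWeights:
    def test_two_cells_row_standardised(self):
        w = build_weights(np.array([[0.0, 0.0], [100_000.0, 0.0]]))
        assert w.weights[0][0] == 1.0 and w.weights[1][0] == 1.0

    def test_interior_lattice_cell_has_12_neighbours_at_200km(self):
        xs, ys = np.meshgrid(np.arange(7), np.arange(7))
        cent = np.column_stack([xs.ravel(), ys.ravel()]) * 100_000.0
        w = build_weights(cent, 200_000.0, "binary")
        centre = 3 * 7 + 3
        assert w.neighbors[centre].size == 12  # rook + diagonal + distance-2

    def test_threshold_below_min_distance_raises(self):
        with pytest.raises(WeightsError, match="no spatial structure"):
            build_weights(np.array([[0.0, 0.0], [100_000.0, 0.0]]), 50_000.0)

    def test_neighbor_relation_symmetric_no_self(self, lattice_10x10):
        _, w = lattice_10x10
        for i, idx in enumerate(w.neighbors):
            assert i not in idx
            for j in idx:
                assert i in w.neighbors[j]

    def test_row_standardised_rows_sum_to_one(self, lattice_10x10):
        _, w = lattice_10x10
        for wrow in w.weights:
            if wrow.size:
                assert wrow.sum() == pytest.approx(1.0, abs=1e-12)

    def test_triplet_export_reconstructs_dense(self, lattice_10x10):
        _, w = lattice_10x10
        dense = np.zeros((w.n, w.n))
        for i, j, wij in w.to_triplets():
            dense[i, j] = wij
        np.testing.assert_array_equal(dense, w.dense())

    def test_subset_restandardises(self):
        cent = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [10.0, 0.0]])
        w = build_weights(cent, 1.5, "row_standardised")
        assert w.n_isolated == 1
        sub, keep = w.nonisolated_subset()
        assert list(keep) == [0, 1, 2]
        assert all(r.sum() == pytest.approx(1.0) for r in sub.weights)


class TestMoran:
    def test_antithetic_pair_is_minus_one(self):
        w = build_weights(np.array([[0.0, 0.0], [1.0, 0.0]]), 2.0, "binary")
        res = morans_i(np.array([1.0, -1.0]), w)
        assert res.i_stat == pytest.approx(-1.0)

    def test_expected_value_is_analytic_null_mean(self, lattice_10x10):
        _, w = lattice_10x10
        res = morans_i(np.random.default_rng(0).normal(size=100), w)
        assert res.expected == -1.0 / 99.0

    def test_constant_values_rejected(self, lattice_10x10):
        _, w = lattice_10x10
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(np.ones(100), w)

    def test_matches_double_loop_oracle(self, lattice_10x10):
        _, w = lattice_10x10
        rng = np.random.default_rng(23)
        W = w.dense()
        for _ in range(50):
            x = rng.normal(size=100)
            res = morans_i(x, w)
            assert res.i_stat == pytest.approx(brute_force_moran(x, W),
                                               abs=1e-12)

    def test_permutation_p_consistent_with_analytic(self, lattice_10x10):
        _, w = lattice_10x10
        rng = np.random.default_rng(3)
        # strongly autocorrelated field from the SAR process itself
        x = np.linalg.solve(np.eye(w.n) - 0.9 * w.dense(),
                            rng.normal(size=100))
        analytic = morans_i(x, w)
        perm = morans_i(x, w, permutations=999, seed=1)
        assert perm.i_stat == analytic.i_stat
        assert perm.p_value < 0.05 and analytic.p_value < 0.05


class TestCorrelogram:
    def test_single_band_collapses_to_global_moran(self, lattice_10x10):
        cent, _ = lattice_10x10
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        bands = correlogram(x, cent, n_classes=1, class_width=1e9)
        w_all = build_weights(cent, 1e9, "binary")
        assert bands[0].i_stat == pytest.approx(morans_i(x, w_all).i_stat,
                                                abs=1e-12)

    def test_white_noise_rarely_exceeds_z3_anywhere(self, lattice_10x10):
        cent, _ = lattice_10x10
        rng = np.random.default_rng(100)
        ok = 0
        n_runs = 200
        for _ in range(n_runs):
            x = rng.normal(size=100)
            bands = correlogram(x, cent, n_classes=8, class_width=100_000.0)
            zs = [abs(b.z) for b in bands if np.isfinite(b.z)]
            ok += max(zs) < 3.0
        assert ok / n_runs >= 0.95

    def test_smoothed_field_positive_short_range_declining(self):
        from scipy.ndimage import gaussian_filter

        xs, ys = np.meshgrid(np.arange(15), np.arange(15))
        cent = np.column_stack([xs.ravel(), ys.ravel()]) * 100_000.0
        rng = np.random.default_rng(6)
        field = gaussian_filter(rng.normal(size=(15, 15)), 2.0, mode="reflect")
        bands = correlogram(field.ravel(), cent, n_classes=8,
                            class_width=100_000.0)
        finite = [b for b in bands if np.isfinite(b.i_stat)]
        assert finite[0].i_stat > 0.3
        assert finite[-1].i_stat < finite[0].i_stat

    def test_empty_band_reported_missing(self, lattice_10x10):
        cent, _ = lattice_10x10
        bands = correlogram(np.random.default_rng(1).normal(size=100), cent,
                            n_classes=2, class_width=50_000.0)
        assert bands[0].n_pairs == 0 and np.isnan(bands[0].i_stat)


class TestOLS:
    def test_exact_linear_data_recovered(self):
        rng = np.random.default_rng(2)
        X, names = build_design(rng.uniform(0, 4, 50), rng.uniform(0, 5, 50))
        beta = np.array([1.0, -0.5, 0.2, 0.05])
        fit = ols_fit(X @ beta, X, names)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-10)
        assert fit.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        X, names = build_design(rng.uniform(0, 4, 80), rng.uniform(0, 5, 80))
        y = rng.normal(size=80)
        fit = ols_fit(y, X, names)
        oracle = np.linalg.inv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-9)
        # residuals orthogonal to the design
        np.testing.assert_allclose(X.T @ fit.residuals, 0.0, atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        x = np.linspace(0, 1, 30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            ols_fit(np.random.default_rng(0).normal(size=30), X,
                    ["intercept", "a", "a_copy"])


class TestSARErrorModel:
    def test_lambda_zero_submodel_equals_ols(self, lattice_20x20):
        _, w = lattice_20x20
        rng = np.random.default_rng(31)
        n = w.n
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = generate_sar_response(X, w, [1.0, 0.5, -0.3, 0.1], 0.0, 1.0, seed=4)
        sar = sar_error_fit(y, X, w, fixed_lambda=0.0)
        ols = ols_fit(y, X)
        np.testing.assert_allclose(sar.beta, ols.beta, atol=1e-6)
        assert sar.log_lik == pytest.approx(ols.log_lik, abs=1e-6)

    def test_eigenvalue_logdet_equals_direct_determinant(self):
        xs, ys = np.meshgrid(np.arange(7), np.arange(7))
        cent = np.column_stack([xs.ravel(), ys.ravel()])[:50] * 100_000.0
        for style in ("binary", "row_standardised"):
            w = build_weights(cent, 150_000.0, style)
            if w.n_isolated:
                w, _ = w.nonisolated_subset()
            eigs = w.eigenvalues()
            W = w.dense()
            lo, hi = 1.0 / eigs.min(), 1.0 / eigs.max()
            for lam in (0.6 * hi, 0.0, 0.4 * lo, 0.9 * lo):
                direct = np.linalg.slogdet(np.eye(w.n) - lam * W)[1]
                via_eigs = np.sum(np.log(1.0 - lam * eigs))
                assert via_eigs == pytest.approx(direct, abs=1e-8)

    def test_profile_grid_oracle_agrees_with_optimiser(self, lattice_20x20):
        _, w = lattice_20x20
        rng = np.random.default_rng(77)
        n = w.n
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = generate_sar_response(X, w, [1.0, 0.5, -0.3, 0.1], 0.7, 1.0, seed=5)
        fit = sar_error_fit(y, X, w)
        grams = _sar_grams(y, X, w.dense())
        eigs = w.eigenvalues()
        lo, hi = fit.lam_bounds
        grid = np.arange(lo + 1e-4, hi - 1e-4, 1e-4)
        lls = np.array([_sar_profile_loglik(l, grams, eigs, n, 4)[0]
                        for l in grid])
        assert abs(grid[np.argmax(lls)] - fit.lam) < 2e-4

    def test_parameter_recovery_30_seeds(self, lattice_20x20):
        _, w = lattice_20x20
        beta = np.array([1.0, 0.5, -0.3, 0.1])
        lams, betas = [], []
        for s in range(30):
            rng = np.random.default_rng(1000 + s)
            X = np.column_stack([np.ones(w.n), rng.normal(size=(w.n, 3))])
            y = generate_sar_response(X, w, beta, 0.7, 1.0, seed=s)
            fit = sar_error_fit(y, X, w)
            lams.append(fit.lam)
            betas.append(fit.beta)
        assert 0.6 < np.median(lams) < 0.8
        assert np.abs(np.median(betas, axis=0) - beta).max() < 0.05

    def test_loglik_at_optimum_dominates_lambda_zero(self, lattice_20x20):
        _, w = lattice_20x20
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(w.n), rng.normal(size=(w.n, 3))])
        y = generate_sar_response(X, w, [1.0, 0.5, -0.3, 0.1], 0.5, 1.0, seed=9)
        fit = sar_error_fit(y, X, w)
        ols = ols_fit(y, X)
        assert fit.log_lik >= ols.log_lik - 1e-8
        assert fit.lam_bounds[0] < fit.lam < fit.lam_bounds[1]
        assert 0.0 <= fit.pseudo_r2 < 1.0

    def test_isolated_cells_rejected(self):
        cent = np.vstack([np.column_stack([np.arange(12), np.zeros(12)]),
                          [100.0, 100.0]])
        w = build_weights(cent, 1.5, "binary")
        y = np.random.default_rng(0).normal(size=13)
        X = np.column_stack([np.ones(13), np.arange(13.0)])
        with pytest.raises(WeightsError, match="neighbour"):
            sar_error_fit(y, X, w)

    def test_sar_innovations_whiter_than_ols_residuals(self, lattice_10x10):
        """Spatial filtering pulls residual Moran's I toward its null mean."""
        cent, w = lattice_10x10
        wins = 0
        n_sims = 100
        e_i = -1.0 / (w.n - 1)
        for s in range(n_sims):
            rng = np.random.default_rng(5000 + s)
            X = np.column_stack([np.ones(w.n), rng.normal(size=(w.n, 1))])
            y = generate_sar_response(X, w, [1.0, 0.5], 0.7, 1.0, seed=s)
            ols = ols_fit(y, X)
            sar = sar_error_fit(y, X, w)
            i_ols = morans_i(ols.residuals, w).i_stat
            i_sar = morans_i(sar.innovations, w).i_stat
            wins += abs(i_sar - e_i) < abs(i_ols - e_i)
        assert wins / n_sims >= 0.9


class TestNagelkerke:
    def test_no_improvement_gives_zero(self):
        assert nagelkerke_r2(-50.0, -50.0, 100) == 0.0

    def test_gaussian_ols_special_case_matches_algebraic_oracle(self):
        rng = np.random.default_rng(19)
        X, names = build_design(rng.uniform(0, 4, 60), rng.uniform(0, 5, 60))
        beta = np.array([0.5, -0.2, 0.1, 0.02])
        y = X @ beta + rng.normal(0, 0.3, 60)
        fit = ols_fit(y, X, names)
        from traitgrid.spatial import intercept_only_loglik

        ll0 = intercept_only_loglik(y)
        got = nagelkerke_r2(fit.log_lik, ll0, 60)
        # Cox-Snell for Gaussian ML equals the classical R^2
        r2_classic = 1.0 - (fit.residuals @ fit.residuals) / (
            ((y - y.mean()) ** 2).sum())
        expected = r2_classic / (1.0 - np.exp((2.0 / 60) * ll0))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_model_loglik(self):
        vals = [nagelkerke_r2(ll, -80.0, 50) for ll in (-80.0, -60.0, -40.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_model_below_null_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-51.0, -50.0, 100)


class TestPredictionCurves:
    def _fit(self, interaction_beta):
        rng = np.random.default_rng(30)
        X, names = build_design(rng.uniform(0, 4, 200), rng.uniform(0, 5, 200))
        beta = np.array([1.0, -0.1, 0.05, interaction_beta])
        y = X @ beta  # noiseless: fitted coefficients exact
        return ols_fit(y, X, names), X

    def test_zero_interaction_gives_parallel_curves(self):
        fit, _ = self._fit(0.0)
        curves = predict_percentile_curves(fit, np.linspace(0, 4, 10),
                                           {"lo": 1.0, "hi": 4.0})
        (_, _, _, p_lo), (_, _, _, p_hi) = curves
        np.testing.assert_allclose(np.diff(p_hi - p_lo), 0.0, atol=1e-10)

    def test_hand_computed_dot_products(self):
        fit, _ = self._fit(0.03)
        vpd_pts = np.array([0.5, 2.0, 3.5])
        (label, lai, _, pred), = predict_percentile_curves(
            fit, vpd_pts, {"fixed": 2.5})
        b = dict(zip(fit.names, fit.beta))
        expected = (b["intercept"] + b["vpd"] * vpd_pts + b["lai"] * 2.5
                    + b["vpd:lai"] * vpd_pts * 2.5)
        np.testing.assert_allclose(pred, expected, atol=1e-12)

    def test_mean_lai_curve_passes_through_mean_prediction(self):
        # exact when the fitted interaction is zero
        fit, X = self._fit(0.0)
        vpd_mean = X[:, 1].mean()
        lai_mean = X[:, 2].mean()
        (_, _, _, pred), = predict_percentile_curves(
            fit, np.array([vpd_mean]), {"mean": lai_mean})
        assert pred[0] == pytest.approx((X @ fit.beta).mean(), abs=1e-10)

    def test_interaction_required(self):
        rng = np.random.default_rng(1)
        X, names = build_design(rng.uniform(0, 4, 30), rng.uniform(0, 5, 30),
                                interaction=False)
        fit = ols_fit(rng.normal(size=30), X, names)
        with pytest.raises(ValueError, match="interaction"):
            predict_percentile_curves(fit, np.linspace(0, 4, 5), {"m": 1.0})
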
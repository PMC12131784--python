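"""Shape-model construction, fitting, regularization, sampling, sweeps."""

import numpy as np
import pytest
from scipy import optimize, stats

from mbssm.model import ShapeModel, ShapeModelResults, build_ssm
from mbssm.metrics import avg_point_distance
from mbssm.shapes import BlockLayout


def centered_rows(rng, n, m):
    """Random training matrix with per-row centroid at the origin."""
    pts = rng.normal(size=(n, m, 3)) * 5
    pts -= pts.mean(axis=1, keepdims=True)
    return pts.reshape(n, 3 * m)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    data = centered_rows(rng, 12, 20)
    return build_ssm(data), data


class TestBuild:
    def test_two_distinct_shapes_one_component(self, rng):
        data = centered_rows(rng, 2, 10)
        results = build_ssm(data)
        assert results.n_components == 1

    def test_identical_shapes_zero_components(self, rng):
        row = centered_rows(rng, 1, 10)[0]
        results = build_ssm(np.tile(row, (5, 1)))
        assert results.n_components == 0

    def test_component_count_capped_at_n_minus_1(self, rng):
        data = centered_rows(rng, 8, 30)  # 90 dims >> 7
        assert build_ssm(data).n_components == 7

    def test_matches_dense_covariance_eigendecomposition(self, rng):
        data = centered_rows(rng, 15, 12)  # 36 dims
        results = build_ssm(data)
        cov = np.cov(data, rowvar=False, ddof=1)
        w, v = np.linalg.eigh(cov)
        w = w[::-1][: results.n_components]
        assert np.allclose(results.eigenvalues, w, rtol=1e-8)
        # eigenvectors agree up to sign
        v = v[:, ::-1][:, : results.n_components]
        overlap = np.abs(np.sum(results.components * v, axis=0))
        assert np.allclose(overlap, 1.0, atol=1e-8)

    def test_orthonormal_columns_and_sorted_eigenvalues(self, fitted):
        results, _ = fitted
        gram = results.components.T @ results.components
        assert np.max(np.abs(gram - np.eye(results.n_components))) < 1e-8
        assert np.all(np.diff(results.eigenvalues) <= 1e-12)

    def test_sign_convention_deterministic(self, fitted):
        results, _ = fitted
        for j in range(results.n_components):
            col = results.components[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_rejects_uncentered_and_tiny_input(self, rng):
        data = rng.normal(size=(5, 30)) + 3.0
        with pytest.raises(ValueError, match="centered"):
            ShapeModel(data)
        with pytest.raises(ValueError):
            ShapeModel(centered_rows(rng, 1, 5))

    def test_mean_per_block_centroid_vanishes(self, small_cohort):
        results = ShapeModel.from_cohort(small_cohort).fit()
        for blk in results.layout.blocks:
            centroid = results.mean[blk.slice].reshape(-1, 3).mean(axis=0)
            assert np.max(np.abs(centroid)) < 1e-6


class TestFitParams:
    def test_mean_maps_to_zero(self, fitted):
        results, _ = fitted
        b, residual = results.fit_params(results.mean)
        assert np.allclose(b, 0) and residual < 1e-10

    def test_single_mode_displacement_recovered(self, fitted):
        results, _ = fitted
        amp = 2 * np.sqrt(results.eigenvalues[0])
        x = results.mean + amp * results.components[:, 0]
        b, _ = results.fit_params(x)
        expected = np.zeros(results.n_components)
        expected[0] = amp
        assert np.allclose(b, expected, atol=1e-10)

    def test_training_members_reconstructed_exactly(self, fitted):
        results, data = fitted
        for row in data:
            fit = results.fit_shape(row, regularize=False)
            assert avg_point_distance(fit.reconstruction, row) < 1e-8

    def test_parameter_recovery_from_sampled_shapes(self, fitted, rng):
        results, _ = fitted
        shape, b = results.sample_shape(rng, results.n_components)
        b_fit, residual = results.fit_params(shape)
        assert np.allclose(b_fit, b, atol=1e-8) and residual < 1e-8

    def test_length_mismatch(self, fitted):
        with pytest.raises(ValueError):
            fitted[0].fit_params(np.zeros(7))


class TestRegularization:
    def test_zero_is_plausible(self, fitted):
        results, _ = fitted
        fit = results.regularize_params(np.zeros(results.n_components))
        assert fit.scale_s == 1.0
        assert np.allclose(fit.b_hat, 0)
        assert np.allclose(fit.reconstruction, results.mean)

    def test_single_large_coefficient_clipped_no_scaling(self, fitted):
        results, _ = fitted
        b = np.zeros(results.n_components)
        b[0] = 5 * np.sqrt(results.eigenvalues[0])
        fit = results.regularize_params(b)
        assert fit.b_hat[0] == pytest.approx(3 * np.sqrt(results.eigenvalues[0]))
        # post-clip Mahalanobis sum is 9, far inside the chi-squared bound
        assert stats.chi2.ppf(0.997, results.dof) > 9
        assert fit.scale_s == 1.0

    def test_all_modes_at_clip_bound_scaled_into_ellipsoid(self, fitted):
        results, _ = fitted
        r = results.n_components
        b = 3 * np.sqrt(results.eigenvalues)
        fit = results.regularize_params(b)
        bound = stats.chi2.ppf(0.997, results.dof)
        assert 9 * r > bound  # constraint binds for this model
        assert fit.scale_s == pytest.approx(np.sqrt(bound / (9 * r)))
        assert fit.mahalanobis_q == pytest.approx(bound)

    def test_closed_form_matches_numeric_qp_oracle(self, fitted, rng):
        """min (s-1)^2 s.t. sum (s b_i)^2 / lam_i <= chi2 bound, solved by a
        generic constrained optimizer, agrees with the closed form."""
        results, _ = fitted
        lam = results.eigenvalues
        bound = stats.chi2.ppf(0.997, results.dof)
        for _ in range(100):
            b = rng.normal(size=lam.size) * np.sqrt(lam) * rng.uniform(0.5, 4)
            b_clip = np.clip(b, -3 * np.sqrt(lam), 3 * np.sqrt(lam))
            q = np.sum(b_clip**2 / lam)
            res = optimize.minimize(
                lambda s: (s[0] - 1) ** 2,
                x0=[1.0],
                constraints=[{"type": "ineq", "fun": lambda s: bound - s[0] ** 2 * q}],
                method="SLSQP",
                tol=1e-14,
            )
            fit = results.regularize_params(b)
            assert fit.scale_s == pytest.approx(min(1.0, abs(res.x[0])), abs=1e-6)

    def test_regularized_fit_always_inside_ellipsoid(self, fitted, rng):
        results, data = fitted
        bound = stats.chi2.ppf(0.997, results.dof)
        for _ in range(50):
            x = rng.normal(size=data.shape[1]) * 8
            x = (x.reshape(-1, 3) - x.reshape(-1, 3).mean(axis=0)).reshape(-1)
            fit = results.fit_shape(x)
            assert fit.mahalanobis_q <= bound + 1e-6
            assert np.all(np.abs(fit.b_hat) <= 3 * np.sqrt(results.eigenvalues) + 1e-9)


class TestReconstructSample:
    def test_reconstruct_partial_coefficients(self, fitted):
        results, _ = fitted
        y = results.reconstruct(np.array([1.0]))
        assert np.allclose(y, results.mean + results.components[:, 0])
        with pytest.raises(ValueError):
            results.reconstruct(np.zeros(results.n_components + 1))

    def test_sample_shape_bounds_and_determinism(self, fitted):
        results, _ = fitted
        with pytest.raises(ValueError):
            results.sample_shape(np.random.default_rng(0), 0)
        s1, b1 = results.sample_shape(np.random.default_rng(42), 3)
        s2, b2 = results.sample_shape(np.random.default_rng(42), 3)
        assert np.array_equal(s1, s2) and np.array_equal(b1, b2)
        assert b1.size == 3

    def test_sampled_coefficient_variance_matches_eigenvalue(self, fitted):
        results, _ = fitted
        b = results.sample_coefficients(np.random.default_rng(7), 10_000, 2)
        assert np.var(b[:, 0]) == pytest.approx(results.eigenvalues[0], rel=0.05)


class TestCompactnessSweep:
    def test_compactness_full_is_one_and_monotone(self, fitted):
        results, _ = fitted
        values = [results.compactness(k) for k in range(1, results.n_components + 1)]
        assert values[-1] == pytest.approx(1.0)
        assert np.all(np.diff(values) >= 0)

    def test_equal_eigenvalues_quarter(self):
        layout = BlockLayout.from_counts([("b", 2)])
        results = ShapeModelResults(np.zeros(6), np.eye(6, 4), np.ones(4), 5, layout)
        assert results.compactness(1) == pytest.approx(0.25)

    def test_geometric_spectrum_hand_ratio(self):
        lam = 4.0 * 0.5 ** np.arange(3)  # 4, 2, 1
        layout = BlockLayout.from_counts([("b", 2)])
        results = ShapeModelResults(np.zeros(6), np.eye(6, 3), lam, 6, layout)
        assert results.compactness(2) == pytest.approx(6.0 / 7.0, abs=1e-12)

    def test_mode_sweep_center_mirror_and_extent(self, fitted):
        results, _ = fitted
        steps = results.mode_sweep(1, n_steps=5)
        b_vals = [s[0] for s in steps]
        limit = 3 * np.sqrt(results.eigenvalues[0])
        assert b_vals[0] == pytest.approx(-limit) and b_vals[-1] == pytest.approx(limit)
        mid = steps[2]
        assert np.allclose(mid[1], results.mean) and np.allclose(mid[2], 0)
        left, right = steps[0][1] - results.mean, steps[-1][1] - results.mean
        assert np.allclose(left, -right, atol=1e-10)
        phi_norms = np.linalg.norm(results.components[:, 0].reshape(-1, 3), axis=1)
        assert steps[-1][2].max() == pytest.approx(limit * phi_norms.max())
        with pytest.raises(ValueError):
            results.mode_sweep(0)
        with pytest.raises(ValueError):
            results.mode_sweep(1, n_steps=1)


class TestResultsSurface:
    def test_truncate_view(self, fitted):
        results, _ = fitted
        t = results.truncate(3)
        assert t.n_components == 3 and t.n_train == results.n_train
        assert np.array_equal(t.eigenvalues, results.eigenvalues[:3])

    def test_summary_mentions_key_quantities(self, fitted):
        results, _ = fitted
        text = results.summary()
        assert str(results.n_train) in text and "mode" in text

    def test_serialization_roundtrip(self, fitted, tmp_path):
        results, _ = fitted
        path = tmp_path / "model.npz"
        results.save(path)
        back = ShapeModelResults.load(path)
        assert np.array_equal(back.mean, results.mean)
        assert np.array_equal(back.components, results.components)
        assert np.array_equal(back.eigenvalues, results.eigenvalues)
        assert back.n_train == results.n_train
        assert back.layout == results.layout
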
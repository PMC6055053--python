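import numpy as np
import pytest

from spectrafuse import (
    ParameterError,
    SpectralMap,
    ValidationError,
    cross_correlation,
    cumulative_curve,
    fuse_blocks,
    pca,
    rgb_composite,
    split_loadings,
    weight_sweep,
)
from tests.conftest import grid_coords


def pca_oracle(x, k):
    """Independent oracle: eigendecomposition of the covariance matrix."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    explained = evals / evals.sum()
    scores = xc @ evecs
    return explained[:k], evecs[:, :k], scores[:, :k]


def aligned_blocks(rng, n=40, pa=6, pb=4):
    coords = grid_coords(8, 5, 75.0)[:n]
    a = SpectralMap(rng.normal(size=(n, pa)), 400.0 + np.arange(pa),
                    coords, "raman")
    b = SpectralMap(rng.uniform(0.1, 1.0, (n, pb)), 500.0 + np.arange(pb),
                    coords, "maldi")
    return a, b


class TestPca:
    def test_single_varying_column(self, rng):
        x = np.ones((20, 5))
        x[:, 0] = rng.normal(size=20)
        model = pca(x, 1)
        np.testing.assert_allclose(model.explained, [1.0], atol=1e-12)

    def test_monte_carlo_anisotropic_gaussian(self):
        rng = np.random.default_rng(2024)
        x = rng.normal(0.0, [2.0, 1.0], size=(100_000, 2))
        model = pca(x, 2)
        np.testing.assert_allclose(model.explained, [0.8, 0.2], atol=0.01)

    def test_matches_eigh_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            x = rng.normal(size=(50, 30))
            model = pca(x, 10)
            exp_o, load_o, scores_o = pca_oracle(x, 10)
            np.testing.assert_allclose(model.explained, exp_o, atol=1e-8)
            # match up to per-column sign
            sign = np.sign(np.sum(model.loadings * load_o, axis=0))
            np.testing.assert_allclose(model.loadings, load_o * sign, atol=1e-8)
            np.testing.assert_allclose(model.scores, scores_o * sign, atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        model = pca(rng.normal(size=(30, 12)), 8)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-8)

    def test_sign_convention(self, rng):
        model = pca(rng.normal(size=(25, 9)), 5)
        for j in range(5):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_global_scaling_invariance(self, rng):
        x = rng.normal(size=(30, 8))
        e1 = pca(x, 5).explained
        e2 = pca(7.3 * x, 5).explained
        np.testing.assert_allclose(e1, e2, atol=1e-12)

    def test_k_out_of_range(self, rng):
        with pytest.raises(ParameterError):
            pca(rng.normal(size=(10, 5)), 10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            pca(np.ones((10, 4)), 2)


class TestCumulativeCurve:
    def test_running_sum(self, rng):
        x = rng.normal(0.0, [5.0, 3.0, 2.0], size=(2000, 3))
        model = pca(x, 3)
        np.testing.assert_allclose(cumulative_curve(model, 3),
                                   np.cumsum(model.explained))

    def test_k_one(self, rng):
        model = pca(rng.normal(size=(20, 6)), 4)
        np.testing.assert_allclose(cumulative_curve(model, 1),
                                   [model.explained[0]])

    def test_full_rank_reaches_one(self, rng):
        x = rng.normal(size=(30, 6))
        model = pca(x, 6)
        assert abs(model.cumulative[-1] - 1.0) < 1e-10

    def test_monotone_bounded(self, rng):
        model = pca(rng.normal(size=(25, 10)), 8)
        curve = cumulative_curve(model)
        assert np.all(np.diff(curve) >= -1e-15)
        assert curve[-1] <= 1.0 + 1e-12


class TestWeightSweep:
    def test_unit_coefficient_matches_unweighted(self, rng):
        a, b = aligned_blocks(rng)
        sweep = weight_sweep(a, b, np.array([1.0, 2.0]), k=5)
        unweighted = pca(np.hstack([a.intensities, b.intensities]), 5)
        np.testing.assert_array_equal(sweep.curves[0], unweighted.cumulative)

    def test_large_coefficient_limit(self, rng):
        a, b = aligned_blocks(rng)
        sweep = weight_sweep(a, b, np.array([1e6]), k=3)
        b_alone = pca(b.intensities, 3)
        assert abs(sweep.curves[0][0] - b_alone.cumulative[0]) < 1e-3

    def test_weighting_changes_spectrum(self, rng):
        a, b = aligned_blocks(rng)
        sweep = weight_sweep(a, b, np.array([1.0, 20.0]), k=5)
        assert not np.allclose(sweep.curves[0], sweep.curves[1])

    def test_curves_nondecreasing_in_k(self, rng):
        a, b = aligned_blocks(rng)
        sweep = weight_sweep(a, b, np.arange(1.0, 6.0), k=6)
        assert np.all(np.diff(sweep.curves, axis=1) >= -1e-15)

    def test_argmin_per_k(self, rng):
        a, b = aligned_blocks(rng)
        coeffs = np.arange(1.0, 8.0)
        sweep = weight_sweep(a, b, coeffs, k=4)
        for j in range(4):
            expected = coeffs[np.argmin(sweep.curves[:, j])]
            assert sweep.argmin_per_k[j] == expected

    def test_negative_coefficient_rejected(self, rng):
        a, b = aligned_blocks(rng)
        with pytest.raises(ParameterError):
            weight_sweep(a, b, np.array([-1.0]), k=3)


class TestSplitLoadings:
    def test_part_lengths_and_concatenation(self, rng):
        a, b = aligned_blocks(rng, pa=5, pb=3)
        fused = fuse_blocks(a, b, 2.0)
        model = pca(fused.matrix, 4)
        parts = split_loadings(model, fused)
        r_axis, r_load = parts["raman"]
        m_axis, m_load = parts["maldi"]
        assert r_load.shape == (5, 4) and m_load.shape == (3, 4)
        np.testing.assert_array_equal(np.vstack([r_load, m_load]),
                                      model.loadings)
        np.testing.assert_array_equal(r_axis, a.axis)
        np.testing.assert_array_equal(m_axis, b.axis)

    def test_provenance_mismatch(self, rng):
        a, b = aligned_blocks(rng)
        fused = fuse_blocks(a, b, 1.0)
        model = pca(fused.matrix[:, :-1], 3)
        with pytest.raises(ValidationError, match="provenance"):
            split_loadings(model, fused)


class TestRgbComposite:
    def make_model(self, scores):
        class Dummy:
            pass

        m = Dummy()
        m.scores = np.asarray(scores, dtype=float)
        m.n_components = m.scores.shape[1]
        return m

    def test_constant_scores_mid_gray(self):
        coords = grid_coords(4, 3)
        model = self.make_model(np.ones((12, 3)))
        img = rgb_composite(model, coords)
        np.testing.assert_allclose(img, 0.5)

    def test_one_hot_blocks_pure_colors(self):
        coords = grid_coords(3, 1)
        scores = np.eye(3)
        img = rgb_composite(self.make_model(scores), coords)
        assert img.shape == (1, 3, 3)
        for j in range(3):
            assert img[0, j, j] == 1.0

    def test_missing_pixels_gray(self):
        coords = np.array([[0.0, 0.0], [25.0, 0.0], [0.0, 25.0]])  # 2x2 minus 1
        img = rgb_composite(self.make_model(np.eye(3)), coords)
        assert img.shape == (2, 2, 3)
        np.testing.assert_allclose(img[1, 1], 0.5)

    def test_non_grid_coords_rejected(self, rng):
        coords = rng.uniform(0, 100, (7, 2))
        with pytest.raises(ValidationError, match="grid"):
            rgb_composite(self.make_model(rng.normal(size=(7, 3))), coords)

    def test_bad_pcs(self, rng):
        coords = grid_coords(4, 3)
        model = self.make_model(rng.normal(size=(12, 3)))
        with pytest.raises(ParameterError):
            rgb_composite(model, coords, pcs=(0, 1, 5))


class TestCrossCorrelation:
    def test_identical_column_r_one(self, rng):
        a, b = aligned_blocks(rng)
        b.intensities[:, 0] = a.intensities[:, 2]
        r = cross_correlation(a, b)
        assert abs(r[2, 0] - 1.0) < 1e-12

    def test_negated_column_r_minus_one(self, rng):
        a, b = aligned_blocks(rng)
        b.intensities[:, 1] = -a.intensities[:, 3]
        r = cross_correlation(a, b)
        assert abs(r[3, 1] + 1.0) < 1e-12

    def test_null_distribution(self):
        rng = np.random.default_rng(77)
        n = 1000
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        a = SpectralMap(rng.normal(size=(n, 20)), 400.0 + np.arange(20),
                        coords, "raman")
        b = SpectralMap(rng.normal(size=(n, 15)), 500.0 + np.arange(15),
                        coords, "maldi")
        r = cross_correlation(a, b)
        assert np.mean(np.abs(r) < 0.1) >= 0.99

    def test_constant_channel_is_nan(self, rng):
        a, b = aligned_blocks(rng)
        b.intensities[:, 2] = 4.2
        r = cross_correlation(a, b)
        assert np.all(np.isnan(r[:, 2]))
        assert not np.isnan(r[:, 0]).any()

    def test_too_few_pixels(self, rng):
        coords = grid_coords(2, 1)
        a = SpectralMap(rng.normal(size=(2, 3)), [1.0, 2.0, 3.0], coords, "raman")
        b = SpectralMap(rng.normal(size=(2, 3)), [1.0, 2.0, 3.0], coords, "maldi")
        with pytest.raises(ValidationError, match="3 shared pixels"):
            cross_correlation(a, b)
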
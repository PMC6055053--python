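import numpy as np
import pytest

from spectrafuse import (
    ParameterError,
    PeakList,
    SpectralMap,
    ValidationError,
    bin_peaks,
    estimate_noise,
    normalize_ms,
    phase_correct,
    pick_peaks,
    tic_normalize,
)
from spectrafuse import raman


def profile_map(intens, axis, pitch=75.0):
    n = intens.shape[0]
    coords = np.column_stack([np.arange(n, dtype=float) * pitch, np.zeros(n)])
    return SpectralMap(intens, axis, coords, "maldi")


class TestEstimateNoise:
    def test_constant_spectrum_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert estimate_noise(np.full(20, 7.0)) == 0.0

    def test_gaussian_noise_calibrated(self):
        rng = np.random.default_rng(7)
        y = rng.normal(0.0, 1.0, 100_000)
        assert 0.95 <= estimate_noise(y) <= 1.05

    def test_robust_to_sparse_peaks(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0.0, 1.0, 5000)
        y[[100, 900, 2500, 3300, 4700]] += 500.0
        assert abs(estimate_noise(y) - 1.0) < 0.1

    def test_too_short(self):
        with pytest.raises(ParameterError):
            estimate_noise(np.ones(5))


class TestPickPeaks:
    def test_all_zeros_empty(self):
        axis = np.linspace(500, 600, 50)
        pl = pick_peaks(axis, np.zeros(50), snr=3.0)
        assert len(pl) == 0

    def test_single_triangular_peak(self):
        axis = np.linspace(500.0, 520.0, 21)
        y = np.zeros(21)
        j = 10
        y[j - 2: j + 3] = [25.0, 50.0, 100.0, 50.0, 25.0]
        pl = pick_peaks(axis, y, snr=3.0)
        assert len(pl) == 1
        assert pl.mz[0] == axis[j]
        assert pl.intensity[0] == 100.0

    def test_known_ions_at_high_snr(self):
        # background-subtracted spectrum: zero-mean noise plus known ions
        rng = np.random.default_rng(11)
        axis = np.arange(500.0, 800.0, 0.05)
        y = rng.normal(0.0, 1.0, axis.size)
        true_mz = np.linspace(520, 780, 10)
        for mz in true_mz:
            y += 20.0 * np.exp(-0.5 * ((axis - mz) / 0.08) ** 2)
        pl = pick_peaks(axis, y, snr=5.0)
        assert len(pl) == 10
        for mz in true_mz:
            assert np.min(np.abs(pl.mz - mz)) <= 0.05 + 1e-9

    def test_sorted_output(self):
        rng = np.random.default_rng(3)
        axis = np.arange(500.0, 600.0, 0.05)
        y = rng.normal(0, 1, axis.size) + 5
        pl = pick_peaks(axis, y, snr=1.0)
        assert np.all(np.diff(pl.mz) > 0)


def ion_profile(axis, positions, heights, width=0.08, shift=0.0):
    y = np.zeros(axis.size)
    for mz, h in zip(positions, heights):
        y += h * np.exp(-0.5 * ((axis - (mz + shift)) / width) ** 2)
    return y


class TestPhaseCorrect:
    axis = np.arange(600.0, 700.0, 0.02)
    anchors = np.array([620.0, 650.0, 680.0])

    def make_map(self, shifts, rng=None):
        rows = []
        for s in shifts:
            y = ion_profile(self.axis, self.anchors, [100.0, 80.0, 90.0], shift=s)
            if rng is not None:
                y = y + rng.normal(0, 0.2, self.axis.size) + 1.0
            rows.append(y)
        return profile_map(np.array(rows), self.axis)

    def test_aligned_data_zero_offsets(self):
        m = self.make_map([0.0] * 4)
        _, model = phase_correct(m, max_shift=0.5, anchors=self.anchors)
        np.testing.assert_allclose(model.offsets, 0.0, atol=1e-9)

    def test_uniform_shift_recovered(self):
        m = self.make_map([0.2] * 6)
        corrected, model = phase_correct(m, max_shift=0.5, anchors=self.anchors)
        np.testing.assert_allclose(model.offsets, -0.2, atol=0.02)
        # corrected peaks sit back on the anchors
        j = np.argmax(corrected.intensities[0])
        assert abs(corrected.axis[j] - 620.0) < 0.05

    def test_random_pixel_shifts_reduced(self):
        rng = np.random.default_rng(21)
        shifts = rng.uniform(-0.3, 0.3, 12)
        m = self.make_map(shifts, rng=rng)
        corrected, model = phase_correct(m, max_shift=0.5, anchors=self.anchors)
        residuals = []
        for i in range(corrected.n_pixels):
            for a in self.anchors:
                lo = np.searchsorted(self.axis, a - 0.5)
                hi = np.searchsorted(self.axis, a + 0.5)
                j = lo + np.argmax(corrected.intensities[i, lo:hi])
                residuals.append(corrected.axis[j] - a)
        rms = np.sqrt(np.mean(np.square(residuals)))
        assert rms < 0.05

    def test_auto_anchor_detection(self):
        m = self.make_map([0.0] * 8)
        _, model = phase_correct(m, max_shift=0.5, anchor_quantile=0.995)
        assert model.anchors.size >= 2

    def test_no_anchors_error(self):
        m = profile_map(np.zeros((4, self.axis.size)) + 1e-12, self.axis)
        with pytest.raises(ValidationError, match="stable intense"):
            phase_correct(m, max_shift=0.5)

    def test_peaklist_input(self):
        lists = [
            PeakList(self.anchors + 0.1, [10.0, 8.0, 9.0], pixel_id=i)
            for i in range(3)
        ]
        corrected, model = phase_correct(lists, max_shift=0.5, anchors=self.anchors)
        np.testing.assert_allclose(model.offsets, -0.1, atol=1e-9)
        np.testing.assert_allclose(corrected[0].mz, self.anchors, atol=1e-9)

    def test_peaklists_require_anchors(self):
        with pytest.raises(ParameterError, match="anchors"):
            phase_correct([PeakList([500.0], [1.0], 0)], max_shift=0.5)


class TestBinPeaks:
    def test_close_peaks_merge(self):
        lists = [PeakList([500.00], [1.0], 0), PeakList([500.05], [1.0], 1)]
        smap, table = bin_peaks(lists, tolerance_ppm=200.0)
        assert table.n_bins == 1

    def test_distant_peaks_split(self):
        lists = [PeakList([500.0], [1.0], 0), PeakList([510.0], [1.0], 1)]
        _, table = bin_peaks(lists, tolerance_ppm=200.0)
        assert table.n_bins == 2

    def test_simulated_ions_exact_recovery(self):
        rng = np.random.default_rng(17)
        true_mz = 600.0 * np.exp(np.arange(30) * 0.002)  # spacing 2000 ppm
        lists = []
        for pix in range(100):
            jitter = rng.normal(0.0, 30e-6, 30) * true_mz  # 30 ppm
            mz = np.sort(true_mz + jitter)
            lists.append(PeakList(mz, rng.uniform(1, 10, 30), pixel_id=pix))
        smap, table = bin_peaks(lists, tolerance_ppm=200.0)
        assert table.n_bins == 30
        rel = np.abs(table.centroids - true_mz) / true_mz
        assert np.max(rel) < 20e-6

    def test_matrix_cell_sums(self):
        lists = [PeakList([500.0, 600.0], [2.0, 3.0], 0),
                 PeakList([500.02, 600.01], [5.0, 7.0], 1)]
        smap, table = bin_peaks(lists, tolerance_ppm=200.0)
        assert smap.intensities.shape == (2, 2)
        np.testing.assert_allclose(smap.intensities, [[2.0, 3.0], [5.0, 7.0]])

    def test_permutation_invariance(self, rng):
        lists = [PeakList(np.sort(rng.uniform(500, 900, 20)),
                          rng.uniform(1, 5, 20), pixel_id=i) for i in range(6)]
        m1, t1 = bin_peaks(lists, 150.0)
        m2, t2 = bin_peaks(list(reversed(lists)), 150.0)
        np.testing.assert_array_equal(t1.centroids, t2.centroids)
        np.testing.assert_array_equal(m1.intensities, m2.intensities)

    def test_bad_tolerance(self):
        with pytest.raises(ParameterError):
            bin_peaks([PeakList([500.0], [1.0], 0)], tolerance_ppm=0.0)

    def test_all_empty_lists(self):
        with pytest.raises(ValidationError):
            bin_peaks([PeakList([], [], 0)], 200.0)

    def test_phase_correction_never_increases_bins(self):
        rng = np.random.default_rng(23)
        anchors = np.array([620.0, 650.0, 680.0])
        ions = np.array([610.0, 630.0, 640.0, 660.0, 670.0, 690.0])
        lists = []
        for pix in range(40):
            shift = rng.uniform(-0.25, 0.25)
            mz = np.sort(np.concatenate([anchors, ions]) + shift)
            lists.append(PeakList(mz, rng.uniform(1, 10, mz.size), pixel_id=pix))
        _, t_raw = bin_peaks(lists, 100.0)
        corrected, _ = phase_correct(lists, max_shift=0.5, anchors=anchors)
        _, t_cor = bin_peaks(corrected, 100.0)
        assert t_cor.n_bins <= t_raw.n_bins


class TestTicNormalize:
    def test_simple_fractions(self):
        m = profile_map(np.array([[2.0, 3.0, 5.0]]), np.array([500.0, 600.0, 700.0]))
        np.testing.assert_allclose(tic_normalize(m).intensities, [[0.2, 0.3, 0.5]])

    def test_equals_l1_normalization_when_nonnegative(self, rng):
        intens = rng.uniform(0.0, 10.0, (5, 12)) + 0.1
        m = profile_map(intens, np.linspace(500, 900, 12))
        out_tic = tic_normalize(m).intensities
        out_l1 = raman.normalize(m, "l1").intensities
        assert np.max(np.abs(out_tic - out_l1)) < 1e-15

    def test_rows_sum_to_one(self, rng):
        intens = rng.uniform(0.1, 5.0, (8, 20))
        out = tic_normalize(profile_map(intens, np.linspace(500, 900, 20)))
        np.testing.assert_allclose(out.intensities.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_tic_pixel_raises(self):
        intens = np.ones((3, 4))
        intens[2] = 0.0
        m = profile_map(intens, np.linspace(500, 800, 4))
        with pytest.raises(ValidationError, match="pixel 2"):
            tic_normalize(m)

    def test_zero_tic_pixel_dropped_when_configured(self):
        intens = np.ones((3, 4))
        intens[2] = 0.0
        m = profile_map(intens, np.linspace(500, 800, 4))
        out = tic_normalize(m, on_zero="drop")
        assert out.n_pixels == 2


class TestNormalizeMs:
    def setup_method(self):
        rng = np.random.default_rng(4)
        self.m = profile_map(rng.uniform(0.5, 5.0, (6, 30)),
                             np.linspace(500, 900, 30))

    def test_tic_default(self):
        out = normalize_ms(self.m)
        np.testing.assert_allclose(out.intensities.sum(axis=1), 1.0)

    def test_rms_unit(self):
        out = normalize_ms(self.m, "rms")
        rms = np.sqrt(np.mean(out.intensities**2, axis=1))
        np.testing.assert_allclose(rms, 1.0, atol=1e-12)

    def test_median_unit(self):
        out = normalize_ms(self.m, "median")
        med = np.median(out.intensities, axis=1)
        np.testing.assert_allclose(med, 1.0, atol=1e-12)

    def test_sqrt_and_log_transforms(self):
        np.testing.assert_allclose(normalize_ms(self.m, "sqrt").intensities,
                                   np.sqrt(self.m.intensities))
        np.testing.assert_allclose(normalize_ms(self.m, "log").intensities,
                                   np.log1p(self.m.intensities))

    def test_noise_normalization(self):
        out = normalize_ms(self.m, "noise")
        assert out.intensities.shape == self.m.intensities.shape

    def test_unknown_method(self):
        with pytest.raises(ParameterError):
            normalize_ms(self.m, "vector")
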
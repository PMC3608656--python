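"""Normalized cross-correlation and peak extraction."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import scanwarp as sw
from scanwarp.errors import InvalidKernelError, NoDetectionsError


def brute_force_pearson(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Independent oracle: double-loop Pearson correlation at every offset."""
    ih, iw = image.shape
    kh, kw = kernel.shape
    out = np.zeros((ih - kh + 1, iw - kw + 1))
    kflat = kernel.ravel().astype(float)
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            win = image[r: r + kh, c: c + kw].ravel().astype(float)
            if win.var() == 0 or kflat.var() == 0:
                out[r, c] = 0.0
            else:
                out[r, c] = np.corrcoef(win, kflat)[0, 1]
    return out


def valid_region(energy: sw.EnergyMap) -> np.ndarray:
    m = energy.valid_mask
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    return energy.values[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]


class TestNormalizedCrossCorrelation:
    @pytest.mark.parametrize("seed,ishape,kshape", [
        (0, (5, 5), (3, 3)),
        (1, (12, 9), (4, 3)),
        (2, (32, 32), (5, 5)),
        (3, (20, 32), (6, 4)),
    ])
    def test_matches_brute_force_oracle(self, seed, ishape, kshape):
        rng = np.random.default_rng(seed)
        image = rng.integers(0, 50, size=ishape).astype(float)
        kern = rng.integers(0, 50, size=kshape).astype(float)
        energy = sw.normalized_cross_correlation(image, sw.MatchKernel(kern))
        np.testing.assert_allclose(
            valid_region(energy), brute_force_pearson(image, kern), atol=1e-9
        )

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(4)
        image = rng.normal(size=(20, 20))
        k = sw.kernel_from_image(image, (5, 7, 6, 5))
        energy = sw.normalized_cross_correlation(image, k)
        # score at the source position (window top-left (5, 7))
        oy, ox = (5 - 1) // 2, (6 - 1) // 2
        assert energy.values[7 + oy, 5 + ox] == pytest.approx(1.0, abs=1e-9)

    def test_negated_kernel_scores_minus_one(self):
        rng = np.random.default_rng(5)
        image = rng.normal(size=(16, 16))
        patch = image[4:9, 6:11]
        energy = sw.normalized_cross_correlation(image, sw.MatchKernel(-patch))
        oy = ox = 2  # (5 - 1) // 2 margin for the 5x5 kernel
        assert energy.values[4 + oy, 6 + ox] == pytest.approx(-1.0, abs=1e-9)

    def test_values_bounded(self):
        rng = np.random.default_rng(6)
        image = rng.normal(size=(40, 40)) * 1e4 + 1e6
        energy = sw.normalized_cross_correlation(
            image, sw.MatchKernel(image[10:17, 10:17])
        )
        assert np.all(np.abs(energy.values) <= 1.0 + 1e-9)

    def test_zero_variance_kernel_rejected(self):
        with pytest.raises(InvalidKernelError):
            sw.MatchKernel(np.ones((4, 4)))

    def test_constant_windows_score_zero(self):
        image = np.zeros((12, 12))
        image[8:11, 8:11] = np.arange(9).reshape(3, 3)
        kern = np.arange(9, dtype=float).reshape(3, 3)
        energy = sw.normalized_cross_correlation(image, sw.MatchKernel(kern))
        assert energy.values[1, 1] == 0.0  # fully flat window

    def test_matches_skimage_match_template(self):
        # independent second route through an established implementation
        from skimage.feature import match_template

        rng = np.random.default_rng(7)
        image = rng.normal(size=(48, 40))
        kern = image[10:19, 12:21]
        ours = valid_region(
            sw.normalized_cross_correlation(image, sw.MatchKernel(kern))
        )
        ref = match_template(image, kern, pad_input=False)
        np.testing.assert_allclose(ours, ref, atol=1e-7)

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(InvalidKernelError):
            sw.normalized_cross_correlation(
                np.zeros((4, 4)), sw.MatchKernel(np.random.default_rng(0).normal(size=(8, 8)))
            )


class TestExtractPeaks:
    def _lattice_energy(self):
        lat = sw.square_lattice(5, 5, 40.0, origin=(60.0, 60.0), unit_side=19)
        pts, _ = sw.generate_lattice_points(lat)
        img = sw.render_lattice_image(pts, 19, (280, 280), fg=1.0, bg=0.0)
        k = sw.kernel_from_image(img, (60 - 13, 60 - 13, 27, 27))
        return pts, sw.normalized_cross_correlation(img, k)

    def test_noiseless_lattice_all_units_found(self):
        pts, energy = self._lattice_energy()
        peaks = sw.extract_peaks(energy, 0.8)
        assert len(peaks) == 25
        d = np.sqrt(((peaks.points[:, None] - pts[None]) ** 2).sum(-1)).min(axis=1)
        assert d.max() < 0.5

    def test_threshold_above_maximum_raises(self):
        # a kernel unrelated to the image never correlates strongly, so a
        # high threshold leaves no connected components
        rng = np.random.default_rng(11)
        image = rng.normal(size=(40, 40))
        kern = rng.normal(size=(7, 7))
        energy = sw.normalized_cross_correlation(image, sw.MatchKernel(kern))
        with pytest.raises(NoDetectionsError) as exc:
            sw.extract_peaks(energy, 0.99)
        assert exc.value.threshold == 0.99

    def test_single_isolated_unit(self):
        img = sw.render_lattice_image(np.array([[30.0, 25.0]]), 9, (64, 56), fg=1.0, bg=0.0)
        k = sw.kernel_from_image(img, (30 - 7, 25 - 7, 15, 15))
        peaks = sw.extract_peaks(sw.normalized_cross_correlation(img, k), 0.5)
        assert len(peaks) == 1
        assert np.hypot(*(peaks.points[0] - [30.0, 25.0])) < 0.5

    @given(st.floats(min_value=0.3, max_value=0.95))
    def test_peak_count_monotone_in_threshold(self, thr):
        _, energy = self._lattice_energy()
        lo = len(sw.extract_peaks(energy, 0.25))
        try:
            hi = len(sw.extract_peaks(energy, thr))
        except NoDetectionsError:
            hi = 0
        assert hi <= lo

    def test_subpixel_flag_gives_integer_positions(self):
        _, energy = self._lattice_energy()
        peaks = sw.extract_peaks(energy, 0.8, subpixel=False)
        frac = peaks.points - np.round(peaks.points)
        np.testing.assert_allclose(frac, 0.0)

    def test_invalid_threshold_rejected(self):
        _, energy = self._lattice_energy()
        with pytest.raises(ValueError):
            sw.extract_peaks(energy, 1.5)

    def test_min_separation_enforced(self):
        _, energy = self._lattice_energy()
        peaks = sw.extract_peaks(energy, 0.3)
        d = np.sqrt(((peaks.points[:, None] - peaks.points[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2.0
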
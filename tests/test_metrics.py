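"""SSIM terms and composition, IoU, accuracy."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from mbada import (
    ConfusionCounts,
    IntensityImage,
    SSIMParams,
    WindowStats,
    accuracy,
    iou,
    mean_ssim,
    mean_ssim_percent,
    ssim_terms,
)


class TestSSIMTerms:
    def test_identical_windows_give_ones(self):
        stats = WindowStats(0.4, 0.4, 0.09, 0.09, 0.09)
        assert ssim_terms(stats) == (1.0, 1.0, 1.0)

    def test_constant_windows(self):
        stats = WindowStats(0.2, 0.8, 0.0, 0.0, 0.0)
        lum, con, struc = ssim_terms(stats)
        assert con == 1.0 and struc == 1.0
        p = SSIMParams()
        expected = (2 * 0.2 * 0.8 + p.C1) / (0.2**2 + 0.8**2 + p.C1)
        assert lum == pytest.approx(expected, rel=1e-14)
        assert lum < 1.0

    def test_luminance_direct_substitution(self):
        stats = WindowStats(1.0, 0.0, 0.0, 0.0, 0.0)
        lum, _, _ = ssim_terms(stats, SSIMParams(c1=0.01, c2=0.01, c3=0.005))
        assert lum == pytest.approx(0.01 / 1.01, rel=1e-14)

    def test_stabilizer_limit_agreement(self):
        """As C1..C3 -> 0 the terms approach the unstabilized ratios."""
        stats = WindowStats(0.5, 0.3, 0.04, 0.09, 0.03)
        raw_l = 2 * 0.5 * 0.3 / (0.25 + 0.09)
        raw_c = 2 * 0.2 * 0.3 / (0.04 + 0.09)
        raw_s = 0.03 / (0.2 * 0.3)
        gaps = []
        for c in (1e-3, 1e-5, 1e-7):
            terms = ssim_terms(stats, SSIMParams(c1=c, c2=c, c3=c))
            gaps.append(max(abs(terms[0] - raw_l), abs(terms[1] - raw_c),
                            abs(terms[2] - raw_s)))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-6

    def test_invalid_stats(self):
        with pytest.raises(ValueError):
            WindowStats(0.5, 0.5, -0.1, 0.1, 0.0)
        with pytest.raises(ValueError):
            WindowStats(0.5, 0.5, 0.01, 0.01, 0.5)


class TestMeanSSIM:
    def test_self_identity_is_exact(self, rng, smooth_image):
        for img in (smooth_image, IntensityImage(rng.random((20, 30, 3)))):
            assert mean_ssim(img, img) == 1.0
            assert mean_ssim_percent(img, img) == 100.0
            assert mean_ssim(img, img, SSIMParams(window="global")) == 1.0

    def test_symmetry(self, rng):
        a = IntensityImage(rng.random((32, 32)))
        b = IntensityImage(np.clip(rng.random((32, 32)), 0, 1))
        assert mean_ssim(a, b) == mean_ssim(b, a)

    def test_two_constant_images_closed_form(self):
        a = IntensityImage(np.full((16, 16), 0.25))
        b = IntensityImage(np.full((16, 16), 0.75))
        params = SSIMParams(window="global", c1=1e-4)
        got = mean_ssim(a, b, params)
        lum, con, struc = ssim_terms(WindowStats(0.25, 0.75, 0.0, 0.0, 0.0), params)
        assert got == pytest.approx(lum * con * struc, rel=1e-14)

    def test_matches_reference_implementation(self, rng):
        """Default windowing agrees with scikit-image's Wang-style SSIM."""
        a = rng.random((48, 56))
        b = np.clip(a + 0.08 * rng.standard_normal(a.shape), 0, 1)
        ref = structural_similarity(a, b, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False, data_range=1.0)
        assert mean_ssim(a, b) == pytest.approx(ref, abs=1e-12)

    def test_channel_permutation_invariance(self, rng):
        a = rng.random((24, 24, 3))
        b = np.clip(a + 0.05 * rng.standard_normal(a.shape), 0, 1)
        perm = [2, 0, 1]
        assert mean_ssim(a, b) == pytest.approx(
            mean_ssim(a[:, :, perm], b[:, :, perm]), abs=1e-15
        )

    def test_tiny_image_falls_back_to_global(self, rng):
        a = rng.random((5, 5))
        assert mean_ssim(a, a) == 1.0

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shapes differ"):
            mean_ssim(rng.random((8, 8)), rng.random((8, 9)))


class TestIoU:
    def test_identical_masks(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:5, 2:5] = True
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), dtype=bool)
        b = np.zeros((8, 8), dtype=bool)
        a[0, 0] = True
        b[7, 7] = True
        assert iou(a, b) == 0.0

    def test_half_overlap(self):
        full = np.ones((8, 8), dtype=int)
        half = np.zeros((8, 8), dtype=int)
        half[:4] = 1
        assert iou(half, full) == 0.5

    def test_both_empty_is_perfect(self):
        e = np.zeros((4, 4), dtype=bool)
        assert iou(e, e) == 1.0

    def test_symmetry_and_bounds(self, rng):
        a = rng.random((16, 16)) > 0.5
        b = rng.random((16, 16)) > 0.5
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            iou(np.full((4, 4), 0.5), np.zeros((4, 4)))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            iou(np.zeros((4, 4)), np.zeros((4, 5)))


class TestAccuracy:
    @pytest.mark.parametrize("tp,tn,fp,fn,expected", [
        (5, 5, 0, 0, 1.0),
        (0, 0, 3, 7, 0.0),
        (3, 2, 3, 2, 0.5),
    ])
    def test_values(self, tp, tn, fp, fn, expected):
        assert accuracy(ConfusionCounts(tp, tn, fp, fn)) == expected

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)
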
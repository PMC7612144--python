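"""Segmentation and colocalization: brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cmquant import coloc
from cmquant.coloc import (
    BackgroundStats, CellROI, ChannelImage, HsvImage, SignalMask,
    ThresholdConfig, background_adjusted_mean, colocalization_metrics,
    extract_signal_mask, gaussian_kernel, gaussian_smooth, render_to_hsv,
    select_denoise_kernel, threshold_signal,
)


def _hsv_from_val(val):
    val = np.asarray(val, dtype=float)
    return HsvImage(hue=np.zeros_like(val), sat=np.zeros_like(val), val=val)


class TestRenderToHsv:
    def test_bit_depth_endpoints(self):
        img16 = ChannelImage(np.array([[0, 65535]], dtype=np.uint16),
                             bit_depth=16)
        hsv = render_to_hsv(img16)
        assert hsv.val[0, 0] == 0.0
        assert hsv.val[0, 1] == 255.0

    def test_8bit_is_identity_with_zero_luts(self, random_channel):
        hsv = render_to_hsv(random_channel, lut_hue=0, lut_sat=0)
        assert np.array_equal(hsv.val, random_channel.pixels.astype(float))
        assert not hsv.sat.any()


class TestBackgroundAdjustedMean:
    def test_uniform_image(self):
        stats = background_adjusted_mean(_hsv_from_val(np.full((8, 8), 100.0)))
        assert stats.k == 100.0
        assert stats.n_nonbackground == 64

    def test_all_zero_degenerates_with_warning(self):
        with pytest.warns(UserWarning):
            stats = background_adjusted_mean(_hsv_from_val(np.zeros((4, 4))))
        assert stats.k == 0.0 and stats.n_nonbackground == 0

    def test_matches_double_loop_oracle(self, rng):
        val = rng.integers(0, 256, size=(16, 16)).astype(float)
        val[rng.random((16, 16)) < 0.3] = 0.0
        total, count = 0.0, 0
        for i in range(16):
            for j in range(16):
                if val[i, j] > 0:
                    total += val[i, j]
                    count += 1
        stats = background_adjusted_mean(_hsv_from_val(val))
        assert stats.n_nonbackground == count
        assert stats.k == pytest.approx(total / count, rel=1e-12)


class TestKernelRule:
    @pytest.mark.parametrize("k,label,expected", [
        (35.0, "TUBULIN", 5),
        (34.999, "TUBULIN", 3),
        (0.0, "TUBULIN", 3),
        (200.0, "VASH2", 3),
        (35.0, "VASH2", 3),
        (35.0, "MAP4", 3),
    ])
    def test_adaptive_kernel(self, k, label, expected):
        stats = BackgroundStats(k=k, n_nonbackground=1)
        assert select_denoise_kernel(stats, label) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            select_denoise_kernel(BackgroundStats(10.0, 1), "DAPI")


class TestGaussianSmooth:
    def test_constant_invariance(self):
        grid = np.full((10, 10), 7.5)
        assert np.allclose(gaussian_smooth(grid, 5), grid, atol=1e-12)

    def test_impulse_gives_normalized_kernel(self):
        grid = np.zeros((9, 9))
        grid[4, 4] = 1.0
        out = gaussian_smooth(grid, 3)
        assert np.allclose(out[3:6, 3:6], gaussian_kernel(3), atol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_nested_loop_convolution(self, rng):
        grid = rng.random((12, 12))
        ksz = 5
        kern = gaussian_kernel(ksz)
        half = ksz // 2
        # edge-inclusive reflection (a b c | c b a), the convention used by
        # the implementation's boundary handling
        padded = np.pad(grid, half, mode="symmetric")
        expected = np.zeros_like(grid)
        for i in range(12):
            for j in range(12):
                acc = 0.0
                for a in range(ksz):
                    for b in range(ksz):
                        acc += kern[a, b] * padded[i + a, j + b]
                expected[i, j] = acc
        assert np.allclose(gaussian_smooth(grid, ksz), expected, atol=1e-10)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((4, 4)), 4)


class TestThresholdWindows:
    def test_quoted_window_examples(self):
        cfg = ThresholdConfig()
        stats = BackgroundStats(k=50.0, n_nonbackground=1)
        img = HsvImage(hue=np.array([[90.0]]), sat=np.array([[20.0]]),
                       val=np.array([[90.0]]))
        assert threshold_signal(img, stats, cfg)[0, 0]  # 90 in [80, 220]
        img_v = HsvImage(hue=np.array([[90.0]]), sat=np.array([[20.0]]),
                         val=np.array([[230.0]]))
        assert not threshold_signal(img_v, stats, cfg)[0, 0]  # v > 220
        img_s = HsvImage(hue=np.array([[90.0]]), sat=np.array([[44.0]]),
                         val=np.array([[90.0]]))
        assert not threshold_signal(img_s, stats, cfg)[0, 0]  # s > 43

    def test_inclusive_bounds_at_ties(self):
        stats = BackgroundStats(k=50.0, n_nonbackground=1)
        img = _hsv_from_val(np.array([[80.0, 220.0, 79.999, 220.001]]))
        raw = threshold_signal(img, stats)
        assert raw.tolist() == [[True, True, False, False]]

    def test_uniform_inside_window_covers_image(self):
        val = np.full((16, 16), 100.0)
        img = _hsv_from_val(val)
        stats = BackgroundStats(k=50.0, n_nonbackground=256)
        mask = extract_signal_mask(img, stats, "VASH2")
        assert mask.n_signal == 256

    @settings(max_examples=25, deadline=None)
    @given(hnp.arrays(np.uint8, (64, 64)))
    def test_mask_matches_per_pixel_oracle(self, pixels):
        """Pre-smoothing mask equals an explicit three-window check."""
        channel = ChannelImage(pixels, bit_depth=8, channel_label="VASH2")
        hsv = render_to_hsv(channel)
        if not (hsv.val > 0).any():
            return
        stats = background_adjusted_mean(hsv)
        raw = threshold_signal(hsv, stats)
        lo = stats.k + 30.0
        for i, j in [(0, 0), (13, 57), (63, 63), (31, 5)]:
            h, s, v = hsv.hue[i, j], hsv.sat[i, j], hsv.val[i, j]
            expected = (0 <= h <= 180) and (0 <= s <= 43) and (lo <= v <= 220)
            assert raw[i, j] == expected
        # full-image oracle
        oracle = (hsv.hue >= 0) & (hsv.hue <= 180) & (hsv.sat >= 0) & \
                 (hsv.sat <= 43) & (hsv.val >= lo) & (hsv.val <= 220)
        assert np.array_equal(raw, oracle)

    def test_raising_val_offset_shrinks_mask(self, random_channel):
        hsv = render_to_hsv(random_channel)
        stats = background_adjusted_mean(hsv)
        masks = [threshold_signal(hsv, stats, ThresholdConfig(val_offset=off))
                 for off in (10.0, 30.0, 60.0)]
        assert (masks[0] >= masks[1]).all()
        assert (masks[1] >= masks[2]).all()


class TestColocalizationMetrics:
    def _mask(self, arr):
        return SignalMask(np.asarray(arr, bool), "VASH2")

    def _imgs(self, shape):
        img = ChannelImage(np.ones(shape, dtype=np.uint8) * 100, bit_depth=8,
                           channel_label="VASH2")
        timg = ChannelImage(np.ones(shape, dtype=np.uint8) * 50, bit_depth=8,
                            channel_label="TUBULIN")
        return img, timg

    def test_identical_masks_full_overlap(self, full_roi, rng):
        m = rng.random((64, 64)) < 0.3
        vimg, timg = self._imgs((64, 64))
        res = colocalization_metrics(self._mask(m), self._mask(m), vimg, timg,
                                     full_roi)
        assert res.frac_on == 1.0 and res.frac_off == 0.0
        assert res.o == m.sum() == res.v

    def test_disjoint_masks(self, full_roi):
        a = np.zeros((64, 64), bool)
        b = np.zeros((64, 64), bool)
        a[:10], b[20:30] = True, True
        vimg, timg = self._imgs((64, 64))
        res = colocalization_metrics(self._mask(a), self._mask(b), vimg, timg,
                                     full_roi)
        assert res.frac_on == 0.0 and res.frac_off == 1.0

    def test_hand_built_pixel_counts(self, full_roi):
        vash = np.zeros((64, 64), bool)
        tub = np.zeros((64, 64), bool)
        vash.flat[:100] = True
        tub.flat[40:140] = True  # overlap = 60 pixels
        vimg, timg = self._imgs((64, 64))
        res = colocalization_metrics(self._mask(vash), self._mask(tub),
                                     vimg, timg, full_roi)
        assert (res.v, res.o) == (100, 60)
        assert res.frac_on == pytest.approx(0.6)
        assert res.frac_off == pytest.approx(0.4)
        assert res.frac_on + res.frac_off == pytest.approx(1.0, abs=1e-12)

    def test_self_correlation_is_one(self, full_roi, rng):
        # dim image (k < 35) so both channels select the same 3x3 kernel
        # and identical inputs undergo identical processing
        pixels = rng.integers(0, 60, (64, 64)).astype(np.uint8)
        img = ChannelImage(pixels, 8, "VASH2")
        img2 = ChannelImage(pixels, 8, "TUBULIN")
        m = self._mask(np.ones((64, 64), bool))
        res = colocalization_metrics(m, m, img, img2, full_roi)
        assert res.pcc == pytest.approx(1.0, abs=1e-12)

    def test_zero_vash2_pixels_yield_nan_with_warning(self, full_roi):
        empty = self._mask(np.zeros((64, 64), bool))
        some = self._mask(np.ones((64, 64), bool))
        vimg, timg = self._imgs((64, 64))
        with pytest.warns(UserWarning, match="fractions undefined"):
            res = colocalization_metrics(empty, some, vimg, timg, full_roi)
        assert np.isnan(res.frac_on) and np.isnan(res.frac_off)

    def test_empty_roi_rejected(self):
        m = self._mask(np.ones((8, 8), bool))
        vimg, timg = self._imgs((8, 8))
        with pytest.raises(ValueError, match="empty ROI"):
            colocalization_metrics(m, m, vimg, timg,
                                   CellROI(np.zeros((8, 8), bool)))

    def test_mfi_is_mean_vash2_intensity(self, full_roi, rng):
        pixels = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        vimg = ChannelImage(pixels, 8, "VASH2")
        timg = ChannelImage(pixels, 8, "TUBULIN")
        m = self._mask(np.ones((64, 64), bool))
        res = colocalization_metrics(m, m, vimg, timg, full_roi)
        assert res.mfi == pytest.approx(pixels.mean())


class TestPccProperties:
    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        x = rng.random(500)
        y = rng.random(500) + 0.3 * x
        from cmquant.stats import pearson_r
        base = pearson_r(x, y)
        assert pearson_r(scale * x + shift, y) == pytest.approx(base,
                                                                abs=1e-9)

    def test_bounds(self, rng):
        from cmquant.stats import pearson_r
        for _ in range(20):
            r = pearson_r(rng.random(50), rng.random(50))
            assert -1.0 <= r <= 1.0
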
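"""Baseline bank tests: Gabor filters, Haralick statistics, HOG, median."""

import math

import numpy as np
import pytest

import oracles
from collagetex import (
    BaselineConfig,
    ImageScene,
    ROIMask,
    aggregate_lesion_feature,
    bank_sizes,
    build_gabor_bank,
    gabor_response_features,
    haralick_feature_map,
    haralick_statistics,
    hog_feature_vector,
)
from collagetex.baselines import HARALICK_STAT_NAMES, _quantize
from collagetex.errors import ConfigError, EmptyROIError


class TestBankArithmetic:
    def test_default_bank_sizes(self):
        sizes = bank_sizes()
        assert sizes["haralick"] == 52  # 13 statistics x 4 window sizes
        assert sizes["gabor"] == 432  # 6 x 8 x 9 grid
        assert sizes["total"] == 584

    def test_gabor_count_is_grid_product(self):
        cfg = BaselineConfig(
            gabor_frequencies=(0.1,), gabor_orientations=(0.0,), gabor_sigmas=(2.0,)
        )
        assert len(build_gabor_bank(cfg)) == 1
        cfg = BaselineConfig(
            gabor_frequencies=(0.1, 0.2),
            gabor_orientations=(0.0, 1.0, 2.0),
            gabor_sigmas=(1.0, 2.0),
        )
        assert len(build_gabor_bank(cfg)) == 2 * 3 * 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            BaselineConfig(gabor_frequencies=())

    @pytest.mark.parametrize("v,width", [(10, 36.0), (15, 24.0), (20, 18.0), (25, 14.4), (30, 12.0)])
    def test_hog_bin_widths(self, v, width):
        assert 360.0 / v == pytest.approx(width)


class TestGabor:
    def test_constant_scene_response_equals_kernel_mean_response(self, rng):
        bank = build_gabor_bank(
            BaselineConfig(
                gabor_frequencies=(0.25,), gabor_orientations=(0.0, math.pi / 4),
                gabor_sigmas=(2.0,),
            )
        )
        scene = ImageScene(np.full((16, 16), 10.0))
        mask = ROIMask(np.ones((16, 16), bool))
        row = gabor_response_features(scene, mask, bank)
        for filt, got in zip(bank, row.values):
            want = abs(filt.kernel.sum()) * 10.0
            assert got == pytest.approx(want, abs=1e-8)
            if abs(filt.kernel.sum()) < 1e-10:  # zero-mean filter
                assert got == pytest.approx(0.0, abs=1e-8)

    def test_feature_count_equals_bank_size(self, rng):
        bank = build_gabor_bank(
            BaselineConfig(
                gabor_frequencies=(0.1, 0.2), gabor_orientations=(0.0,),
                gabor_sigmas=(1.5, 2.5),
            )
        )
        scene = ImageScene(rng.random((12, 12)))
        row = gabor_response_features(scene, ROIMask(np.ones((12, 12), bool)), bank)
        assert len(row.values) == len(bank) == 4

    def test_impulse_response_matches_naive_convolution(self):
        from scipy import ndimage

        bank = build_gabor_bank(
            BaselineConfig(
                gabor_frequencies=(0.25,), gabor_orientations=(math.pi / 6,),
                gabor_sigmas=(1.0,),
            )
        )
        k = bank[0].kernel
        img = np.zeros((8, 8))
        img[4, 4] = 1.0
        got_re = ndimage.convolve(img, np.real(k), mode="nearest")
        # naive space-domain convolution loop, replicate edges
        kh, kw = k.shape
        want = np.zeros((8, 8))
        for r in range(8):
            for c in range(8):
                acc = 0.0
                for i in range(kh):
                    for j in range(kw):
                        rr = min(max(r + kh // 2 - i, 0), 7)
                        cc = min(max(c + kw // 2 - j, 0), 7)
                        acc += img[rr, cc] * np.real(k)[i, j]
                want[r, c] = acc
        np.testing.assert_allclose(got_re, want, atol=1e-8)


class TestHaralick:
    def test_bank_is_13_stats_by_4_windows(self, rng):
        scene = ImageScene(rng.random((10, 10)))
        mask = ROIMask(np.ones((10, 10), bool))
        cfg = BaselineConfig(haralick_levels=8)
        maps, row = haralick_feature_map(scene, mask, cfg)
        assert len(row.values) == 52
        assert maps.shape == (52, 10, 10)
        assert np.all(np.isfinite(row.values))

    def test_constant_roi_degenerates(self):
        scene = ImageScene(np.full((8, 8), 5.0))
        mask = ROIMask(np.ones((8, 8), bool))
        cfg = BaselineConfig(haralick_window_sizes=(3,), haralick_levels=8)
        _, row = haralick_feature_map(scene, mask, cfg)
        stats = dict(zip(row.names, row.values))
        assert stats["haralick_w3_angular_second_moment"] == pytest.approx(1.0)
        assert stats["haralick_w3_contrast"] == pytest.approx(0.0)

    def test_statistics_match_hand_enumerated_glcm(self):
        # 6x6 two-level toy image: vertical stripes of width 1
        img = np.tile([0.0, 9.0], (6, 3))
        q = _quantize(img, np.ones((6, 6), bool), 2)
        # hand enumeration: distance-1 pairs in 4 directions, symmetric
        M = np.zeros((2, 2))
        for (dr, dc) in ((0, 1), (1, 1), (1, 0), (1, -1)):
            for r in range(6):
                for c in range(6):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < 6 and 0 <= cc < 6:
                        M[q[r, c], q[rr, cc]] += 1
                        M[q[rr, cc], q[r, c]] += 1
        P = M / M.sum()
        got = haralick_statistics(P)
        # independent closed-form checks of selected statistics
        assert got[0] == pytest.approx((P**2).sum())  # ASM
        contrast = sum(
            (i - j) ** 2 * P[i, j] for i in range(2) for j in range(2)
        )
        assert got[1] == pytest.approx(contrast)
        ent = -sum(
            P[i, j] * math.log2(P[i, j])
            for i in range(2)
            for j in range(2)
            if P[i, j] > 0
        )
        assert got[8] == pytest.approx(ent)
        idm = sum(
            P[i, j] / (1 + (i - j) ** 2) for i in range(2) for j in range(2)
        )
        assert got[4] == pytest.approx(idm)
        assert len(got) == len(HARALICK_STAT_NAMES) == 13

    def test_shift_invariance_via_roi_quantization(self, rng):
        img = np.floor(rng.random((9, 9)) * 16)
        mask = ROIMask(np.ones((9, 9), bool))
        cfg = BaselineConfig(haralick_window_sizes=(3, 5), haralick_levels=8)
        _, row_a = haralick_feature_map(ImageScene(img), mask, cfg)
        _, row_b = haralick_feature_map(ImageScene(img + 1000.0), mask, cfg)
        np.testing.assert_allclose(row_a.values, row_b.values, atol=1e-12)


class TestHOG:
    def test_ramp_concentrates_in_zero_orientation_bin(self):
        r = np.indices((12, 12))[0].astype(float)
        row = hog_feature_vector(
            ImageScene(r), ROIMask(np.ones((12, 12), bool)), 10
        )
        # orientation 0 lies in bin v/2 = 5 with signed binning over 360 deg
        assert row.values[5] == pytest.approx(1.0)

    def test_matches_per_pixel_loop_oracle(self, rng):
        img = rng.random((12, 12)) * 30
        mask = np.ones((12, 12), bool)
        v = 10
        row = hog_feature_vector(ImageScene(img), ROIMask(mask), v)
        grads = oracles.naive_gradients(img)
        hist = np.zeros(v)
        for (r, c) in np.argwhere(mask):
            g0, g1 = grads[0][r, c], grads[1][r, c]
            ang = math.atan2(g1, g0)
            mag = math.hypot(g0, g1)
            k = min(int((ang + math.pi) / (2 * math.pi / v)), v - 1)
            hist[k] += mag
        np.testing.assert_allclose(row.values, hist / hist.sum(), atol=1e-15)

    def test_off_grid_v_warns_but_computes(self, rng):
        scene = ImageScene(rng.random((10, 10)))
        mask = ROIMask(np.ones((10, 10), bool))
        with pytest.warns(UserWarning):
            row = hog_feature_vector(scene, mask, 12)
        assert len(row.values) == 12


class TestMedianAggregation:
    def test_examples_and_sort_oracle(self, rng):
        assert aggregate_lesion_feature([1, 2, 100]) == 2.0
        assert aggregate_lesion_feature([7.5]) == 7.5
        vals = rng.normal(size=10_000)
        s = np.sort(vals)
        want = (s[4999] + s[5000]) / 2.0
        assert aggregate_lesion_feature(vals) == pytest.approx(want, abs=1e-14)

    def test_empty_rejected(self):
        with pytest.raises(EmptyROIError):
            aggregate_lesion_feature([])
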
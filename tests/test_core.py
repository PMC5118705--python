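"""Unit and property tests for the descriptor core: gradients, dominant
orientations, discretization, co-occurrence, and entropy maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from collagetex import (
    CollageConfig,
    ImageScene,
    ROIMask,
    collage_entropy_map_2d,
    collage_entropy_maps_3d,
    compute_gradient_field,
    cooccurrence_entropy,
    discretize_orientation,
    dominant_orientation_2d,
    dominant_orientation_3d,
    orientation_cooccurrence,
)
from collagetex.core import (
    OFFSETS_2D,
    OFFSETS_3D,
    CooccurrenceMatrix,
    assemble_gradient_matrix,
    discretize_elevation,
)
from collagetex.errors import (
    ConfigError,
    DegenerateInputError,
    NoPairsError,
    NumericalInputError,
)


class TestGradients:
    @pytest.mark.parametrize(
        "fn,expected",
        [
            (lambda r, c: r, (1.0, 0.0)),
            (lambda r, c: np.zeros_like(r, dtype=float) + 5.0, (0.0, 0.0)),
            (lambda r, c: 2.0 * r + 3.0 * c, (2.0, 3.0)),
        ],
    )
    def test_central_difference_exact_on_ramps(self, fn, expected):
        r, c = np.indices((9, 9))
        field = compute_gradient_field(ImageScene(fn(r, c).astype(float)))
        interior = (slice(1, -1), slice(1, -1))
        assert np.allclose(field.components[0][interior], expected[0])
        assert np.allclose(field.components[1][interior], expected[1])

    def test_reflect_policy_rejects_thin_axes(self):
        scene = ImageScene(np.ones((2, 8)))
        with pytest.raises(DegenerateInputError):
            compute_gradient_field(scene, boundary_policy="reflect")

    def test_matches_loop_oracle_including_boundary(self, rng):
        img = rng.random((7, 8)) * 50
        for policy in ("replicate", "reflect"):
            field = compute_gradient_field(ImageScene(img), policy)
            ref = oracles.naive_gradients(img, policy)
            for got, want in zip(field.components, ref):
                np.testing.assert_array_equal(got, want)


class TestGradientMatrix:
    def test_window_shape_2d_and_3d(self, rng):
        cfg = CollageConfig(window_radius=1)
        f2 = compute_gradient_field(ImageScene(rng.random((8, 8))))
        assert assemble_gradient_matrix(f2, (4, 4), cfg).shape == (9, 2)
        f3 = compute_gradient_field(ImageScene(rng.random((8, 8, 8))))
        assert assemble_gradient_matrix(f3, (4, 4, 4), cfg).shape == (27, 3)

    def test_constant_scene_gives_zero_matrix(self):
        cfg = CollageConfig(window_radius=1)
        f = compute_gradient_field(ImageScene(np.full((8, 8), 3.0)))
        assert not np.any(assemble_gradient_matrix(f, (2, 2), cfg))


class TestDominantOrientation:
    def test_aligned_rows_give_axis_angles(self):
        res = dominant_orientation_2d(np.tile([1.0, 0.0], (9, 1)))
        assert res.theta == pytest.approx(0.0)
        np.testing.assert_allclose(res.psi, [1.0, 0.0], atol=1e-12)
        res = dominant_orientation_2d(np.tile([0.0, 1.0], (9, 1)))
        assert res.theta == pytest.approx(math.pi / 2)

    def test_3d_axis_conventions(self):
        res = dominant_orientation_3d(np.tile([1.0, 0.0, 0.0], (27, 1)))
        assert res.theta == pytest.approx(0.0)
        assert res.phi == pytest.approx(0.0)
        res = dominant_orientation_3d(np.tile([0.0, 0.0, 1.0], (27, 1)))
        assert res.phi == pytest.approx(math.pi / 2)
        assert res.theta == pytest.approx(0.0)  # degenerate azimuth

    def test_all_zero_matrix_is_degenerate(self):
        res = dominant_orientation_2d(np.zeros((9, 2)))
        assert res.degenerate and res.theta == 0.0
        res = dominant_orientation_3d(np.zeros((27, 3)))
        assert res.degenerate and res.theta == 0.0 and res.phi == 0.0

    def test_nonfinite_rejected(self):
        G = np.ones((9, 2))
        G[0, 0] = np.nan
        with pytest.raises(NumericalInputError):
            dominant_orientation_2d(G)

    def test_2d_matches_grid_search_oracle(self, rng):
        for _ in range(10):
            G = rng.normal(size=(9, 2))
            got = dominant_orientation_2d(G)
            want = oracles.grid_search_orientation_2d(G)
            ang = math.atan2(want[1], want[0])
            diff = abs(
                math.remainder(got.theta - ang, 2 * math.pi)
            )
            assert diff < 2e-3

    def test_3d_matches_spherical_grid_search_oracle(self, rng):
        for _ in range(5):
            G = rng.normal(size=(27, 3))
            got = dominant_orientation_3d(G)
            want = oracles.grid_search_orientation_3d(G)
            # compare as unit vectors after the shared sign rule
            cosang = float(np.clip(got.psi @ want, -1.0, 1.0))
            assert math.acos(cosang) < 2e-3

    def test_unit_norm_unless_degenerate(self, rng):
        for _ in range(20):
            G = rng.normal(size=(25, 2))
            res = dominant_orientation_2d(G)
            assert np.linalg.norm(res.psi) == pytest.approx(1.0, abs=1e-12)


class TestDiscretization:
    def test_known_bins_at_B64(self):
        cfg = CollageConfig(orientation_bins=64)
        assert discretize_orientation(0.0, cfg) == 32
        assert discretize_orientation(math.pi, cfg) == 63  # clamp rule

    def test_out_of_range_rejected(self):
        cfg = CollageConfig(orientation_bins=64)
        with pytest.raises(ConfigError):
            discretize_orientation(4.0, cfg)
        with pytest.raises(ConfigError):
            discretize_elevation(2.0, cfg)

    def test_uniform_draws_fill_bins_uniformly(self, rng):
        cfg = CollageConfig(orientation_bins=32)
        from scipy.stats import chisquare

        draws = rng.uniform(-math.pi, math.pi, size=10_000)
        idx = discretize_orientation(draws, cfg)
        counts = np.bincount(idx, minlength=32)
        assert chisquare(counts).pvalue > 0.001


class TestCooccurrence:
    def test_uniform_window_counts_by_enumeration(self):
        cfg = CollageConfig(orientation_bins=16)
        M = orientation_cooccurrence(np.full((3, 3), 5), cfg)
        ref = oracles.window_cooc_counts(
            np.full((3, 3), 5), (0, 0), 3, OFFSETS_2D, 16
        )
        np.testing.assert_array_equal(M.counts, ref)
        assert M.counts[5, 5] == 40  # 20 unordered pairs, counted both ways

    def test_checkerboard_window_matches_enumeration(self):
        cfg = CollageConfig(orientation_bins=16)
        r, c = np.indices((3, 3))
        w = ((r + c) % 2) * 7  # bins 0 and 7 alternating
        M = orientation_cooccurrence(w, cfg)
        ref = oracles.window_cooc_counts(w, (0, 0), 3, OFFSETS_2D, 16)
        np.testing.assert_array_equal(M.counts, ref)
        # axis-aligned neighbors always differ; only diagonals repeat a bin
        assert M.counts[0, 7] > 0 and M.counts[0, 0] > 0

    def test_single_location_window_has_no_pairs(self):
        cfg = CollageConfig(orientation_bins=16)
        with pytest.raises(NoPairsError):
            orientation_cooccurrence(np.array([[3]]), cfg)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1), st.sampled_from([2, 3]))
    def test_symmetry_and_normalization(self, seed, dims):
        rng = np.random.default_rng(seed)
        B = int(rng.integers(2, 17))
        cfg = CollageConfig(orientation_bins=B)
        shape = tuple(rng.integers(2, 5, size=dims))
        w = rng.integers(0, B, size=shape)
        M = orientation_cooccurrence(w, cfg)
        np.testing.assert_array_equal(M.counts, M.counts.T)
        assert abs(M.normalized.sum() - 1.0) < 1e-12

    def test_3d_offsets_are_the_13_unique_directions(self):
        assert len(OFFSETS_3D) == 13
        assert len({o for o in OFFSETS_3D} | {tuple(-x for x in o) for o in OFFSETS_3D}) == 26


class TestEntropy:
    def test_point_mass_and_uniform_four_cells(self):
        M = np.zeros((8, 8), dtype=int)
        M[2, 2] = 10
        assert cooccurrence_entropy(CooccurrenceMatrix(M)) == 0.0
        M = np.zeros((8, 8), dtype=int)
        M[0, 1] = M[1, 0] = M[2, 3] = M[3, 2] = 5
        assert cooccurrence_entropy(CooccurrenceMatrix(M)) == pytest.approx(2.0)

    def test_matches_extended_precision_sum(self, rng):
        from mpmath import mp, mpf, log

        mp.dps = 40
        counts = rng.integers(0, 20, size=(12, 12))
        got = cooccurrence_entropy(CooccurrenceMatrix(counts))
        total = mpf(int(counts.sum()))
        want = -sum(
            (mpf(int(c)) / total) * log(mpf(int(c)) / total) / log(mpf(2))
            for c in counts.ravel()
            if c > 0
        )
        assert abs(got - float(want)) < 1e-10

    def test_empty_matrix_rejected(self):
        with pytest.raises(NoPairsError):
            cooccurrence_entropy(CooccurrenceMatrix(np.zeros((4, 4), int)))


class TestEntropyMaps:
    def test_constant_scene_gives_zero_map(self, full_mask, tiny_config):
        scene = ImageScene(np.full((12, 12), 9.0))
        emap = collage_entropy_map_2d(scene, full_mask((12, 12)), tiny_config)
        assert np.all(emap.roi_values == 0.0)

    def test_constant_volume_gives_two_zero_maps(self, full_mask, tiny_config):
        scene = ImageScene(np.full((9, 9, 5), 1.0))
        et, ep = collage_entropy_maps_3d(scene, full_mask((9, 9, 5)), tiny_config)
        assert np.all(et.roi_values == 0.0) and np.all(ep.roi_values == 0.0)

    def test_2d_map_equals_naive_reimplementation(self, rng, full_mask):
        cfg = CollageConfig(window_radius=1, orientation_bins=16)
        img = rng.random((16, 16)) * 100
        emap = collage_entropy_map_2d(ImageScene(img), full_mask((16, 16)), cfg)
        (want,) = oracles.naive_entropy_maps(
            img, np.ones((16, 16), bool), 1, 16, OFFSETS_2D
        )
        np.testing.assert_array_equal(emap.values, want)

    def test_3d_maps_equal_naive_reimplementation(self, rng, full_mask):
        cfg = CollageConfig(window_radius=1, orientation_bins=16)
        vol = rng.random((10, 10, 5)) * 10
        et, ep = collage_entropy_maps_3d(
            ImageScene(vol), full_mask((10, 10, 5)), cfg
        )
        want_t, want_p = oracles.naive_entropy_maps(
            vol, np.ones((10, 10, 5), bool), 1, 16, OFFSETS_3D
        )
        np.testing.assert_array_equal(et.values, want_t)
        np.testing.assert_array_equal(ep.values, want_p)

    def test_z_ramp_volume_has_zero_elevation_entropy(self, full_mask):
        cfg = CollageConfig(window_radius=1, orientation_bins=16)
        z = np.indices((8, 8, 8))[2].astype(float)
        _, ep = collage_entropy_maps_3d(ImageScene(z), full_mask((8, 8, 8)), cfg)
        assert np.all(ep.roi_values == 0.0)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(0, 2**32 - 1))
    def test_entropy_bounds_under_fuzzing(self, seed):
        rng = np.random.default_rng(seed)
        B = int(rng.choice([4, 16, 64]))
        cfg = CollageConfig(window_radius=int(rng.integers(1, 3)), orientation_bins=B)
        img = rng.normal(size=(int(rng.integers(8, 15)),) * 2) * rng.lognormal()
        mask = np.ones(img.shape, bool)
        emap = collage_entropy_map_2d(ImageScene(img), ROIMask(mask), cfg)
        eps = emap.roi_values
        assert np.all(eps >= 0.0) and np.all(eps <= 2 * math.log2(B) + 1e-12)

    def test_only_roi_pixels_are_defined(self, rng, tiny_config):
        img = rng.random((12, 12))
        mask = np.zeros((12, 12), bool)
        mask[4:8, 4:8] = True
        emap = collage_entropy_map_2d(ImageScene(img), ROIMask(mask), tiny_config)
        assert np.all(np.isfinite(emap.values[mask]))
        assert np.all(np.isnan(emap.values[~mask]))
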
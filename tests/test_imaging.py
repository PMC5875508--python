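"""Geometry, resampling, morphology and distance-field operations."""

import numpy as np
import pytest

from atlasseg.errors import GeometryError
from atlasseg.imaging import (
    BinaryMask,
    ScalarVolume,
    VolumeGrid,
    dilate_mask,
    gradient_magnitude,
    resample,
    signed_distance,
)
from atlasseg.transforms import Affine3D

from oracles import brute_force_dilate, brute_force_signed_distance


class TestVolumeGrid:
    def test_index_physical_roundtrip(self):
        grid = VolumeGrid((10, 12, 14), (2.5, 1.0, 1.5), (-20.0, 3.0, 7.0))
        idx = np.array([[0, 0, 0], [9, 11, 13], [3, 4, 5]], dtype=float)
        back = grid.physical_to_index(grid.index_to_physical(idx))
        np.testing.assert_allclose(back, idx, atol=1e-10)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(GeometryError):
            VolumeGrid((4, 4, 4), (0.0, 1.0, 1.0))
        with pytest.raises(GeometryError):
            VolumeGrid((4, 4, 4), direction=np.eye(3) * 2.0)

    def test_shape_mismatch_rejected(self):
        grid = VolumeGrid((4, 4, 4))
        with pytest.raises(GeometryError):
            ScalarVolume(grid, np.zeros((4, 4, 5)))


class TestResample:
    def test_identity_is_exact(self, unit_grid):
        rng = np.random.RandomState(0)
        vol = ScalarVolume(unit_grid, rng.rand(*unit_grid.shape) * 100)
        out = resample(vol, unit_grid, None, "linear")
        np.testing.assert_allclose(out.values, vol.values, atol=1e-12)

    def test_lattice_aligned_shift(self, unit_grid):
        rng = np.random.RandomState(1)
        vol = ScalarVolume(unit_grid, rng.rand(*unit_grid.shape) * 100)
        # transform maps target points into source space: +1 voxel along axis 0
        shift = Affine3D.translation_only([1.0, 0.0, 0.0])
        out = resample(vol, unit_grid, shift, "linear")
        np.testing.assert_allclose(out.values[:-1], vol.values[1:], atol=1e-9)

    def test_half_voxel_linear_interpolation(self):
        grid = VolumeGrid((8, 4, 4), (1.0, 1.0, 1.0))
        vals = np.zeros(grid.shape)
        vals[4:] = 10.0  # step along axis 0 between index 3 and 4
        vol = ScalarVolume(grid, vals)
        out = resample(vol, grid, Affine3D.translation_only([0.5, 0, 0]), "linear")
        assert out.values[3, 2, 2] == pytest.approx(5.0)

    def test_mask_resampling_stays_binary_with_fill(self, unit_grid):
        mask = BinaryMask(unit_grid, np.ones(unit_grid.shape, np.uint8), "m")
        out = resample(mask, unit_grid, Affine3D.translation_only([4.0, 0, 0]), "nearest")
        assert set(np.unique(out.values)) <= {0, 1}
        assert out.values[-3:].sum() == 0  # out-of-field filled with background

    def test_ct_out_of_field_fill_is_air(self, unit_grid):
        vol = ScalarVolume(unit_grid, np.full(unit_grid.shape, 55.0))
        out = resample(vol, unit_grid, Affine3D.translation_only([30.0, 0, 0]))
        assert np.all(out.values == -1000.0)


class TestDilateMask:
    def test_zero_margin_is_identity(self, unit_grid):
        m = BinaryMask(unit_grid, np.zeros(unit_grid.shape, np.uint8), "m")
        m.values[8, 8, 8] = 1
        out = dilate_mask(m, 0.0)
        np.testing.assert_array_equal(out.values, m.values)

    def test_single_voxel_isotropic_ball(self):
        grid = VolumeGrid((5, 5, 5), (1.0, 1.0, 1.0))
        m = np.zeros(grid.shape, np.uint8)
        m[2, 2, 2] = 1
        out = dilate_mask(BinaryMask(grid, m, "m"), 1.0)
        expect = brute_force_dilate(m.astype(bool), grid.spacing, 1.0)
        np.testing.assert_array_equal(out.bool, expect)
        assert out.voxel_count == 7  # face-neighbour ball

    def test_anisotropic_spacing_respected(self):
        grid = VolumeGrid((5, 5, 5), (2.5, 1.0, 1.0))
        m = np.zeros(grid.shape, np.uint8)
        m[2, 2, 2] = 1
        out = dilate_mask(BinaryMask(grid, m, "m"), 2.0)
        expect = brute_force_dilate(m.astype(bool), grid.spacing, 2.0)
        np.testing.assert_array_equal(out.bool, expect)
        assert out.values[1, 2, 2] == 0 and out.values[3, 2, 2] == 0  # 2.5 mm away
        assert out.values[2, 0, 2] == 1  # 2.0 mm along the fine axes

    def test_empty_mask_warns_unchanged(self, unit_grid):
        m = BinaryMask(unit_grid, np.zeros(unit_grid.shape, np.uint8), "m")
        with pytest.warns(UserWarning):
            out = dilate_mask(m, 5.0)
        assert out.voxel_count == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_blobs(self, seed):
        from conftest import random_blob

        grid = VolumeGrid((9, 9, 9), (1.5, 1.0, 2.0))
        blob = random_blob(grid.shape, grid.spacing, seed, p=0.15)
        out = dilate_mask(BinaryMask(grid, blob.astype(np.uint8), "b"), 2.2)
        expect = brute_force_dilate(blob, grid.spacing, 2.2)
        np.testing.assert_array_equal(out.bool, expect)

    def test_two_step_composition_bounds(self):
        # continuous morphology gives dilate(a) then dilate(b) == dilate(a+b);
        # on the voxel lattice the intermediate rounding can only lose
        # reachable points, so the two-step result is sandwiched between
        # dilate(m, a) and dilate(m, a + b)
        grid = VolumeGrid((12, 12, 12), (1.0, 1.0, 1.0))
        m = np.zeros(grid.shape, np.uint8)
        m[5:7, 5:7, 5:7] = 1
        mask = BinaryMask(grid, m, "m")
        two_step = dilate_mask(dilate_mask(mask, 1.5), 1.5)
        one_step = dilate_mask(mask, 3.0)
        assert np.all(one_step.bool >= two_step.bool)
        assert np.all(two_step.bool >= dilate_mask(mask, 1.5).bool)


class TestGradientMagnitude:
    def test_constant_volume_zero(self, unit_grid):
        vol = ScalarVolume(unit_grid, np.full(unit_grid.shape, 42.0))
        assert np.allclose(gradient_magnitude(vol, 0.0).values, 0.0)

    def test_linear_ramp_slope_per_mm(self):
        grid = VolumeGrid((12, 6, 6), (2.5, 1.0, 1.0))
        x = grid.physical_points()[..., 0]
        vol = ScalarVolume(grid, 3.0 * x)
        gm = gradient_magnitude(vol, 0.0)
        np.testing.assert_allclose(gm.values[1:-1], 3.0, atol=1e-9)

    def test_positive_homogeneity(self, unit_grid):
        rng = np.random.RandomState(3)
        vals = rng.rand(*unit_grid.shape)
        g1 = gradient_magnitude(ScalarVolume(unit_grid, vals), 0.0).values
        g2 = gradient_magnitude(ScalarVolume(unit_grid, 2.5 * vals), 0.0).values
        np.testing.assert_allclose(g2, 2.5 * g1, rtol=1e-9)

    def test_step_edge_peak_at_edge(self):
        grid = VolumeGrid((40, 3, 3), (1.0, 1.0, 1.0))
        vals = np.zeros(grid.shape)
        vals[20:] = 100.0
        gm = gradient_magnitude(ScalarVolume(grid, vals), 2.0)
        profile = gm.values[:, 1, 1]
        peak = np.argmax(profile)
        assert peak in (19, 20)
        # dense 1D oracle: convolve the step with a sampled Gaussian, then
        # central differences; its peak bounds the continuous DoG response
        # h / (sigma * sqrt(2 pi)) from below
        k = np.arange(-12, 13)
        kern = np.exp(-(k**2) / (2 * 2.0**2))
        kern /= kern.sum()
        step = np.zeros(64)
        step[32:] = 100.0
        smooth = np.convolve(step, kern, mode="same")
        oracle_peak = np.abs(np.gradient(smooth)).max()
        assert profile[peak] == pytest.approx(oracle_peak, rel=1e-3)
        assert oracle_peak <= 100.0 / (2.0 * np.sqrt(2 * np.pi))


class TestSignedDistance:
    def test_ball_center_depth(self):
        grid = VolumeGrid((21, 21, 21), (1.0, 1.0, 1.0))
        pts = grid.physical_points()
        c = np.array([10.0] * 3)
        mask = BinaryMask(grid, (np.linalg.norm(pts - c, axis=-1) <= 6.0).astype(np.uint8), "b")
        phi = signed_distance(mask)
        assert phi.phi[10, 10, 10] == pytest.approx(-6.0, abs=1.0)

    def test_adjacent_outside_voxel_bound(self):
        grid = VolumeGrid((7, 7, 7), (1.0, 1.0, 1.5))
        m = np.zeros(grid.shape, np.uint8)
        m[2:5, 2:5, 2:5] = 1
        phi = signed_distance(BinaryMask(grid, m, "m"))
        assert 0 < phi.phi[5, 3, 3] <= 1.5 * 1.5

    def test_degenerate_masks_rejected(self, unit_grid):
        with pytest.raises(GeometryError):
            signed_distance(BinaryMask(unit_grid, np.ones(unit_grid.shape, np.uint8), "m"))
        with pytest.raises(GeometryError):
            signed_distance(BinaryMask(unit_grid, np.zeros(unit_grid.shape, np.uint8), "m"))

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_brute_force_oracle(self, seed):
        from conftest import random_blob

        grid = VolumeGrid((8, 8, 8), (1.0, 1.3, 0.8))
        blob = random_blob(grid.shape, grid.spacing, seed, p=0.3)
        assert blob.any() and not blob.all()
        phi = signed_distance(BinaryMask(grid, blob.astype(np.uint8), "b")).phi
        # EDT signed distance uses voxel-centre distances on each side; the
        # oracle measures distance to the opposite set, so they agree exactly
        expect = brute_force_signed_distance(blob, grid.spacing)
        np.testing.assert_allclose(phi, expect, atol=1e-9)

    def test_sign_flip_negates_near_interface(self):
        from conftest import random_blob

        grid = VolumeGrid((10, 10, 10), (1.0, 1.0, 1.0))
        blob = random_blob(grid.shape, grid.spacing, 9, p=0.3)
        phi = signed_distance(BinaryMask(grid, blob.astype(np.uint8), "b")).phi
        phic = signed_distance(BinaryMask(grid, (~blob).astype(np.uint8), "b")).phi
        near = np.abs(phi) <= 1.0
        np.testing.assert_allclose(phi[near], -phic[near], atol=1.0)
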
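"""Threshold / region-grow / split / crop / fill / edit mask toolchain."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import cytoprint as cp
from cytoprint.errors import ChannelLookupError


def _stack_from(grid: np.ndarray, voxel=(1.0, 1.0, 1.0)) -> cp.VoxelStack:
    return cp.VoxelStack(data=grid[None].astype(np.uint8), voxel_size=voxel,
                         channels=[cp.ChannelSpec("ch")], bit_depth=8)


def _two_blob_grid():
    grid = np.zeros((10, 20, 20), np.uint8)
    grid[2:5, 2:5, 2:5] = 200  # blob A: 27 voxels
    grid[6:8, 12:14, 12:14] = 200  # blob B: 8 voxels
    return grid


class TestThreshold:
    def test_band_selects_constant_grid(self):
        stack = _stack_from(np.full((4, 4, 4), 100, np.uint8))
        mask = cp.threshold_mask(stack, "ch", cp.ThresholdParams(50, 200))
        assert mask.data.all()

    def test_full_range_is_all_true(self):
        stack = _stack_from(np.random.default_rng(0).integers(0, 256, (4, 4, 4)).astype(np.uint8))
        assert cp.threshold_mask(stack, "ch", cp.ThresholdParams(0, 255)).data.all()

    def test_phantom_shell_recovered_exactly_without_blur(self):
        spec = dataclasses.replace(cp.phantom.preset("panc1_like"),
                                   psf_sigma_um=(0, 0, 0), noise="none")
        spec.intensities = {"shell": 180, "nucleus": 200, "background": 10}
        stack, truth = cp.generate_cell_phantom(spec)
        mask = cp.threshold_mask(stack, "TRITC", cp.ThresholdParams(100, 255))
        assert mask.voxel_count == int(truth["shell"].sum())

    def test_unknown_channel_raises(self):
        stack = _stack_from(np.zeros((2, 2, 2), np.uint8))
        with pytest.raises(ChannelLookupError):
            cp.threshold_mask(stack, "nope", cp.ThresholdParams(0, 255))


class TestRegionGrow:
    def test_grows_only_seeded_blob(self):
        stack = _stack_from(_two_blob_grid())
        mask = cp.region_grow(stack, "ch", (3, 3, 3), 100, 255)
        # oracle: scipy 26-connected component containing the seed
        labels, _ = ndimage.label(_two_blob_grid() >= 100,
                                  structure=ndimage.generate_binary_structure(3, 3))
        assert np.array_equal(mask.data, labels == labels[3, 3, 3])
        assert mask.voxel_count == 27

    def test_uniform_grid_grows_everywhere(self):
        stack = _stack_from(np.full((3, 3, 3), 50, np.uint8))
        assert cp.region_grow(stack, "ch", (1, 1, 1), 40, 60).data.all()

    def test_singleton_when_only_seed_matches(self):
        grid = np.zeros((3, 3, 3), np.uint8)
        grid[1, 1, 1] = 77
        mask = cp.region_grow(_stack_from(grid), "ch", (1, 1, 1), 77, 77)
        assert mask.voxel_count == 1

    def test_seed_outside_range_raises(self):
        stack = _stack_from(np.zeros((3, 3, 3), np.uint8))
        with pytest.raises(ValueError):
            cp.region_grow(stack, "ch", (0, 0, 0), 100, 255)

    def test_subset_of_threshold(self):
        stack = _stack_from(_two_blob_grid())
        grow = cp.region_grow(stack, "ch", (3, 3, 3), 100, 255)
        thresh = cp.threshold_mask(stack, "ch", cp.ThresholdParams(100, 255))
        assert not (grow.data & ~thresh.data).any()


class TestSplitMask:
    def test_two_components_sorted_by_size(self):
        mask = cp.Mask(_two_blob_grid() > 0, (1, 1, 1))
        parts = cp.split_mask(mask)
        assert [p.voxel_count for p in parts] == [27, 8]

    def test_union_and_disjointness(self):
        mask = cp.Mask(_two_blob_grid() > 0, (1, 1, 1))
        parts = cp.split_mask(mask)
        union = np.zeros_like(mask.data)
        for p in parts:
            assert not (union & p.data).any()
            union |= p.data
        assert np.array_equal(union, mask.data)

    def test_single_component_identity(self, sphere_mask):
        parts = cp.split_mask(sphere_mask)
        assert len(parts) == 1
        assert np.array_equal(parts[0].data, sphere_mask.data)

    def test_empty_mask_yields_empty_list(self):
        assert cp.split_mask(cp.Mask(np.zeros((3, 3, 3), bool), (1, 1, 1))) == []


class TestCropMask:
    def test_full_roi_is_identity(self):
        mask = cp.Mask(_two_blob_grid() > 0, (1, 1, 1))
        out = cp.crop_mask(mask, cp.ROI((0, 10), (0, 20), (0, 20)))
        assert np.array_equal(out.data, mask.data)

    def test_roi_keeps_only_enclosed_blob(self):
        mask = cp.Mask(_two_blob_grid() > 0, (1, 1, 1))
        out = cp.crop_mask(mask, cp.ROI((0, 6), (0, 10), (0, 10)))
        assert out.voxel_count == 27
        assert out.data.shape == mask.data.shape  # registration preserved

    def test_disjoint_roi_clears_everything(self):
        mask = cp.Mask(_two_blob_grid() > 0, (1, 1, 1))
        out = cp.crop_mask(mask, cp.ROI((8, 10), (0, 2), (0, 2)))
        assert out.voxel_count == 0

    def test_out_of_bounds_roi_raises(self):
        mask = cp.Mask(np.ones((3, 3, 3), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            cp.crop_mask(mask, cp.ROI((0, 4), (0, 3), (0, 3)))


class TestFillMask:
    def _hollow_sphere(self):
        n, r = 40, 12
        c = 20
        z, y, x = np.mgrid[0:n, 0:n, 0:n]
        d2 = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2
        shell = (d2 <= r**2) & (d2 >= (r - 2) ** 2)
        solid = d2 <= r**2
        return cp.Mask(shell, (1, 1, 1)), solid

    def test_volumetric_fill_closes_hollow_sphere(self):
        mask, solid = self._hollow_sphere()
        filled = cp.fill_mask(mask, "volumetric", radius=1)
        # the filled mask must contain the whole solid ball (shell + interior)
        assert filled.data[solid].all()
        # and stay close to it: closing with radius 1 may add a thin rind only
        assert filled.voxel_count <= ndimage.binary_dilation(solid, iterations=1).sum()

    def test_extensive_and_idempotent(self, sphere_mask):
        out1 = cp.fill_mask(sphere_mask, "volumetric", radius=2)
        assert (out1.data | sphere_mask.data).sum() == out1.voxel_count  # superset
        out2 = cp.fill_mask(out1, "volumetric", radius=2)
        assert np.array_equal(out1.data, out2.data)

    def test_already_solid_identity(self, sphere_mask):
        out = cp.fill_mask(sphere_mask, "per_slice", radius=0)
        assert np.array_equal(out.data, sphere_mask.data)

    def test_per_slice_fills_annulus_in_one_slice_only(self):
        data = np.zeros((5, 21, 21), bool)
        yy, xx = np.mgrid[0:21, 0:21]
        d2 = (yy - 10) ** 2 + (xx - 10) ** 2
        data[2] = (d2 <= 64) & (d2 >= 36)
        filled = cp.fill_mask(cp.Mask(data, (1, 1, 1)), "per_slice")
        disk = ndimage.binary_fill_holes(data[2])
        assert np.array_equal(filled.data[2], disk)
        assert not filled.data[[0, 1, 3, 4]].any()


class TestEditMask:
    def test_set_region(self):
        mask = cp.Mask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        out = cp.edit_mask(mask, set_regions=[cp.ROI((0, 2), (0, 2), (0, 2))])
        assert out.voxel_count == 8

    def test_set_then_clear_same_region_is_empty(self):
        mask = cp.Mask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        roi = cp.ROI((0, 2), (0, 2), (0, 2))
        out = cp.edit_mask(mask, set_regions=[roi], clear_regions=[roi])
        assert out.voxel_count == 0

    def test_clearing_corner_of_cube(self):
        mask = cp.Mask(np.ones((4, 4, 4), bool), (1, 1, 1))
        out = cp.edit_mask(mask, clear_regions=[cp.ROI((0, 2), (0, 2), (0, 2))])
        assert out.voxel_count == 64 - 8


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_split_partition_property(seed):
    """split_mask components always partition the input exactly."""
    rng = np.random.default_rng(seed)
    data = rng.random((6, 8, 8)) > 0.7
    parts = cp.split_mask(cp.Mask(data, (1, 1, 1)))
    union = np.zeros_like(data)
    total = 0
    for p in parts:
        assert not (union & p.data).any()
        union |= p.data
        total += p.voxel_count
    assert np.array_equal(union, data)
    assert total == int(data.sum())
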
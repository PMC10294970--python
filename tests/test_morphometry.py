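"""Feret diameters, projections and per-object morphometry records."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytoprint as cp


def _disk(radius_px=20, pad=4):
    n = 2 * (radius_px + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = n // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def _ellipse(a_um, b_um, px, angle_deg=0.0, pad_um=3.0):
    n = int(2 * (max(a_um, b_um) + pad_um) / px) + 1
    yy, xx = (np.mgrid[0:n, 0:n] * px)
    c = (n // 2) * px
    th = np.radians(angle_deg)
    xr = np.cos(th) * (xx - c) + np.sin(th) * (yy - c)
    yr = -np.sin(th) * (xx - c) + np.cos(th) * (yy - c)
    return (xr / a_um) ** 2 + (yr / b_um) ** 2 <= 1.0


def brute_force_feret(image2d, pixel_size, step_deg=0.25):
    """Oracle: caliper width over a dense fan of directions on all corners."""
    from cytoprint.morphometry import _corner_points

    pts = _corner_points(image2d, pixel_size)
    thetas = np.arange(0.0, 180.0, step_deg) * np.pi / 180.0
    dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    proj = pts @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.max()), float(widths.min())


class TestProjectMask:
    def test_single_slice_identity(self):
        data = np.zeros((1, 5, 5), bool)
        data[0, 1:4, 1:4] = True
        img, (dy, dx) = cp.project_mask(cp.Mask(data, (1.0, 0.5, 0.5)))
        assert np.array_equal(img, data[0])
        assert (dy, dx) == (0.5, 0.5)

    def test_two_slices_union(self):
        data = np.zeros((2, 6, 6), bool)
        data[0, 0:2, 0:2] = True
        data[1, 4:6, 4:6] = True
        img, _ = cp.project_mask(cp.Mask(data, (1, 1, 1)))
        assert img.sum() == 8

    def test_ellipsoid_projects_to_matching_ellipse(self):
        z, y, x = np.mgrid[0:21, 0:41, 0:41]
        data = ((z - 10) / 6.0) ** 2 + ((y - 20) / 15.0) ** 2 + ((x - 20) / 9.0) ** 2 <= 1
        img, _ = cp.project_mask(cp.Mask(data, (1, 1, 1)))
        expected = ((y[0] - 20) / 15.0) ** 2 + ((x[0] - 20) / 9.0) ** 2 <= 1
        assert (img ^ expected).sum() <= expected.sum() * 0.02  # within a pixel rim

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            cp.project_mask(cp.Mask(np.zeros((2, 2, 2), bool), (1, 1, 1)))


class TestFeretDiameters:
    def test_circle_diameter(self):
        # radius 5 um at 0.25 um pixels; the pixel-corner convention can add
        # up to ~1.4 px along diagonal caliper directions
        d1, d2 = cp.feret_diameters(_disk(20), (0.25, 0.25))
        assert d1 == pytest.approx(10.0, abs=1.5 * 0.25)
        assert d2 == pytest.approx(10.0, abs=1.5 * 0.25)
        assert d1 == pytest.approx(d2, rel=0.02)  # symmetry

    def test_epithelial_cell_body_axes(self):
        img = _ellipse(22.3, 17.95, px=0.25, angle_deg=25.0)
        d1, d2 = cp.feret_diameters(img, (0.25, 0.25))
        assert d1 == pytest.approx(44.6, rel=0.02)
        assert d2 == pytest.approx(35.9, rel=0.02)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_on_random_blobs(self, seed):
        rng = np.random.default_rng(seed)
        img = np.zeros((40, 40), bool)
        pts = rng.integers(5, 35, size=(20, 2))
        img[pts[:, 0], pts[:, 1]] = True
        d1, d2 = cp.feret_diameters(img, (1.0, 1.0))
        o1, o2 = brute_force_feret(img, (1.0, 1.0))
        assert d1 == pytest.approx(o1, rel=1e-3)
        assert d2 == pytest.approx(o2, rel=2e-3)

    def test_empty_image_raises(self):
        with pytest.raises(ValueError):
            cp.feret_diameters(np.zeros((4, 4), bool), (1, 1))


class TestMeasureObjects:
    def test_nucleus_phantom_recovery(self):
        rec = cp.validation.recover_morphometry("panc1_nucleus")
        assert rec.d1_um == pytest.approx(18.8, rel=0.02)
        assert rec.d2_um == pytest.approx(13.7, rel=0.02)
        assert rec.davg_um == pytest.approx((rec.d1_um + rec.d2_um) / 2)
        assert rec.davg_um == pytest.approx(16.25, rel=0.02)

    def test_two_identical_spheres_give_identical_records(self):
        z, y, x = np.mgrid[0:20, 0:20, 0:50] * 1.0
        a = (z - 10) ** 2 + (y - 10) ** 2 + (x - 10) ** 2 <= 36
        b = (z - 10) ** 2 + (y - 10) ** 2 + (x - 35) ** 2 <= 36
        recs = cp.measure_objects(cp.Mask(a | b, (1, 1, 1)))
        assert len(recs) == 2
        assert recs[0].d1_um == pytest.approx(recs[1].d1_um)
        assert recs[0].volume_um3 == pytest.approx(recs[1].volume_um3)

    def test_min_voxels_filter(self):
        data = np.zeros((5, 20, 20), bool)
        data[2, 2:10, 2:10] = True  # 64 voxels
        data[2, 15, 15] = True  # speck
        recs = cp.measure_objects(cp.Mask(data, (1, 1, 1)), min_voxels=8)
        assert len(recs) == 1

    def test_empty_mask_gives_empty_list(self):
        assert cp.measure_objects(cp.Mask(np.zeros((3, 3, 3), bool), (1, 1, 1))) == []

    def test_davg_suppressed_for_elongated_objects_in_report(self):
        rec = cp.MorphometryRecord(1, d1_um=40.0, d2_um=10.0, davg_um=25.0,
                                   area_um2=100.0, volume_um3=100.0)
        frame = cp.morphometry.records_to_frame([rec])
        assert np.isnan(frame["Davg_um"].iloc[0])


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_d1_dominates_d2_and_scales_linearly(seed):
    rng = np.random.default_rng(seed)
    img = np.zeros((30, 30), bool)
    pts = rng.integers(3, 27, size=(12, 2))
    img[pts[:, 0], pts[:, 1]] = True
    d1, d2 = cp.feret_diameters(img, (1.0, 1.0))
    assert d1 >= d2 > 0
    s1, s2 = cp.feret_diameters(img, (2.5, 2.5))
    assert s1 == pytest.approx(2.5 * d1, rel=1e-9)
    assert s2 == pytest.approx(2.5 * d2, rel=1e-9)


def test_recovered_axes_converge_with_finer_pixels():
    errs = []
    for px in (1.0, 0.25):
        img = _ellipse(22.3, 17.95, px=px, angle_deg=30.0)
        d1, _ = cp.feret_diameters(img, (px, px))
        errs.append(abs(d1 - 44.6))
    assert errs[1] < errs[0]
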
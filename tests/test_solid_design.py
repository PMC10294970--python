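"""Solidification, plane splitting, clearance Booleans, fit checks, assemblies."""

import numpy as np
import pytest
import trimesh

import cytoprint as cp
from cytoprint.errors import ConfigurationError, GeometryError

SHELL_VOL = 4.0 / 3.0 * np.pi * (11.0**3 - 10.0**3)  # r=10 shell t=1
FILLED_VOL = 4.0 / 3.0 * np.pi * 11.0**3


class TestSolidify:
    def test_shell_volume(self, sphere_mesh_mm):
        part = cp.solidify(sphere_mesh_mm, 1.0, "shell")
        assert part.is_watertight
        assert part.volume == pytest.approx(SHELL_VOL, rel=0.05)
        assert part.wall_thickness == 1.0

    def test_filled_volume(self, sphere_mesh_mm):
        part = cp.solidify(sphere_mesh_mm, 1.0, "filled")
        assert part.is_watertight
        assert part.volume == pytest.approx(FILLED_VOL, rel=0.05)
        assert part.wall_thickness == "filled"

    def test_open_hemisphere_closed_by_offset(self, sphere_mesh_mm):
        hemi = sphere_mesh_mm.mesh.copy()
        hemi.update_faces(hemi.triangles_center[:, 2] < 0)
        part = cp.solidify(cp.SurfaceMesh(hemi, unit="mm"), 1.0, "filled")
        assert part.is_watertight
        assert part.volume > 0

    def test_nonpositive_thickness_rejected(self, sphere_mesh_mm):
        with pytest.raises(ValueError):
            cp.solidify(sphere_mesh_mm, 0.0, "filled")


class TestPlaneSplit:
    def test_unit_cube_halves(self):
        part = cp.SolidPart(trimesh.creation.box(extents=(1, 1, 1)), name="cube")
        upper, lower = cp.plane_split(part, cp.Plane((0, 0, 0), (0, 0, 1)))
        assert upper.volume == pytest.approx(0.5, rel=0.01)
        assert lower.volume == pytest.approx(0.5, rel=0.01)
        assert upper.is_watertight and lower.is_watertight

    def test_sphere_centroid_split_symmetric(self):
        part = cp.SolidPart(trimesh.creation.icosphere(3, 10.0), name="s")
        upper, lower = cp.plane_split(part, cp.Plane((0, 0, 0), (0, 0, 1)))
        total = part.volume
        assert abs(upper.volume - lower.volume) / total < 0.01
        assert upper.volume + lower.volume == pytest.approx(total, rel=0.01)

    def test_cap_split_conserves_volume(self):
        part = cp.SolidPart(trimesh.creation.icosphere(3, 10.0), name="s")
        upper, lower = cp.plane_split(part, cp.Plane((0, 0, 9.0), (0, 0, 1)))
        assert upper.volume + lower.volume == pytest.approx(part.volume, rel=0.01)
        assert upper.volume < 0.02 * part.volume  # a thin cap

    def test_missing_plane_flags_and_returns_part(self):
        part = cp.SolidPart(trimesh.creation.box(extents=(1, 1, 1)), name="cube")
        kept, other = cp.plane_split(part, cp.Plane((0, 0, 10.0), (0, 0, 1)))
        assert other is None
        assert kept.meta.get("split_missed")
        assert kept.volume == pytest.approx(part.volume, rel=1e-6)


class TestSubtractInsert:
    def test_cube_cavity_with_unit_clearance(self, cube_part, insert_part):
        out = cp.subtract_insert(cube_part, insert_part, 1.0)
        assert out.is_watertight
        assert out.volume == pytest.approx(8000 - 1728, rel=0.02)

    def test_small_clearance_approaches_plain_difference(self, cube_part, insert_part):
        out = cp.subtract_insert(cube_part, insert_part, 0.01)
        assert out.volume == pytest.approx(8000 - 1000, rel=0.02)

    def test_insert_outside_host_leaves_host(self, cube_part):
        far = cp.SolidPart(
            trimesh.creation.box(extents=(5, 5, 5),
                                 transform=trimesh.transformations.translation_matrix((30, 0, 0))),
            name="far")
        out = cp.subtract_insert(cube_part, far, 1.0)
        assert out.volume == pytest.approx(cube_part.volume, rel=0.02)

    def test_result_never_intersects_insert(self, cube_part, insert_part):
        out = cp.subtract_insert(cube_part, insert_part, 0.5)
        report = cp.verify_fit(out, insert_part, 0.5)
        assert report["intersection_volume"] <= report["voxel_tolerance"] ** 3 * 4

    def test_host_volume_strictly_decreases_with_clearance(self, cube_part, insert_part):
        vols = [cp.subtract_insert(cube_part, insert_part, c).volume
                for c in (0.3, 0.6, 0.9)]
        assert vols[0] > vols[1] > vols[2]

    def test_nonpositive_clearance_rejected(self, cube_part, insert_part):
        with pytest.raises(ValueError):
            cp.subtract_insert(cube_part, insert_part, 0.0)


class TestVerifyFit:
    def test_designed_fit_passes_with_expected_gap(self, cube_part, insert_part):
        host = cp.subtract_insert(cube_part, insert_part, 1.0)
        report = cp.verify_fit(host, insert_part, 1.0)
        assert report["pass"]
        assert report["min_gap"] == pytest.approx(1.0, abs=2 * report["voxel_tolerance"])

    def test_touching_insert_still_passes(self, cube_part, insert_part):
        host = cp.subtract_insert(cube_part, insert_part, 1.0)
        touching = cp.SolidPart(
            trimesh.creation.box(extents=(10, 10, 10),
                                 transform=trimesh.transformations.translation_matrix((1, 0, 0))),
            name="touching")
        report = cp.verify_fit(host, touching, 1.0)
        assert report["pass"]
        assert report["min_gap"] == pytest.approx(0.0, abs=report["voxel_tolerance"])

    def test_oversized_insert_fails(self, cube_part, insert_part):
        host = cp.subtract_insert(cube_part, insert_part, 1.0)
        big = cp.SolidPart(trimesh.creation.box(extents=(15, 15, 15)), name="big")
        report = cp.verify_fit(host, big, 1.0)
        assert not report["pass"]
        assert report["intersection_volume"] > 0


class TestBuildAssembly:
    def _toy_parts(self):
        host = cp.SolidPart(trimesh.creation.box(extents=(20, 20, 20)), name="cell")
        nuc = cp.SolidPart(trimesh.creation.icosphere(2, 4.0), name="nucleus")
        extra = cp.SolidPart(
            trimesh.creation.box(extents=(4, 4, 18),
                                 transform=trimesh.transformations.translation_matrix((7, 7, 0))),
            name="fibers")
        return host, nuc, extra

    def test_split_plus_fit_gives_three_parts(self, tmp_path):
        host, nuc, _ = self._toy_parts()
        assembly, paths = cp.build_assembly(
            {"cell": host, "nucleus": nuc},
            splits=[("cell", cp.Plane((0, 0, 0), (0, 0, 1)))],
            fits=[("cell", "nucleus", 0.3)],
            out_dir=tmp_path, model_name="toy")
        assert len(paths) == 3
        assert set(assembly.parts) == {"cell_upper", "cell_lower", "nucleus"}
        for part in assembly.parts.values():
            assert part.is_watertight and part.volume > 0

    def test_three_structures_no_split(self, tmp_path):
        host, nuc, extra = self._toy_parts()
        assembly, paths = cp.build_assembly(
            {"factin": host, "asma": extra, "nuclei": nuc},
            fits=[("factin", "nuclei", 0.3)],
            out_dir=tmp_path, model_name="toy3")
        assert len(paths) == 3

    def test_two_structures_single_fit(self, tmp_path):
        host, nuc, _ = self._toy_parts()
        assembly, paths = cp.build_assembly(
            {"factin": host, "nucleus": nuc},
            fits=[("factin", "nucleus", 0.3)],
            out_dir=tmp_path, model_name="toy2")
        assert len(paths) == 2
        manifest = assembly.manifest()
        assert len(manifest["parts"]) == 2
        assert manifest["fits"][0]["clearance"] == 0.3

    def test_unresolved_names_rejected(self):
        host, nuc, _ = self._toy_parts()
        with pytest.raises(ConfigurationError):
            cp.build_assembly({"cell": host}, fits=[("cell", "ghost", 0.3)])

    def test_zero_clearance_fit_rejected(self):
        host, nuc, _ = self._toy_parts()
        with pytest.raises((ConfigurationError, ValueError)):
            cp.build_assembly({"cell": host, "nucleus": nuc},
                              fits=[("cell", "nucleus", 0.0)])
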
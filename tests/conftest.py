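import numpy as np
import pytest
import trimesh

import cytoprint as cp


def digitized_sphere_mask(radius_um: float = 10.0, voxel: float = 0.5) -> cp.Mask:
    """Solid sphere digitised at isotropic voxels, fully inside the grid."""
    n = int(2 * radius_um / voxel) + 8
    c = (n // 2) * voxel
    z, y, x = np.mgrid[0:n, 0:n, 0:n] * voxel
    data = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius_um**2
    return cp.Mask(data, (voxel, voxel, voxel))


@pytest.fixture(scope="session")
def sphere_mask() -> cp.Mask:
    return digitized_sphere_mask(10.0, 0.5)


@pytest.fixture(scope="session")
def sphere_surface(sphere_mask) -> cp.SurfaceMesh:
    return cp.extract_surface(sphere_mask)


@pytest.fixture(scope="session")
def sphere_mesh_mm() -> cp.SurfaceMesh:
    """Analytic icosphere r=10, treated as model-scale (mm)."""
    return cp.SurfaceMesh(trimesh.creation.icosphere(subdivisions=3, radius=10.0), unit="mm")


@pytest.fixture(scope="session")
def cube_part() -> cp.SolidPart:
    return cp.SolidPart(trimesh.creation.box(extents=(20.0, 20.0, 20.0)), name="host")


@pytest.fixture(scope="session")
def insert_part() -> cp.SolidPart:
    return cp.SolidPart(trimesh.creation.box(extents=(10.0, 10.0, 10.0)), name="insert")


@pytest.fixture(scope="session")
def panc1_run(tmp_path_factory):
    """One full PANC-1 pipeline run shared across tests (it is the slow part)."""
    out = tmp_path_factory.mktemp("panc1_run")
    count, result = cp.validation.preset_part_count("panc1_like", out, seed=1)
    return count, result


@pytest.fixture(scope="session")
def hdf_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("hdf_run")
    count, result = cp.validation.preset_part_count("hdf_like", out, seed=1)
    return count, result


@pytest.fixture(scope="session")
def shsy5y_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("shsy5y_run")
    count, result = cp.validation.preset_part_count("shsy5y_like", out, seed=1)
    return count, result
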
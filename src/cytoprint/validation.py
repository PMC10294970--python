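"""Desk-scale validation experiments: recover known phantom geometry.

These helpers generate noise-free, PSF-off phantoms whose configured
in-plane axes are the archetype morphometrics, push them through the
segmentation + morphometry chain, and report the measured diameters — a
closed-loop check that the pipeline measures what was put in.  They are
used by the test suite and the acceptance script alike.
"""

from __future__ import annotations

import dataclasses

from .morphometry import MorphometryRecord, measure_objects
from .phantom import CellSpec, PhantomSpec, generate_cell_phantom
from .pipeline import preset_run_config, run_pipeline
from .segmentation import ThresholdParams, fill_mask, threshold_mask

__all__ = ["ARCHETYPE_BODIES", "recovery_spec", "recover_morphometry", "preset_part_count"]

# archetype -> (channel, configured in-plane diameters D1/D2 um, phantom layout)
ARCHETYPE_BODIES: dict[str, dict] = {
    "panc1_body": dict(
        channel="TRITC", d1=44.6, d2=35.9,
        shape=(16, 256, 256), voxel=(15.0 / 16, 0.25, 0.25),
        cell=dict(semi_axes=(22.3, 17.95, 5.5), center=(32.0, 32.0, 7.5),
                  angle_deg=20.0, body_shape="ellipsoid", shell_thickness_um=1.2),
    ),
    "panc1_nucleus": dict(
        channel="DAPI", d1=18.8, d2=13.7,
        shape=(16, 256, 256), voxel=(15.0 / 16, 0.25, 0.25),
        cell=dict(semi_axes=(22.3, 17.95, 5.5), center=(32.0, 32.0, 7.5),
                  angle_deg=20.0, body_shape="ellipsoid", shell_thickness_um=1.2,
                  nucleus_semi_axes=(9.4, 6.85, 3.5)),
    ),
    "shsy5y_body": dict(
        channel="TRITC", d1=16.5, d2=9.7,
        shape=(36, 256, 256), voxel=(10.0 / 36, 0.1, 0.1),
        cell=dict(semi_axes=(8.25, 4.85, 2.6), center=(12.8, 12.8, 5.0),
                  angle_deg=15.0, body_shape="polygon", shell_thickness_um=0.8),
    ),
    "hdf_body": dict(
        channel="TRITC", d1=195.5, d2=43.4,
        shape=(33, 512, 512), voxel=(16.0 / 33, 0.5, 0.5),
        cell=dict(semi_axes=(97.75, 21.7, 5.0), center=(128.0, 128.0, 8.0),
                  angle_deg=15.0, body_shape="spindle", shell_thickness_um=1.5),
    ),
}


def recovery_spec(archetype: str, seed: int = 0) -> PhantomSpec:
    """A noise-free, PSF-off single-cell phantom for one archetype body/nucleus."""
    conf = ARCHETYPE_BODIES[archetype]
    return PhantomSpec(
        shape=conf["shape"],
        voxel_size=conf["voxel"],
        cells=[CellSpec(**conf["cell"])],
        psf_sigma_um=(0.0, 0.0, 0.0),
        noise="none",
        seed=seed,
    )


def recover_morphometry(archetype: str, seed: int = 0) -> MorphometryRecord:
    """Generate, threshold at half-max, fill, project and measure; largest object."""
    conf = ARCHETYPE_BODIES[archetype]
    stack, _ = generate_cell_phantom(recovery_spec(archetype, seed))
    grid = stack.channel(conf["channel"])
    mask = threshold_mask(stack, conf["channel"],
                          ThresholdParams(float(grid.max()) / 2.0, 2 ** stack.bit_depth - 1))
    mask = fill_mask(mask, mode="volumetric", radius=2)
    records = measure_objects(mask, min_voxels=64)
    return records[0]


def preset_part_count(name: str, out_dir, seed: int = 0) -> tuple[int, dict]:
    """Run the full dismountable pipeline on a preset; STL part count + result."""
    result = run_pipeline(preset_run_config(name, out_dir=out_dir, seed=seed))
    return len(result["stl_paths"]), result
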
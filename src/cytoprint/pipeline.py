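"""End-to-end runs: stack (or phantom) → masks → meshes → scaled solids →
dismountable assembly → reports.

A single :class:`RunConfig` drives everything so a run is reproducible from
its config + seed alone.  Stages execute in a fixed order — acquire,
segment, fill, mesh, smooth, scale, solidify, fit/split, report — and the
log narrates each stage with the parameters and derived quantities
(magnification, print resolution, part volumes).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import yaml

from . import morphometry, phantom, scaling_print, segmentation, solid_design, stack_io
from .errors import ConfigurationError
from .meshing import decimate_mesh, extract_surface, smooth_mesh
from .scaling_print import PrintConfig, ScaleMap, apply_scale, print_resolution
from .segmentation import ThresholdParams, fill_mask, threshold_mask
from .solid_design import Plane, build_assembly

__all__ = ["StructureConfig", "RunConfig", "run_pipeline", "preset_run_config", "load_config"]

logger = logging.getLogger("cytoprint")


@dataclasses.dataclass
class StructureConfig:
    """How one channel becomes one printable structure."""

    name: str
    channel: str
    color: str = "white"
    threshold: tuple[float, float] | None = None  # None: half-max band
    fill_mode: str = "volumetric"
    fill_radius: int = 2
    solidify_mode: str = "filled"


@dataclasses.dataclass
class RunConfig:
    """Everything a pipeline run needs; exactly one of input_path / preset."""

    structures: list[StructureConfig]
    input_path: str | None = None
    preset: str | None = None
    voxel_size: tuple[float, float, float] | None = None  # µm override for files
    channels: list[str] | None = None
    smooth_iterations: int = 10
    smooth_strength: float = 0.5
    decimate_fraction: float | None = None
    mesh_gaussian_sigma: float = 0.7  # voxels, pre-marching-cubes smoothing
    solidify_thickness_mm: float = 1.0
    splits: list[str] = dataclasses.field(default_factory=list)
    fits: list[tuple[str, str, float]] = dataclasses.field(default_factory=list)
    magnification: float | None = None
    target_size_mm: float | None = None
    print_config: PrintConfig = dataclasses.field(default_factory=PrintConfig)
    max_grid: int = solid_design.DEFAULT_MAX_GRID
    out_dir: str = "cytoprint_out"
    model_name: str = "model"
    seed: int = 0

    def __post_init__(self):
        if (self.input_path is None) == (self.preset is None):
            raise ConfigurationError("exactly one of input_path / preset must be set")
        if self.magnification is None and self.target_size_mm is None:
            raise ConfigurationError("set magnification or target_size_mm")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["structures"] = [StructureConfig(**s) for s in d.get("structures", [])]
        if "print_config" in d and isinstance(d["print_config"], dict):
            d["print_config"] = PrintConfig(**d["print_config"])
        if "fits" in d:
            d["fits"] = [tuple(f) for f in d["fits"]]
        if "voxel_size" in d and d["voxel_size"] is not None:
            d["voxel_size"] = tuple(d["voxel_size"])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _acquire(config: RunConfig):
    if config.preset is not None:
        spec = phantom.preset(config.preset, seed=config.seed)
        stack, truth = phantom.generate_cell_phantom(spec)
        return stack, truth
    stack = stack_io.read_stack(
        config.input_path, voxel_size=config.voxel_size, channels=config.channels,
    )
    return stack, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns a result dict with paths and reports."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / f"{config.model_name}_run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        logger.info("run finished in %.1f s", time.time() - t0)
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path) -> dict:
    stage = "acquire"
    try:
        logger.info("stage acquire: %s", config.preset or config.input_path)
        stack, truth = _acquire(config)
        logger.info("stack shape %s, voxel size %s um", stack.shape, stack.voxel_size)

        maxval = 2 ** stack.bit_depth - 1
        masks = {}
        records_all = []
        stage = "segment"
        for s in config.structures:
            grid = stack.channel(s.channel)
            if s.threshold is not None:
                params = ThresholdParams(*s.threshold)
            else:
                params = ThresholdParams(float(grid.max()) / 2.0, maxval)
            mask = threshold_mask(stack, s.channel, params)
            mask = fill_mask(mask, mode=s.fill_mode, radius=s.fill_radius)
            masks[s.name] = mask
            logger.info("stage segment: %s from %s, band [%g, %g], %d voxels",
                        s.name, s.channel, params.gv_min, params.gv_max, mask.voxel_count)

        stage = "morphometry"
        for s in config.structures:
            for rec in morphometry.measure_objects(masks[s.name], min_voxels=64):
                records_all.append((s.name, rec))
        morph_path = out_dir / f"{config.model_name}_morphometry.csv"
        frame = morphometry.records_to_frame([r for _, r in records_all])
        frame.insert(0, "structure", [n for n, _ in records_all])
        frame.to_csv(morph_path, index=False)
        logger.info("stage morphometry: %d objects -> %s", len(records_all), morph_path.name)

        stage = "mesh"
        surfaces = {}
        for s in config.structures:
            surf = extract_surface(masks[s.name], gaussian_sigma=config.mesh_gaussian_sigma)
            if config.smooth_iterations:
                surf = smooth_mesh(surf, config.smooth_iterations, config.smooth_strength)
            if config.decimate_fraction:
                surf = decimate_mesh(surf, config.decimate_fraction)
            surfaces[s.name] = surf
            logger.info("stage mesh: %s -> %d faces, area %.1f um^2",
                        s.name, surf.face_count, surf.area)

        stage = "scale"
        if config.magnification is not None:
            scale = ScaleMap(config.magnification)
        else:
            longest = max(float(s.mesh.extents.max()) for s in surfaces.values())
            scale = scaling_print.make_scale_map(longest, config.target_size_mm)
        resolution = print_resolution(scale, config.print_config)
        logger.info("stage scale: M=%g, print resolution %.4g um/layer at %.2g mm layers",
                    scale.magnification, resolution, config.print_config.layer_height)
        scaled = {name: apply_scale(surf, scale) for name, surf in surfaces.items()}

        stage = "solidify"
        parts = {}
        for s in config.structures:
            part = solid_design.solidify(
                scaled[s.name], config.solidify_thickness_mm, s.solidify_mode,
                name=s.name, color_tag=s.color, max_grid=config.max_grid,
            )
            parts[s.name] = part
            logger.info("stage solidify: %s (%s, %.2g mm) -> %.1f mm^3, watertight=%s",
                        s.name, s.solidify_mode, config.solidify_thickness_mm,
                        part.volume, part.is_watertight)

        stage = "assemble"
        splits = [(name, None) for name in config.splits]
        assembly, stl_paths = build_assembly(
            parts, splits=splits, fits=config.fits, out_dir=out_dir,
            model_name=config.model_name, max_grid=config.max_grid,
        )
        for name, part in assembly.parts.items():
            logger.info("stage assemble: part %s volume %.1f mm^3 watertight=%s",
                        name, part.volume, part.is_watertight)

        stage = "report"
        reports = {
            "magnification": scale.magnification,
            "print_resolution_um": resolution,
            "layer_height_mm": config.print_config.layer_height,
            "parts": {},
        }
        for name, part in assembly.parts.items():
            reports["parts"][name] = scaling_print.printability_report(
                part, config.print_config)
        report_path = out_dir / f"{config.model_name}_print_report.json"
        report_path.write_text(json.dumps(reports, indent=2))
        logger.info("stage report: %s", report_path.name)

        return {
            "out_dir": out_dir,
            "stl_paths": stl_paths,
            "assembly": assembly,
            "scale": scale,
            "print_report": reports,
            "morphometry": frame,
            "masks": masks,
            "truth": truth,
        }
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise type(exc)(f"[stage {stage}] {exc}") from exc


# Magnifications follow each archetype's model:original scale bar
# (1 cm : 10 µm, 2 cm : 100 µm, 5 cm : 5 µm).
_PRESET_MAGNIFICATION = {"panc1_like": 1000.0, "hdf_like": 200.0, "shsy5y_like": 10000.0}


def preset_run_config(name: str, out_dir: str | Path = "cytoprint_out", seed: int = 0,
                      **overrides) -> RunConfig:
    """The default end-to-end configuration for each phantom preset.

    * ``panc1_like``: cell surface (from the cortical f-actin channel) split
      into upper/lower halves around the fitted nucleus — a 3-part model.
    * ``hdf_like``: f-actin and α-SMA cytoskeletons as separate solids plus
      the fitted nuclei — 3 parts, no plane split.
    * ``shsy5y_like``: f-actin body hosting the fitted nucleus — 2 parts.
    """
    clearance = solid_design.DEFAULT_CLEARANCE
    # known-good grey-value bands for the phantom presets: cortical shells
    # are thin relative to the PSF, so their blurred intensity at the cell's
    # top/bottom caps drops to ~45% of the in-plane peak — a half-max band
    # would cut the caps off and the body would not close.  Nuclei are solid
    # blobs whose half-max contour is their boundary, so they keep the
    # adaptive default.
    # the neuron-like preset's 0.8 um shell is thinner than the axial PSF,
    # so its cap signal is weaker still
    shell_band = (40.0, 255.0) if name == "shsy5y_like" else (50.0, 255.0)
    if name == "panc1_like":
        structures = [
            StructureConfig("cell", "TRITC", color="translucent", threshold=shell_band),
            StructureConfig("nucleus", "DAPI", color="blue"),
        ]
        splits, fits = ["cell"], [("cell", "nucleus", clearance)]
    elif name == "hdf_like":
        structures = [
            StructureConfig("factin", "TRITC", color="red", threshold=shell_band),
            StructureConfig("asma", "AF647", color="mint", threshold=shell_band),
            StructureConfig("nuclei", "DAPI", color="blue"),
        ]
        splits, fits = [], [("factin", "nuclei", clearance)]
    elif name == "shsy5y_like":
        structures = [
            StructureConfig("factin", "TRITC", color="red", threshold=shell_band),
            StructureConfig("nucleus", "DAPI", color="blue"),
        ]
        splits, fits = [], [("factin", "nucleus", clearance)]
    else:
        raise KeyError(f"unknown preset {name!r}")
    cfg = dict(
        structures=structures,
        preset=name,
        splits=splits,
        fits=fits,
        magnification=_PRESET_MAGNIFICATION[name],
        out_dir=str(out_dir),
        model_name=name.replace("_like", ""),
        seed=seed,
    )
    cfg.update(overrides)
    return RunConfig(**cfg)
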
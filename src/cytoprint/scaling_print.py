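"""µm → mm magnification, print configuration, and printability reporting.

A cultured cell is a few tens of µm across; an FDM printer works in mm with
a ~0.2 mm layer.  The :class:`ScaleMap` carries the magnification
``M = model length / original length`` (dimensionless), meshes are rescaled
by ``M x 10^-3`` from µm into model mm, and the print-resolution report
states the original-scale feature size one printed layer represents,
``h x 10^3 / M`` µm for layer height ``h`` mm.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import UnitError
from .meshing import SurfaceMesh

__all__ = [
    "ScaleMap",
    "PrintConfig",
    "make_scale_map",
    "scale_map_for_target",
    "apply_scale",
    "invert_scale",
    "print_resolution",
    "printability_report",
]

# a large-format desktop FDM build volume (mm); override per printer
DEFAULT_BUILD_VOLUME = (330.0, 240.0, 300.0)


@dataclasses.dataclass(frozen=True)
class ScaleMap:
    """Magnification between original µm and model mm."""

    magnification: float  # model length / original length, dimensionless
    original_unit: str = "um"
    model_unit: str = "mm"

    def __post_init__(self):
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")

    @property
    def um_to_mm(self) -> float:
        """Coordinate multiplier taking µm vertex coordinates to model mm."""
        return self.magnification * 1e-3


@dataclasses.dataclass(frozen=True)
class PrintConfig:
    """FDM settings that drive the print report (not a slicer)."""

    layer_height: float = 0.2  # mm
    infill_percent: float = 10.0
    infill_pattern: str = "triangular"
    min_wall: float = 1.0  # mm; walls at/above this print stably
    supports: bool = True

    def __post_init__(self):
        if self.layer_height <= 0:
            raise ValueError("layer height must be positive")
        if not (0 <= self.infill_percent <= 100):
            raise ValueError("infill must be a percentage")


def make_scale_map(original_length_um: float, model_length_mm: float) -> ScaleMap:
    """Magnification from a stated model:original scale bar.

    ``1 cm (model) : 10 µm (original)`` is ``make_scale_map(10, 10)`` -> M=1000.
    """
    if original_length_um <= 0 or model_length_mm <= 0:
        raise ValueError("lengths must be positive")
    return ScaleMap(model_length_mm / (original_length_um * 1e-3))


def scale_map_for_target(surface: SurfaceMesh, target_longest_mm: float) -> ScaleMap:
    """Auto-fit: magnification that makes the mesh's longest extent ``target`` mm."""
    extent_um = float(np.max(surface.mesh.extents))
    return make_scale_map(extent_um, target_longest_mm)


def apply_scale(surface: SurfaceMesh, scale: ScaleMap) -> SurfaceMesh:
    """Rescale a µm mesh into model mm (lengths x M·10⁻³, volumes cubed)."""
    if surface.unit != scale.original_unit:
        raise UnitError(f"apply_scale expects a {scale.original_unit} mesh, got {surface.unit}")
    tm = surface.mesh.copy()
    tm.apply_scale(scale.um_to_mm)
    out = SurfaceMesh(tm, unit=scale.model_unit, meta=dict(surface.meta))
    return out.with_history(f"apply_scale(M={scale.magnification})")


def invert_scale(surface: SurfaceMesh, scale: ScaleMap) -> SurfaceMesh:
    """Undo :func:`apply_scale`; round-trips coordinates to ~1e-9 relative."""
    if surface.unit != scale.model_unit:
        raise UnitError(f"invert_scale expects a {scale.model_unit} mesh, got {surface.unit}")
    tm = surface.mesh.copy()
    tm.apply_scale(1.0 / scale.um_to_mm)
    out = SurfaceMesh(tm, unit=scale.original_unit, meta=dict(surface.meta))
    return out.with_history(f"invert_scale(M={scale.magnification})")


def print_resolution(scale: ScaleMap, config: PrintConfig) -> float:
    """Original-scale feature size (µm) that one printed layer represents."""
    return config.layer_height * 1e3 / scale.magnification


def _first_hits(triangles: np.ndarray, origins: np.ndarray,
                directions: np.ndarray) -> np.ndarray:
    """Nearest positive ray-triangle intersection distance per ray (NaN if none).

    Vectorised Möller–Trumbore over all (ray, triangle) pairs, chunked to
    bound memory.
    """
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    out = np.full(len(origins), np.nan)
    chunk = max(int(4e6 // max(len(triangles), 1)), 1)
    eps = 1e-12
    for s in range(0, len(origins), chunk):
        o = origins[s:s + chunk][:, None, :]
        d = directions[s:s + chunk][:, None, :]
        p = np.cross(d, e2[None, :, :])
        det = np.einsum("rtk,tk->rt", p, e1)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), np.nan)
        tvec = o - v0[None, :, :]
        u = np.einsum("rtk,rtk->rt", tvec, p) * inv
        q = np.cross(tvec, e1[None, :, :])
        v = np.einsum("rtk,rk->rt", q, directions[s:s + chunk]) * inv
        t = np.einsum("rtk,tk->rt", q, e2) * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > eps)
        t = np.where(hit, t, np.inf)
        best = t.min(axis=1)
        out[s:s + chunk] = np.where(np.isfinite(best), best, np.nan)
    return out


def _ray_wall_thickness(mesh, n_samples: int, seed: int = 0) -> np.ndarray:
    """Inward ray-cast wall thicknesses at sampled surface points."""
    rng = np.random.default_rng(seed)
    n_faces = len(mesh.faces)
    take = min(n_samples, n_faces)
    idx = rng.permutation(n_faces)[:take] if take < n_faces else np.arange(n_faces)
    normals = mesh.face_normals[idx]
    eps = 1e-4 * float(np.max(mesh.extents))
    origins = mesh.triangles_center[idx] - normals * eps
    t = _first_hits(mesh.triangles.view(np.ndarray), origins, -normals)
    return t[np.isfinite(t)]


def printability_report(part, config: PrintConfig = PrintConfig(),
                        build_volume: tuple[float, float, float] = DEFAULT_BUILD_VOLUME,
                        n_samples: int = 96) -> dict:
    """Estimate the minimum wall thickness and check part vs build volume.

    Walls are probed by casting rays inward from sampled surface points; a
    part is flagged stable iff the minimum wall is at least ``config.min_wall``
    (1 mm by default — the empirical FDM stability threshold).
    """
    mesh = getattr(part, "mesh", part)
    walls = _ray_wall_thickness(mesh, n_samples)
    min_wall = float(walls.min()) if len(walls) else float("nan")
    extents = mesh.extents
    fits = bool(np.all(np.sort(extents) <= np.sort(np.asarray(build_volume))))
    return {
        "part": getattr(part, "name", "part"),
        "min_wall_mm": min_wall,
        "median_wall_mm": float(np.median(walls)) if len(walls) else float("nan"),
        "stable": bool(len(walls) and min_wall >= config.min_wall),
        "min_wall_required_mm": config.min_wall,
        "bounding_box_mm": [float(e) for e in extents],
        "build_volume_mm": list(build_volume),
        "fits_build_volume": fits,
        "layer_height_mm": config.layer_height,
        "infill_percent": config.infill_percent,
        "infill_pattern": config.infill_pattern,
        "supports": config.supports,
    }
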
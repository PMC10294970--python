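"""Cell and nucleus morphometry: Feret diameters, projected area, volume.

Adherent cultured cells are flat, so the longest (D1) and shortest (D2)
caliper diameters are measured in-plane on the z-projection of each mask
component; ``Davg = (D1 + D2) / 2``.  Calipers use rotating directions over
the convex hull of the foreground *pixel corners* (pixel-as-square region),
the usual binary-image convention.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .segmentation import Mask

__all__ = [
    "MorphometryRecord",
    "project_mask",
    "feret_diameters",
    "measure_objects",
    "records_to_frame",
    "write_morphometry_csv",
]

_CONN26 = ndimage.generate_binary_structure(3, 3)

# suppress Davg in reports above this elongation (spindles: an "average
# diameter" of a 5:1 cell is not a meaningful size)
ELONGATION_SUPPRESS_RATIO = 3.0


@dataclasses.dataclass(frozen=True)
class MorphometryRecord:
    """Per-object measurements, µm-based."""

    object_id: int
    d1_um: float  # longest caliper diameter
    d2_um: float  # shortest caliper diameter
    davg_um: float  # (D1 + D2) / 2
    area_um2: float  # projected area
    volume_um3: float

    def __post_init__(self):
        if not (self.d1_um >= self.d2_um > 0):
            raise ValueError(f"need D1 >= D2 > 0, got {self.d1_um}, {self.d2_um}")

    @property
    def elongation(self) -> float:
        return self.d1_um / self.d2_um


def project_mask(mask: Mask) -> tuple[np.ndarray, tuple[float, float]]:
    """Logical-OR projection along z; returns (2D image, (dy, dx))."""
    if not mask.data.any():
        raise ValueError("cannot project an empty mask")
    return mask.data.any(axis=0), (mask.voxel_size[1], mask.voxel_size[2])


def _corner_points(image2d: np.ndarray, pixel_size: tuple[float, float]) -> np.ndarray:
    """Corners of the boundary pixels, as (x, y) in µm."""
    img = np.asarray(image2d, dtype=bool)
    interior = ndimage.binary_erosion(img)
    boundary = img & ~interior
    if not boundary.any():
        boundary = img
    iy, ix = np.nonzero(boundary)
    dy, dx = pixel_size
    x = ix * dx
    y = iy * dy
    hx, hy = dx / 2.0, dy / 2.0
    return np.concatenate([
        np.stack([x - hx, y - hy], axis=1),
        np.stack([x + hx, y - hy], axis=1),
        np.stack([x - hx, y + hy], axis=1),
        np.stack([x + hx, y + hy], axis=1),
    ])


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    if len(points) <= 3:
        return points
    hull = ConvexHull(points)
    return points[hull.vertices]


def feret_diameters(image2d: np.ndarray, pixel_size: tuple[float, float]) -> tuple[float, float]:
    """Maximum (D1) and minimum (D2) caliper diameters of the foreground, µm.

    D1 is the largest point pair distance on the convex hull; D2 comes from
    rotating calipers (the minimum width is attained perpendicular to some
    hull edge; ties break toward the smaller edge index).
    """
    if not np.asarray(image2d, dtype=bool).any():
        raise ValueError("empty image has no Feret diameters")
    pts = _hull_vertices(_corner_points(image2d, pixel_size))
    d1 = float(pdist(pts).max())
    # rotating calipers: width across each hull edge direction
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.linalg.norm(edges, axis=1)
    keep = lengths > 0
    normals = np.stack([-edges[keep][:, 1], edges[keep][:, 0]], axis=1) / lengths[keep, None]
    proj = pts @ normals.T  # (points, edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    d2 = float(widths.min())
    return d1, d2


def measure_objects(mask: Mask, min_voxels: int = 1) -> list[MorphometryRecord]:
    """One record per 26-connected component with at least ``min_voxels``."""
    labels, n = ndimage.label(mask.data, structure=_CONN26)
    records: list[MorphometryRecord] = []
    if n == 0:
        return records
    dz, dy, dx = mask.voxel_size
    counts = np.bincount(labels.ravel())
    objects = ndimage.find_objects(labels)
    oid = 0
    for lab in range(1, n + 1):
        if counts[lab] < min_voxels:
            continue
        sl = objects[lab - 1]
        comp = labels[sl] == lab
        proj = comp.any(axis=0)
        d1, d2 = feret_diameters(proj, (dy, dx))
        oid += 1
        records.append(MorphometryRecord(
            object_id=oid,
            d1_um=d1,
            d2_um=d2,
            davg_um=(d1 + d2) / 2.0,
            area_um2=float(proj.sum()) * dy * dx,
            volume_um3=float(counts[lab]) * dz * dy * dx,
        ))
    records.sort(key=lambda r: -r.volume_um3)
    return [dataclasses.replace(r, object_id=i + 1) for i, r in enumerate(records)]


def records_to_frame(records: list[MorphometryRecord],
                     suppress_elongated_davg: bool = True) -> pd.DataFrame:
    """Records as a table; Davg is blanked for very elongated objects."""
    rows = []
    for r in records:
        davg = r.davg_um
        if suppress_elongated_davg and r.elongation > ELONGATION_SUPPRESS_RATIO:
            davg = np.nan
        rows.append({"id": r.object_id, "D1_um": r.d1_um, "D2_um": r.d2_um,
                     "Davg_um": davg, "area_um2": r.area_um2, "volume_um3": r.volume_um3})
    return pd.DataFrame(rows, columns=["id", "D1_um", "D2_um", "Davg_um",
                                       "area_um2", "volume_um3"])


def write_morphometry_csv(records: list[MorphometryRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path
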
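"""Signed-distance voxel engine backing the solid-design operations.

Marching-cubes meshes of real cells are rarely clean enough for exact mesh
Booleans, so offsets, plane cuts and clearance subtractions all run on a
discretised signed-distance field (SDF):

1. sample every triangle on a barycentric lattice at half-pitch spacing and
   bin the samples into grid voxels, remembering for each touched voxel one
   surface sample and its outward normal;
2. flood-fill from the grid border to find the unambiguous outside, and
   classify surface-band voxels by the sign of ``(centre - sample) . normal``
   — a genuine voxel-centre inside test, so the occupancy carries no
   half-voxel inflation;
3. two Euclidean distance transforms give a signed field φ (> 0 inside,
   ≈ 0 on the surface); iso-bands far from the surface can be refined with
   exact point distances (KD-tree over the surface samples) before an
   offset level is extracted;
4. offsets, Booleans and plane cuts are min/max compositions on φ, and the
   result surface is re-extracted by marching cubes at level 0 — the linear
   interpolation places surfaces with sub-voxel accuracy.

Grid convention: fields are indexed ``[ix, iy, iz]`` with uniform pitch;
``origin`` is the physical position of voxel ``(0, 0, 0)``'s centre.  The
grid is phase-shifted half a pitch off the mesh bounding box so axis-aligned
planar faces fall midway between sample layers, where both the voxel
classification and marching cubes reconstruct them exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .errors import GeometryError

# 6-connectivity for the outside flood fill: the sampled surface band is
# face-tight, so the outside cannot leak through it diagonally
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)

_MAX_SAMPLE_BLOCK = 4_000_000  # points per rasterisation block (memory bound)


@dataclasses.dataclass
class SignedField:
    """Signed distance samples of a solid (positive inside) on a uniform grid."""

    phi: np.ndarray  # float32, indexed (ix, iy, iz)
    pitch: float
    origin: np.ndarray  # physical coords of voxel (0,0,0) centre
    surface_points: np.ndarray | None = None  # one representative per band voxel

    @property
    def solid(self) -> np.ndarray:
        return self.phi > 0

    @property
    def volume(self) -> float:
        return float((self.phi > 0).sum()) * self.pitch**3

    def centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.pitch * np.arange(self.phi.shape[axis])

    def grid_points(self) -> np.ndarray:
        """All voxel centre coordinates, shape (*grid, 3)."""
        cx, cy, cz = (self.centers(a) for a in range(3))
        return np.stack(np.meshgrid(cx, cy, cz, indexing="ij"), axis=-1)

    def refine_level(self, level: float) -> None:
        """Replace φ near an iso-level with exact distances to the surface samples.

        Worth doing for offset levels a couple of pitches away from the
        surface, where the voxel-centre EDT otherwise carries a curvature-
        dependent bias.  In-place.
        """
        if self.surface_points is None or abs(level) < 2.0 * self.pitch:
            return
        band = np.abs(self.phi - level) <= 1.5 * self.pitch
        if not band.any():
            return
        idx = np.argwhere(band)
        pts = self.origin[None, :] + idx * self.pitch
        d, _ = cKDTree(self.surface_points).query(pts, workers=-1)
        self.phi[band] = np.where(self.phi[band] > 0, d, -d).astype(np.float32)


def _bary_lattice(n: int) -> np.ndarray:
    """Barycentric lattice (m, 3) covering a triangle at subdivision n."""
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    keep = (i + j) <= n
    u = i[keep] / n
    v = j[keep] / n
    return np.stack([1.0 - u - v, u, v], axis=1)


def _grid_for(bounds: np.ndarray, pitch: float, pad: int,
              snap_axis: int | None = None, snap_value: float = 0.0) -> tuple[np.ndarray, tuple]:
    """Origin and shape covering ``bounds`` with ``pad`` spare voxels.

    The origin sits half a pitch off the bounding box so axis-aligned faces
    straddle sample layers; ``snap_axis`` additionally phases the grid so
    ``snap_value`` falls exactly midway between two layers (plane splits).
    """
    lo = bounds[0] - pad * pitch + 0.5 * pitch
    hi = bounds[1] + pad * pitch
    if snap_axis is not None:
        frac = (snap_value - lo[snap_axis]) / pitch
        lo[snap_axis] += (frac - np.floor(frac) - 0.5) * pitch
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / pitch)) + 1 for a in range(3))
    return np.asarray(lo, dtype=float), shape


def _rasterize(mesh: trimesh.Trimesh, pitch: float, origin: np.ndarray,
               shape: tuple) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin lattice samples of the surface into voxels.

    Returns (flat voxel indices, representative sample point, representative
    outward normal) — one entry per touched voxel.
    """
    tri = mesh.triangles.view(np.ndarray)
    nrm = mesh.face_normals.view(np.ndarray)
    edge = np.linalg.norm(np.roll(tri, -1, axis=1) - tri, axis=2).max(axis=1)
    n_sub = np.maximum(np.ceil(edge / (0.5 * pitch)).astype(np.int64), 1)

    acc_idx: list[np.ndarray] = []
    acc_pts: list[np.ndarray] = []
    acc_nrm: list[np.ndarray] = []
    shape_arr = np.asarray(shape)
    for n in np.unique(n_sub):
        bary = _bary_lattice(int(n))
        sel = np.nonzero(n_sub == n)[0]
        block = max(int(_MAX_SAMPLE_BLOCK // max(len(bary), 1)), 1)
        for s in range(0, len(sel), block):
            ids = sel[s:s + block]
            pts = np.einsum("mk,tkd->tmd", bary, tri[ids]).reshape(-1, 3)
            ptn = np.repeat(nrm[ids], len(bary), axis=0)
            vox = np.round((pts - origin[None, :]) / pitch).astype(np.int64)
            np.clip(vox, 0, shape_arr - 1, out=vox)
            flat = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape)
            uniq, first = np.unique(flat, return_index=True)
            acc_idx.append(uniq)
            acc_pts.append(pts[first])
            acc_nrm.append(ptn[first])
    flat = np.concatenate(acc_idx)
    pts = np.concatenate(acc_pts)
    ptn = np.concatenate(acc_nrm)
    uniq, first = np.unique(flat, return_index=True)
    return uniq, pts[first], ptn[first]


def signed_field(mesh: trimesh.Trimesh, pitch: float, pad: int = 3,
                 grid: tuple[np.ndarray, tuple] | None = None,
                 snap_axis: int | None = None, snap_value: float = 0.0) -> SignedField:
    """Sample the signed distance to a mesh on a uniform grid (positive inside).

    Open meshes get no flooded interior; only the locally-inside half of
    their surface band counts as solid, which is what the offset operations
    need to close them.
    """
    if mesh.is_watertight and mesh.volume < 0:
        mesh = mesh.copy()
        mesh.invert()
    if grid is None:
        origin, shape = _grid_for(mesh.bounds.copy(), pitch, pad, snap_axis, snap_value)
    else:
        origin, shape = grid

    uniq, samples, normals = _rasterize(mesh, pitch, origin, shape)
    band = np.zeros(shape, dtype=bool)
    band.ravel()[uniq] = True

    # free space splits into components: border-connected ones are outside;
    # each enclosed component is material or a cavity depending on which side
    # of the nearest surface it sits (outward normal vote), so watertight
    # parts with internal voids — a carved cavity, say — classify correctly
    free = ~band
    labels, n = ndimage.label(free, structure=_FACE_STRUCT)
    interior = np.zeros(shape, dtype=bool)
    if n:
        border = np.zeros(shape, dtype=bool)
        border[0, :, :] = border[-1, :, :] = True
        border[:, 0, :] = border[:, -1, :] = True
        border[:, :, 0] = border[:, :, -1] = True
        outside_labels = set(np.unique(labels[border & free])) - {0}
        enclosed = [lab for lab in range(1, n + 1) if lab not in outside_labels]
        if enclosed:
            tree = cKDTree(samples)
            for lab in enclosed:
                vox = np.argwhere(labels == lab)
                probe = vox[:: max(len(vox) // 16, 1)][:16]
                pts = origin[None, :] + probe * pitch
                _, nearest = tree.query(pts, workers=-1)
                side = np.einsum("ij,ij->i", pts - samples[nearest], normals[nearest])
                if np.median(side) <= 0.0:  # behind the surface: material
                    interior[labels == lab] = True

    # classify band voxels by their nearest surface sample's outward normal
    centers = origin[None, :] + np.stack(np.unravel_index(uniq, shape), axis=1) * pitch
    inside_band = np.einsum("ij,ij->i", centers - samples, normals) <= 0.0
    solid = interior
    solid.ravel()[uniq[inside_band]] = True

    d_in = ndimage.distance_transform_edt(solid, sampling=pitch)
    d_out = ndimage.distance_transform_edt(~solid, sampling=pitch)
    # voxel centres sit on average half a pitch off the true surface
    phi = np.where(solid, d_in - 0.5 * pitch, -(d_out - 0.5 * pitch)).astype(np.float32)
    return SignedField(phi, pitch, origin, surface_points=samples)


def mesh_from_field(field: np.ndarray, pitch: float, origin: np.ndarray,
                    level: float = 0.0) -> trimesh.Trimesh:
    """Marching-cubes surface of a scalar field (solid where field > level)."""
    if not (field > level).any():
        raise GeometryError("field has no interior (solid collapsed?)")
    # a ~1e-3 pitch dither breaks the degenerate saddle configurations where
    # marching cubes would otherwise pinch the surface into non-manifold
    # edges; the geometric displacement is negligible
    rng = np.random.default_rng(0xC1707)
    field = field.astype(np.float32) + (
        (rng.random(field.shape, dtype=np.float32) - 0.5) * (1e-3 * pitch)
    )
    pad_value = float(min(field.min(), level) - pitch)
    padded = np.pad(field, 1, constant_values=pad_value)
    verts, faces, _, _ = measure.marching_cubes(padded, level=level)
    verts = (verts - 1.0) * pitch + np.asarray(origin)[None, :]
    # marching cubes emits an indexed, manifold surface already; re-welding
    # nearby vertices can pinch it, so keep it as-is
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if tm.is_watertight and tm.volume < 0:
        tm.invert()
    return tm


def pick_pitch(bounds: np.ndarray, rule_pitch: float, max_grid: int = 160) -> float:
    """The engine resolution: the requested pitch, floored so the grid stays tractable."""
    extent = float(np.max(np.asarray(bounds)[1] - np.asarray(bounds)[0]))
    return max(rule_pitch, extent / max_grid)
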
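"""Synthetic confocal phantoms with known ground truth.

Each phantom emulates a stained, adherent cultured cell as imaged by a
scanning confocal microscope: a flattened cell body whose f-actin signal is
cortical (a shell just under the surface, on the TRITC channel), an interior
nucleus (DAPI), and optionally fibre-like second cytoskeleton structures
(α-SMA on an AF647 channel) or stress fibres.  Channels are blurred by an
anisotropic Gaussian PSF (σz > σxy, as in confocal optics) and degraded by
detector noise.  The unblurred binary structure grids are returned alongside
the stack, so segmentation and morphometry can be validated against ground
truth.

Three presets mirror the archetypes this pipeline is built around:

* ``panc1_like`` — one compact epithelial cell, round body (in-plane Feret
  44.6 x 35.9 µm), roundish nucleus (18.8 x 13.7 µm), 16 z-planes over 15 µm.
* ``hdf_like`` — two contacting spindle-shaped fibroblasts (195.5 x 43.4 µm)
  with an extra α-SMA fibre channel, 33 z-planes over 16 µm, 512² at 0.5 µm.
* ``shsy5y_like`` — one small neuron-like cell, polygonal body
  (16.5 x 9.7 µm) with 3 protrusions, 36 z-planes over 10 µm at 0.1 µm/px.

Not emulated: photon-accurate shot statistics, spectral bleed-through,
stage drift, refractive-index aberrations.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .stack_io import ChannelSpec, VoxelStack

__all__ = [
    "CellSpec",
    "FiberSpec",
    "PhantomSpec",
    "generate_cell_phantom",
    "preset",
    "PRESET_NAMES",
]


@dataclasses.dataclass
class CellSpec:
    """One cell: body geometry, cortical shell, nucleus, protrusions.

    ``semi_axes`` are (a, b, c): in-plane long, in-plane short, axial — µm.
    ``body_shape`` is ``ellipsoid``, ``spindle`` (tapered superellipse
    profile, exponent 1.5) or ``polygon`` (convex polygon inscribed in the
    (a, b) ellipse with vertices pinned on both principal axes, so the
    projected Feret diameters equal 2a and 2b).
    """

    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float]  # (x, y, z) µm
    angle_deg: float = 0.0
    body_shape: str = "ellipsoid"
    shell_thickness_um: float = 1.2
    nucleus_semi_axes: tuple[float, float, float] | None = None
    nucleus_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    nucleus_bump_amplitude: float = 0.0  # fractional radial perturbation
    n_protrusions: int = 0
    protrusion_length_um: float = 3.5
    protrusion_radius_um: float = 0.7
    polygon_vertices: int = 8

    def __post_init__(self):
        a, b, c = self.semi_axes
        if self.shell_thickness_um >= min(a, b, c):
            raise PhantomSpecError(
                f"shell thickness {self.shell_thickness_um} must be below the "
                f"smallest cell semi-axis {min(a, b, c)}"
            )


@dataclasses.dataclass
class FiberSpec:
    """A curved-tube structure (stress fibre / α-SMA bundle)."""

    points: list[tuple[float, float, float]]  # polyline control points, µm
    radius_um: float = 1.2
    channel: str = "AF647"


@dataclasses.dataclass
class PhantomSpec:
    """Full description of a synthetic stack; fixed seed ⇒ bit-identical output."""

    shape: tuple[int, int, int]  # (z, y, x)
    voxel_size: tuple[float, float, float]  # (dz, dy, dx) µm
    cells: list[CellSpec]
    fibers: list[FiberSpec] = dataclasses.field(default_factory=list)
    psf_sigma_um: tuple[float, float, float] = (1.0, 0.3, 0.3)  # (z, y, x)
    noise: str = "none"  # none | gaussian | poisson
    noise_sigma: float = 4.0
    intensities: dict = dataclasses.field(default_factory=lambda: {
        "shell": 180, "nucleus": 200, "fiber": 160, "background": 0,
    })
    bit_depth: int = 8
    seed: int = 0


def _rotated_inplane(yy: np.ndarray, xx: np.ndarray, center, angle_deg: float):
    """In-plane coordinates (x', y') relative to centre, rotated by angle."""
    cx, cy = center[0], center[1]
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    xr = c * (xx - cx) + s * (yy - cy)
    yr = -s * (xx - cx) + c * (yy - cy)
    return xr, yr


def _body_plane_measure(cell: CellSpec, xr: np.ndarray, yr: np.ndarray) -> np.ndarray:
    """g(x, y): in-plane boundary measure; the body at height z is g <= s(z)²...

    Returns the squared-equivalent radial measure so that the 3D inside test
    is ``g + (z'/c)² <= 1`` for every body shape.
    """
    a, b, _ = cell.semi_axes
    if cell.body_shape == "ellipsoid":
        return (xr / a) ** 2 + (yr / b) ** 2
    if cell.body_shape == "spindle":
        p = 1.5  # sub-quadratic exponent: pointed (fusiform) ends
        return ((np.abs(xr) / a) ** p + (np.abs(yr) / b) ** p) ** (2.0 / p)
    if cell.body_shape == "polygon":
        # convex polygon inscribed in the (a, b) ellipse; vertices pinned at
        # all four principal-axis points so projected Feret = (2a, 2b)
        n = max(cell.polygon_vertices, 6)
        base = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        pinned = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        ang = np.sort(np.unique(np.concatenate([base + 0.12, pinned])))
        vx, vy = a * np.cos(ang), b * np.sin(ang)
        g = np.full(xr.shape, -np.inf)
        for i in range(len(ang)):
            x0, y0 = vx[i], vy[i]
            x1, y1 = vx[(i + 1) % len(ang)], vy[(i + 1) % len(ang)]
            # outward half-plane measure normalised to 1 on the edge
            nx_, ny_ = y1 - y0, x0 - x1
            d = nx_ * x0 + ny_ * y0
            g = np.maximum(g, (nx_ * xr + ny_ * yr) / d)
        return np.square(np.maximum(g, 0.0))
    raise PhantomSpecError(f"unknown body shape {cell.body_shape!r}")


def _coords(shape, voxel_size):
    nz, ny, nx = shape
    dz, dy, dx = voxel_size
    z = np.arange(nz) * dz
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx
    return z, y, x


def _cell_body_mask(cell: CellSpec, shape, voxel_size) -> np.ndarray:
    z, y, x = _coords(shape, voxel_size)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    xr, yr = _rotated_inplane(yy, xx, cell.center, cell.angle_deg)
    g = _body_plane_measure(cell, xr, yr)
    zr = (z - cell.center[2]) / cell.semi_axes[2]
    inside = g[None, :, :] + (zr ** 2)[:, None, None] <= 1.0
    return inside


def _nucleus_mask(cell: CellSpec, shape, voxel_size, rng) -> np.ndarray:
    if cell.nucleus_semi_axes is None:
        return np.zeros(shape, dtype=bool)
    a, b, c = cell.nucleus_semi_axes
    ox, oy, oz = cell.nucleus_offset
    th = math.radians(cell.angle_deg)
    # nucleus offset expressed in the cell's rotated frame
    cx = cell.center[0] + ox * math.cos(th) - oy * math.sin(th)
    cy = cell.center[1] + ox * math.sin(th) + oy * math.cos(th)
    cz = cell.center[2] + oz
    z, y, x = _coords(shape, voxel_size)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    xr, yr = _rotated_inplane(yy, xx, (cx, cy), cell.angle_deg)
    zr = z - cz
    v = ((xr / a) ** 2 + (yr / b) ** 2)[None, :, :] + ((zr / c) ** 2)[:, None, None]
    if cell.nucleus_bump_amplitude > 0:
        # low-order angular bumps: irregular (but smooth) nuclear outline
        phase = rng.uniform(0, 2 * np.pi, size=3)
        phi = np.arctan2(yr, xr)[None, :, :]
        psi = np.arctan2(zr[:, None, None], np.hypot(xr, yr)[None, :, :] + 1e-9)
        w = (np.sin(3 * phi + phase[0]) + 0.6 * np.sin(5 * phi + phase[1])
             + 0.5 * np.sin(2 * psi + phase[2])) / 2.1
        bound = (1.0 + cell.nucleus_bump_amplitude * w) ** 2
    else:
        bound = 1.0
    return v <= bound


def _protrusion_masks(cell: CellSpec, shape, voxel_size) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    if cell.n_protrusions <= 0:
        return out
    a, b, _ = cell.semi_axes
    z, y, x = _coords(shape, voxel_size)
    zz = z[:, None, None]
    yy = y[None, :, None]
    xx = x[None, None, :]
    angles = np.linspace(0, 2 * np.pi, cell.n_protrusions, endpoint=False) + 0.7
    th = math.radians(cell.angle_deg)
    for ang in angles:
        # start just inside the body boundary, run outward in-plane
        r0 = math.hypot(a * math.cos(ang), b * math.sin(ang))
        ang_w = ang + th
        ux, uy = math.cos(ang_w), math.sin(ang_w)
        sx = cell.center[0] + 0.85 * r0 * ux
        sy = cell.center[1] + 0.85 * r0 * uy
        sz = cell.center[2]
        length = cell.protrusion_length_um + 0.15 * r0
        # distance from each voxel to the protrusion axis segment
        px = xx - sx
        py = yy - sy
        pz = zz - sz
        t = np.clip((px * ux + py * uy) / length, 0.0, 1.0)
        dx_ = px - t * length * ux
        dy_ = py - t * length * uy
        radius = cell.protrusion_radius_um * (1.0 - 0.6 * t)
        out |= dx_ ** 2 + dy_ ** 2 + pz ** 2 <= radius ** 2
    return out


def _fiber_mask(fiber: FiberSpec, shape, voxel_size) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    pts = np.asarray(fiber.points, dtype=float)
    if len(pts) < 2:
        return out
    dz, dy, dx = voxel_size
    step = min(dz, dy, dx) * 0.5
    dense = []
    for p0, p1 in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(p1 - p0)
        n = max(int(np.ceil(seg / step)), 1)
        t = np.linspace(0, 1, n, endpoint=False)[:, None]
        dense.append(p0 + t * (p1 - p0))
    dense.append(pts[-1:])
    dense = np.concatenate(dense)
    r = fiber.radius_um
    nz, ny, nx = shape
    for px, py, pz in dense:
        iz0 = max(int((pz - r) / dz) - 1, 0); iz1 = min(int((pz + r) / dz) + 2, nz)
        iy0 = max(int((py - r) / dy) - 1, 0); iy1 = min(int((py + r) / dy) + 2, ny)
        ix0 = max(int((px - r) / dx) - 1, 0); ix1 = min(int((px + r) / dx) + 2, nx)
        if iz0 >= iz1 or iy0 >= iy1 or ix0 >= ix1:
            continue
        zi = (np.arange(iz0, iz1) * dz - pz)[:, None, None]
        yi = (np.arange(iy0, iy1) * dy - py)[None, :, None]
        xi = (np.arange(ix0, ix1) * dx - px)[None, None, :]
        out[iz0:iz1, iy0:iy1, ix0:ix1] |= zi**2 + yi**2 + xi**2 <= r**2
    return out


def generate_cell_phantom(spec: PhantomSpec) -> tuple[VoxelStack, dict[str, np.ndarray]]:
    """Render a phantom stack plus its ground-truth structure grids.

    Returns ``(stack, truth)`` where ``truth`` maps ``cell``, ``shell``,
    ``nucleus`` (and ``fibers`` when present) to binary ``(z, y, x)`` grids.
    Raises :class:`PhantomSpecError` if any nucleus pokes out of its cell.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    vs = spec.voxel_size

    cell_total = np.zeros(shape, dtype=bool)
    shell_total = np.zeros(shape, dtype=bool)
    nucleus_total = np.zeros(shape, dtype=bool)
    for cell in spec.cells:
        body = _cell_body_mask(cell, shape, vs)
        if not body.any():
            raise PhantomSpecError("a cell body lies outside the stack volume")
        nuc = _nucleus_mask(cell, shape, vs, rng)
        if (nuc & ~body).any():
            raise PhantomSpecError("nucleus not contained in its cell body")
        # cortical shell: body minus its interior eroded by the shell thickness
        depth = ndimage.distance_transform_edt(body, sampling=vs)
        shell = body & (depth <= cell.shell_thickness_um)
        prot = _protrusion_masks(cell, shape, vs)
        cell_total |= body | prot
        shell_total |= shell | prot
        nucleus_total |= nuc

    truth: dict[str, np.ndarray] = {
        "cell": cell_total, "shell": shell_total, "nucleus": nucleus_total,
    }
    fiber_by_channel: dict[str, np.ndarray] = {}
    if spec.fibers:
        fibers_total = np.zeros(shape, dtype=bool)
        for fiber in spec.fibers:
            m = _fiber_mask(fiber, shape, vs)
            fibers_total |= m
            acc = fiber_by_channel.setdefault(fiber.channel, np.zeros(shape, dtype=bool))
            acc |= m
        truth["fibers"] = fibers_total

    inten = spec.intensities
    background = float(inten.get("background", 0))
    channel_imgs: dict[str, np.ndarray] = {}
    channel_imgs["TRITC"] = np.where(
        shell_total | fiber_by_channel.get("TRITC", False),
        float(inten.get("shell", 180)), background,
    ).astype(np.float64)
    channel_imgs["DAPI"] = np.where(
        nucleus_total, float(inten.get("nucleus", 200)), background)
    if "AF647" in fiber_by_channel:
        channel_imgs["AF647"] = np.where(
            fiber_by_channel["AF647"], float(inten.get("fiber", 160)), background)

    maxval = 2 ** spec.bit_depth - 1
    sig_vox = tuple(s / v for s, v in zip(spec.psf_sigma_um, vs))
    out = []
    names = []
    for name, img in channel_imgs.items():
        if any(s > 0 for s in sig_vox):
            img = ndimage.gaussian_filter(img, sigma=sig_vox)
        if spec.noise == "gaussian":
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        elif spec.noise == "poisson":
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        elif spec.noise != "none":
            raise PhantomSpecError(f"unknown noise model {spec.noise!r}")
        out.append(np.clip(np.round(img), 0, maxval))
        names.append(name)

    dtype = np.uint16 if spec.bit_depth > 8 else np.uint8
    data = np.stack(out).astype(dtype)
    targets = {"TRITC": "f-actin", "DAPI": "nuclei", "AF647": "a-SMA"}
    channels = [ChannelSpec(n, stain=n, target=targets.get(n, "")) for n in names]
    stack = VoxelStack(data=data, voxel_size=vs, channels=channels,
                       bit_depth=spec.bit_depth)
    return stack, truth


PRESET_NAMES = ("panc1_like", "hdf_like", "shsy5y_like")


def preset(name: str, seed: int = 0) -> PhantomSpec:
    """A ready-made PhantomSpec for one of the three cell archetypes.

    Stack geometry follows the archetype's imaging session (slice count /
    section thickness) and the body/nucleus axes follow the archetype's
    morphometry: see the module docstring.
    """
    if name == "panc1_like":
        return PhantomSpec(
            shape=(16, 256, 256),
            voxel_size=(15.0 / 16, 0.25, 0.25),
            cells=[CellSpec(
                semi_axes=(22.3, 17.95, 5.5),
                center=(32.0, 32.0, 7.5),
                angle_deg=20.0,
                body_shape="ellipsoid",
                shell_thickness_um=1.2,
                nucleus_semi_axes=(9.4, 6.85, 3.5),
                nucleus_offset=(2.0, 1.0, 0.0),
            )],
            noise="gaussian",
            seed=seed,
        )
    if name == "hdf_like":
        cells = []
        fibers = []
        for cx, cy, ang in ((118.0, 108.0, 15.0), (138.0, 148.0, -12.0)):
            cells.append(CellSpec(
                semi_axes=(97.75, 21.7, 5.0),
                center=(cx, cy, 8.0),
                angle_deg=ang,
                body_shape="spindle",
                shell_thickness_um=1.5,
                nucleus_semi_axes=(22.05, 8.6, 3.2),
            ))
            th = math.radians(ang)
            ux, uy = math.cos(th), math.sin(th)
            for off in (-5.0, 0.0, 5.0):
                p0 = (cx - 70 * ux - off * uy, cy - 70 * uy + off * ux, 8.0)
                pm = (cx + off * -0.3 * uy, cy + off * 0.3 * ux, 8.0)
                p1 = (cx + 70 * ux - off * uy, cy + 70 * uy + off * ux, 8.0)
                fibers.append(FiberSpec([p0, pm, p1], radius_um=1.4, channel="AF647"))
        return PhantomSpec(
            shape=(33, 512, 512),
            voxel_size=(16.0 / 33, 0.5, 0.5),
            cells=cells,
            fibers=fibers,
            noise="gaussian",
            seed=seed,
        )
    if name == "shsy5y_like":
        return PhantomSpec(
            shape=(36, 256, 256),
            voxel_size=(10.0 / 36, 0.1, 0.1),
            cells=[CellSpec(
                semi_axes=(8.25, 4.85, 2.6),
                center=(12.8, 12.8, 5.0),
                angle_deg=15.0,
                body_shape="polygon",
                shell_thickness_um=0.8,
                nucleus_semi_axes=(3.2, 2.95, 1.7),
                n_protrusions=3,
                protrusion_length_um=3.5,
                protrusion_radius_um=0.7,
            )],
            noise="gaussian",
            seed=seed,
        )
    raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
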
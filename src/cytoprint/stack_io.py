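"""Reading and writing the pipeline's file formats.

Confocal z-stacks come in as multi-page TIFFs and are normalised to a
:class:`VoxelStack` with axis order ``(channel, z, y, x)`` and physical voxel
sizes in micrometres.  Meshes leave (and re-enter) as STL via trimesh.

Voxel-size precedence is strict: an explicit override beats TIFF metadata,
and if neither is present reading fails — a silently assumed voxel size would
corrupt every physical measurement downstream.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import trimesh

from .errors import ConfigurationError, FormatError

__all__ = [
    "ChannelSpec",
    "VoxelStack",
    "read_stack",
    "write_stack",
    "validate_scale",
    "read_stl",
    "write_stl",
]


@dataclasses.dataclass(frozen=True)
class ChannelSpec:
    """One fluorescence channel: a free-text name, the stain, and its target.

    Example: ``ChannelSpec("DAPI", stain="DAPI", target="nuclei")``.
    """

    name: str
    stain: str = ""
    target: str = ""


@dataclasses.dataclass
class VoxelStack:
    """Multi-channel 3D intensity grid with physical voxel sizes.

    ``data`` is ordered ``(channel, z, y, x)``; ``voxel_size`` is
    ``(dz, dy, dx)`` in µm.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channels: list[ChannelSpec]
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError(f"stack data must be 4D (c, z, y, x), got ndim={self.data.ndim}")
        if len(self.channels) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channels)} channel specs for {self.data.shape[0]} channel planes"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise FormatError(f"channel names not unique: {names}")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(f"voxel sizes must be positive, got {self.voxel_size}")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 2**self.bit_depth - 1):
            raise FormatError(
                f"intensities outside [0, {2**self.bit_depth - 1}] for bit depth {self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(z, y, x)``."""
        return self.data.shape[1:]

    def channel_index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.name == name:
                return i
        from .errors import ChannelLookupError

        raise ChannelLookupError(f"no channel named {name!r}; have {[c.name for c in self.channels]}")

    def channel(self, name: str) -> np.ndarray:
        """The ``(z, y, x)`` intensity grid of one named channel."""
        return self.data[self.channel_index(name)]

    def extent(self) -> tuple[float, float, float]:
        """Physical extent ``(z, y, x)`` in µm (count × voxel size)."""
        nz, ny, nx = self.shape
        dz, dy, dx = self.voxel_size
        return (nz * dz, ny * dy, nx * dx)


def _voxel_size_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Try to recover (dz, dy, dx) in µm from TIFF/ImageJ metadata."""
    page = tif.pages[0]
    dx = dy = dz = None
    tags = page.tags
    if "XResolution" in tags and "YResolution" in tags:
        xres = tags["XResolution"].value
        yres = tags["YResolution"].value
        xres = xres[0] / xres[1] if isinstance(xres, tuple) else float(xres)
        yres = yres[0] / yres[1] if isinstance(yres, tuple) else float(yres)
        unit_scale = 1.0  # assume pixels-per-µm unless the unit says otherwise
        unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else None
        if unit in (2, tifffile.RESUNIT.INCH):
            unit_scale = 1.0 / 25400.0  # per inch -> per µm
        elif unit in (3, tifffile.RESUNIT.CENTIMETER):
            unit_scale = 1.0 / 10000.0
        if xres > 0 and yres > 0:
            dx = 1.0 / (xres * unit_scale)
            dy = 1.0 / (yres * unit_scale)
    ij = tif.imagej_metadata or {}
    if "spacing" in ij:
        dz = float(ij["spacing"])
    if dx is None or dy is None or dz is None:
        return None
    return (dz, dy, dx)


def read_stack(
    path: str | Path,
    *,
    voxel_size: tuple[float, float, float] | None = None,
    channels: Sequence[ChannelSpec | str] | None = None,
    n_channels: int | None = None,
    layout: str = "cfirst",
    bit_depth: int | None = None,
) -> VoxelStack:
    """Read a multi-page TIFF z-stack into a canonical ``(c, z, y, x)`` grid.

    Parameters
    ----------
    voxel_size
        ``(dz, dy, dx)`` in µm.  Overrides TIFF metadata; if neither is
        available a :class:`ConfigurationError` is raised.
    channels
        Channel specs (or bare names) in channel order; defines the channel
        count if ``n_channels`` is not given.
    layout
        Page interleaving for plain 3D page streams: ``"cfirst"`` means the
        channel index varies fastest (c0z0, c1z0, ...), ``"zfirst"`` means
        the z index varies fastest.  Ignored when the TIFF declares its axes.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes  # e.g. 'YX', 'ZYX', 'ZCYX', 'CZYX'
        meta_vs = _voxel_size_from_tiff(tif)
        meta_channels = None
        ij = tif.imagej_metadata or {}
        if channels is None and "cyto_channels" in ij:
            try:
                meta_channels = [ChannelSpec(**c) for c in json.loads(ij["cyto_channels"])]
            except (ValueError, TypeError):
                meta_channels = None

    chans = list(channels) if channels is not None else meta_channels
    if chans is not None:
        chans = [c if isinstance(c, ChannelSpec) else ChannelSpec(str(c)) for c in chans]
    nc = n_channels or (len(chans) if chans else None)

    axes = axes.replace("S", "")  # no RGB samples expected
    if "C" in axes and arr.ndim >= 3:
        # the file declares its channel axis: trust it
        order = [axes.index(a) for a in "CZYX" if a in axes]
        arr = np.transpose(arr, order)
        if "Z" not in axes:
            arr = arr[:, None]
        data = arr
        if nc is not None and data.shape[0] != nc:
            raise FormatError(f"file has {data.shape[0]} channels, config says {nc}")
    else:
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise FormatError(f"unsupported TIFF dimensionality {arr.ndim}")
        nc = nc or 1
        npages = arr.shape[0]
        if npages % nc:
            raise FormatError(f"{npages} pages not divisible by {nc} channels")
        nz = npages // nc
        if layout == "cfirst":
            data = arr.reshape(nz, nc, *arr.shape[1:]).transpose(1, 0, 2, 3)
        elif layout == "zfirst":
            data = arr.reshape(nc, nz, *arr.shape[1:])
        else:
            raise ConfigurationError(f"unknown page layout {layout!r}")

    vs = voxel_size or meta_vs
    if vs is None:
        raise ConfigurationError(
            f"no voxel size: {path.name} carries no usable resolution metadata and no override was given"
        )

    nc = data.shape[0]
    if chans is not None and len(chans) != nc:
        if channels is not None:
            raise FormatError(f"{len(chans)} channel specs for {nc} channels in file")
        chans = None  # stale embedded metadata: fall back to generic names
    if chans is None:
        chans = [ChannelSpec(f"ch{i}") for i in range(nc)]
    if bit_depth is None:
        bit_depth = 16 if data.dtype.itemsize > 1 else 8
    return VoxelStack(data=np.ascontiguousarray(data), voxel_size=tuple(float(v) for v in vs),
                      channels=chans, bit_depth=bit_depth)


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write a stack as an ImageJ-flavoured multi-page TIFF (round-trips voxel size)."""
    path = Path(path)
    dz, dy, dx = stack.voxel_size
    data = stack.data
    if data.dtype not in (np.uint8, np.uint16):
        data = data.astype(np.uint16 if stack.bit_depth > 8 else np.uint8)
    # ImageJ layout wants TZCYXS ordering; we write (z, c, y, x)
    channel_info = json.dumps([
        {"name": c.name, "stain": c.stain, "target": c.target} for c in stack.channels
    ])
    tifffile.imwrite(
        str(path),
        np.ascontiguousarray(data.transpose(1, 0, 2, 3)),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZCYX",
                  "cyto_channels": channel_info},
    )
    return path


def validate_scale(
    stack: VoxelStack,
    expected_extent: tuple[float, float, float],
    tol: float = 0.01,
) -> dict:
    """Check stack physical extent (count × voxel size) against expected (z, y, x) µm.

    Returns a report dict; failures are carried in the report, not raised.
    """
    if any(e <= 0 for e in expected_extent):
        raise ConfigurationError("expected extents must be positive")
    computed = stack.extent()
    axes_report = {}
    ok = True
    for axis, comp, exp in zip("zyx", computed, expected_extent):
        err = abs(comp - exp) / exp
        axis_ok = err <= tol
        ok &= axis_ok
        axes_report[axis] = {
            "computed_um": float(comp),
            "expected_um": float(exp),
            "relative_error": float(err),
            "pass": bool(axis_ok),
        }
    return {"pass": bool(ok), "tol": float(tol), "axes": axes_report}


def write_stl(mesh, path: str | Path, mode: str = "binary") -> Path:
    """Write a mesh (SurfaceMesh/SolidPart or trimesh.Trimesh) as STL."""
    tm = getattr(mesh, "mesh", mesh)
    if len(tm.faces) == 0:
        raise ValueError("refusing to write an empty mesh")
    path = Path(path)
    if mode == "binary":
        path.write_bytes(tm.export(file_type="stl"))
    elif mode == "ascii":
        out = tm.export(file_type="stl_ascii")
        path.write_text(out if isinstance(out, str) else out.decode())
    else:
        raise ConfigurationError(f"unknown STL mode {mode!r}")
    return path


def read_stl(path: str | Path) -> trimesh.Trimesh:
    """Load an STL file as a processed trimesh (duplicate vertices merged)."""
    tm = trimesh.load(str(path), file_type="stl", process=True)
    if isinstance(tm, trimesh.Scene):
        tm = tm.to_mesh()
    return tm
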
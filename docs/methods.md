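# Methods

## Scope and model

`cytoprint` reconstructs printable solids from fluorescence z-stacks of
adherent cultured cells.  The object model is deliberately simple: a
**VoxelStack** is an intensity grid ordered `(channel, z, y, x)` with voxel
sizes `(dz, dy, dx)` in µm; a **Mask** is a binary grid registered to it;
a **SurfaceMesh** is a triangle mesh whose vertices live in physical
coordinates (µm until a ScaleMap is applied, mm afterwards; voxel centres at
`(i·dz, j·dy, k·dx)` from the first voxel centre, right-handed x-y-z); a
**SolidPart** is a watertight mesh with colour and wall metadata; an
**Assembly** is a set of named parts with split planes and
(host, insert, clearance) fit relations.

## Segmentation

Segmentation reproduces a manual thresholding session programmatically:
band thresholds (`gv_min ≤ I ≤ gv_max`), seeded region grow (the
26-connected component of the band containing the seed), connected-component
splitting (largest first), ROI cropping that zeroes rather than reshapes (so
masks stay registered to the stack), and gap closing.  Closing is 3D
morphological closing with a ball of radius 2 voxels followed by 3D hole
filling — the radius matches the PSF-scale holes fluorescent shells actually
have — or 2D per-slice hole filling for flat structures.  Interactive brush
edits are replaced by ROI set/clear lists applied in a fixed order
(reproducibility over interactivity).  Connectivity is 26-neighbour in 3D,
8-neighbour in 2D: thin diagonal actin fibres must not fall apart.
Grey-value thresholds are never hard-coded: structures without an explicit
band are thresholded at half the channel's observed maximum, which is the
right contour for solid blobs (nuclei recover with Dice ≥ 0.95 on the
phantoms).  Cortical shells are different: a rind thinner than the axial
PSF blurs to ~45% of its in-plane peak at the cell's top and bottom caps,
so a half-max band would cut the caps off and the body would never close.
The preset configurations therefore ship known-good shell bands (grey value
≥ 50 of 255; ≥ 40 for the neuron-like preset whose 0.8 µm shell is thinner
than the axial PSF), chosen from the PSF/shell geometry, after which
closing + hole filling recovers ≥ 99% of the true cell-body voxels.

## Meshing

Surfaces are marching cubes at iso-level 0.5 with the anisotropic voxel
spacing applied directly, optionally after Gaussian pre-smoothing of the
binary grid (σ = 0.7 voxel in the pipeline) to remove voxel staircase
before the mesh exists.  Smoothing is Taubin's shrink/inflate scheme
(λ = 0.5, ν = 0.53, 10 iterations): topology untouched, enclosed volume
preserved to well under 5%.  Simplification is voxel remeshing — re-extract
the surface from a signed-distance grid whose pitch is chosen (and
coarsened on retry) to meet the face budget — because it cannot break
watertightness; meshes at a minimal face count pass through unchanged.
A digitised r = 10 µm sphere at 0.5 µm voxels meshes to within 0.5% of
4/3·π·r³, and the error shrinks as voxels do.

## The signed-distance solid engine

Offsets, plane cuts and clearance Booleans all run on a discretised signed
distance field rather than exact mesh arithmetic, which is fragile on
marching-cubes output.  The engine:

* samples each triangle on a barycentric lattice at half-pitch spacing,
  binning samples into grid voxels (memory-bounded blocks);
* flood-fills free space from the grid border; surviving enclosed components
  are classified by the outward normal of their nearest surface sample, and
  the surface-band voxels by the sign of `(centre − sample)·normal` — a true
  voxel-centre inside test with no half-voxel inflation, which also makes
  internal cavities come out hollow;
* builds φ (> 0 inside) from two Euclidean distance transforms with a
  half-pitch centring correction, and refines iso-bands ≥ 2 pitches from the
  surface with exact KD-tree point distances (the EDT-to-voxel-centres
  distance is biased on curved surfaces);
* composes operations as min/max on φ — filled offset `φ + t`, shell
  `min(φ + t, −φ)`, subtraction with clearance `min(φ_host, −(φ_ins + c))`,
  plane halves `min(φ, ±d_plane)` — and re-extracts with marching cubes at
  level 0, where linear interpolation places surfaces with sub-voxel
  accuracy.  A ~10⁻³-pitch field dither removes the degenerate saddle
  configurations where marching cubes would pinch the mesh non-manifold.

Grid placement matters: the grid is phase-shifted half a pitch off the
bounding box (and snapped per-axis for axis-aligned split planes) so planar
faces land exactly midway between sample layers and are reconstructed
exactly.  Split halves are extracted from the same grid, so their cut faces
coincide and volumes sum to the whole within 1%.

**Resolution.**  The engine pitch follows `min(thickness, clearance)/4`
but is floored at `longest bounding-box extent / max_grid`
(`max_grid` = 160 by default, 192 for plane splits): distance transforms on
grids much beyond ~200³ dominate runtime without improving the fit
tolerances, which are reported in units of the realised pitch anyway
(`verify_fit` uses 2 × pitch).  Defaults: 1 mm offset thickness (the
empirical FDM wall-stability threshold) and 0.3 mm clearance (a typical FDM
slip fit); both are config inputs.

## Scaling and print reporting

Magnification is `M = model length (mm·10³) / original length (µm)` —
specified directly, or auto-fitted so the longest extent reaches a target
model size.  Coordinates scale by `M·10⁻³` (µm → mm); apply/invert
round-trips to 1e−9 relative.  The preset models use M = 1000, 200 and
10000 respectively (1 cm : 10 µm, 2 cm : 100 µm, 5 cm : 5 µm).  The print
report states the original-scale feature size one 0.2 mm layer represents,
`h·10³/M` µm, and estimates minimum wall thickness by casting rays inward
from ~100 sampled faces (own vectorised Möller–Trumbore; first positive hit
= local wall).  Near the knife-edge rim where a split plane meets a cavity
the true wall legitimately tends to zero; the report says so rather than
hiding it — the stability flag applies to solidified parts, whose walls are
bounded below by the offset thickness.  Build volume defaults to
330 × 240 × 300 mm.

## Morphometry

Adherent cells are flat, so diameters are measured in-plane on the
z-projection (logical OR) of each 26-connected component: D1 = maximum and
D2 = minimum caliper (Feret) diameter over the convex hull of the foreground
pixel *corners* (the pixel-as-square convention; at the 0.1–0.5 µm pixels
used here the half-pixel convention bias is far inside the 2% acceptance
band).  The minimum is computed by rotating calipers — the minimum width is
attained perpendicular to a hull edge; ties break to the lower edge index.
`Davg = (D1+D2)/2`; reports blank it for objects with D1/D2 > 3, where an
"average diameter" of a spindle is not a meaningful size.  Volume is voxel
count × voxel volume.

## Phantoms: what they emulate, and what they don't

Each phantom cell is a flattened body (ellipsoid; superellipse-profile
fusiform for the spindle-shaped fibroblast, exponent 1.5; or a convex
polygon inscribed in the D1/D2 ellipse with vertices pinned on both
principal axes for the neuron-like cell) whose cortical f-actin signal is
the rind within a shell thickness of the surface (EDT-based, so it is a
true metric rind under anisotropic voxels), an interior nuclear ellipsoid
with optional low-order angular bumps (amplitude 0 by default so recovery
tests are exact), optional tapered protrusions and curved-tube fibre
bundles.  Channels are blurred by an anisotropic Gaussian PSF
(σ = 1.0/0.3/0.3 µm z/y/x — confocal-like, σz > σxy) and degraded by
Gaussian (σ = 4 grey values) or Poisson noise.  Presets fix the stack
geometry to the three archetypes' imaging sessions — 16 planes / 15 µm at
0.25 µm px, 33 / 16 µm at 0.5 µm px (512², two cells, α-SMA channel),
36 / 10 µm at 0.1 µm px — and the body/nucleus axes to the archetype
morphometrics (e.g. epithelial body 44.6 × 35.9 µm, nuclei 18.8 × 13.7 µm).
A fixed seed makes output bit-identical.

Not emulated: photon-accurate shot statistics, spectral bleed-through,
refractive aberrations, stage drift, cell-to-cell biological variability.
Passing recovery tests therefore demonstrates that the measurement chain is
unbiased on known geometry at realistic sampling — not that segmentation
thresholds transfer to any particular microscope's data, which is why all
thresholds remain config inputs.

## Degenerate inputs and tie-breaks

Empty masks/meshes are rejected with typed errors; a split plane that
misses its part returns `(part, None)` with a `split_missed` flag; a
single-voxel mask meshes to its dual octahedron (volume = voxel volume/6 —
the honest level-0.5 iso-surface, not the voxel cube); open surfaces are
closed by the voxel offset in `solidify`; thresholds at the full grey range
produce the all-true mask.  Component ordering is by descending size with
stable ties; morphometry records are renumbered by descending volume.

## Problem sizes

Default runs are desk-scale by construction: phantom grids of 1–8.6 M
voxels, engine grids ≤ 160–192 per axis, ~100 wall-probe rays per part.
A full preset pipeline takes ~15–20 s and < 1.5 GB; the three-preset
acceptance run a few minutes.
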
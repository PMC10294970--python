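"""Segment a phantom stack and turn the masks into µm-scale surface meshes.

The nucleus is a solid blob, so its half-max contour is its boundary; the
cortical f-actin shell blurs much weaker at the cell's top/bottom caps, so
it gets the preset's lower grey-value band (>= 50) before gap closing.
Then: marching-cubes iso-surface with the anisotropic voxel spacing
applied, and volume-preserving smoothing.
"""

import cytoprint as cp

stack, truth = cp.generate_cell_phantom(cp.preset("panc1_like", seed=1))

for channel, label in (("TRITC", "cell body (f-actin)"), ("DAPI", "nucleus")):
    grid = stack.channel(channel)
    mask = cp.threshold_mask(stack, channel,
                             cp.ThresholdParams(50 if channel == "TRITC" else float(grid.max()) / 2, 255))
    mask = cp.fill_mask(mask, mode="volumetric", radius=2)
    surf = cp.extract_surface(mask, gaussian_sigma=0.7)
    surf = cp.smooth_mesh(surf, iterations=10)
    stats = cp.mesh_stats(surf)
    print(f"{label}: {stats['face_count']} faces, "
          f"area {stats['surface_area']:.0f} um^2, "
          f"volume {stats.get('volume', float('nan')):.0f} um^3, "
          f"watertight={stats['watertight']}")
    cp.write_stl(surf, f"surface_{channel}.stl")
# Volumes are in um^3 because no magnification has been applied yet; the
# watertight flag must be True for the solids stage to accept the surface.
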
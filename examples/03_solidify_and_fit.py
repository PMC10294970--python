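"""Scale a cell surface to printable millimetres and design the dismountable fit.

Applies the 1 cm : 10 µm magnification (M = 1000), offsets the surfaces into
watertight solids (≥ 1 mm walls print stably), carves the nucleus out of the
cell with a 0.3 mm clearance, splits the cell by a horizontal plane through
its centroid, and verifies the insert actually fits.
"""

import cytoprint as cp

stack, _ = cp.generate_cell_phantom(cp.preset("panc1_like", seed=1))
scale = cp.make_scale_map(10.0, 10.0)  # 1 cm printed : 10 um original
print(f"magnification M = {scale.magnification:.0f}")

parts = {}
for channel, name in (("TRITC", "cell"), ("DAPI", "nucleus")):
    grid = stack.channel(channel)
    gv_min = 50.0 if channel == "TRITC" else float(grid.max()) / 2  # shell band
    mask = cp.fill_mask(cp.threshold_mask(
        stack, channel, cp.ThresholdParams(gv_min, 255)))
    surf = cp.smooth_mesh(cp.extract_surface(mask, gaussian_sigma=0.7), 10)
    surf = cp.apply_scale(surf, scale)
    parts[name] = cp.solidify(surf, thickness=1.0, mode="filled", name=name)
    print(f"solidified {name}: {parts[name].volume:.0f} mm^3, "
          f"watertight={parts[name].is_watertight}")

# carve the nucleus cavity and prove the insert fits before cutting anything
host = cp.subtract_insert(parts["cell"], parts["nucleus"], clearance=0.3)
fit = cp.verify_fit(host, parts["nucleus"], 0.3)
print(f"fit check: intersection {fit['intersection_volume']:.2f} mm^3, "
      f"min gap {fit['min_gap']:.2f} mm, pass={fit['pass']}")

assembly, stl_paths = cp.build_assembly(
    parts,
    splits=[("cell", None)],  # horizontal plane through the volume centroid
    fits=[("cell", "nucleus", 0.3)],  # 0.3 mm clearance so the print fits
    out_dir="assembly_panc1", model_name="panc1")
print(f"emitted {len(stl_paths)} STL parts: {sorted(p.name for p in stl_paths)}")
# 3 parts = split upper + lower cell halves + the nucleus that nests inside.
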
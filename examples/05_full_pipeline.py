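"""Run the whole chain on the neuron-like preset: phantom → dismountable STL set.

One config drives everything: segmentation thresholds, meshing, the
5 cm : 5 µm magnification (M = 10000), 1 mm solidification, the nucleus fit
with 0.3 mm clearance, and the print report.
"""

import json

import cytoprint as cp

cfg = cp.preset_run_config("shsy5y_like", out_dir="run_shsy5y", seed=1)
result = cp.run_pipeline(cfg)

print(f"{len(result['stl_paths'])} STL parts:")
for path in result["stl_paths"]:
    print(f"  {path}")
report = result["print_report"]
print(f"magnification M = {report['magnification']:.0f}; one 0.2 mm layer "
      f"represents {report['print_resolution_um']} um at original scale")
for name, rep in report["parts"].items():
    print(f"  {name}: bbox {['%.0f' % b for b in rep['bounding_box_mm']]} mm, "
          f"min wall {rep['min_wall_mm']:.1f} mm, stable={rep['stable']}")
print("morphometry:")
print(result["morphometry"].to_string(index=False))
# 2 parts (cytoskeleton + nucleus) mirror the neuron model's dismountability.
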
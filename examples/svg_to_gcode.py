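"""Scratch an arbitrary vector drawing: fit the maze fixture into a 6-well.

Any SVG (paths, basic shapes) is flattened to polylines and scaled so its
bounding-box circumradius fills the well's safe region, guaranteeing
containment for any drawing shape.
"""

import numpy as np

import scratchkit as sk

plate = sk.load_preset("6well")
spec = sk.PatternSpec(mode="svg", svg_source=sk.fixture_svg("maze"),
                      svg_scale=100.0, scratch_cycles=1)
r_safe = sk.safe_radius(plate, spec.tip_offset)

drawing = sk.parse_and_flatten(spec.svg_source, spec.flatten_tol)
paths = sk.fit_to_well(drawing, spec.svg_scale, r_safe)
program = sk.emit_program(plate, ["A1"], paths, spec)
program.write("maze.gcode")

total = sum(p.length() for p in paths)
max_r = max(p.max_radius() for p in paths)
print(f"subpaths:            {len(paths)}")
print(f"total scratch path:  {total:.1f} mm")
print(f"max point radius:    {max_r:.3f} mm (safe radius {r_safe} mm)")
print(f"program length:      {len(program.lines)} lines")
# max radius <= safe radius: the drawing never approaches the well wall
# closer than the 2 mm tip offset.
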
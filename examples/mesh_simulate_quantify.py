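"""Full-well mesh: generate, simulate the swept footprint, quantify one line.

The mesh protocol places 18 parallel lines 1.6 mm apart across a 6-well
well; swept by the 1.2 mm (1000 uL) tip this leaves 0.4 mm cell bridges.
Here we simulate a three-line excerpt at coarse pixels to keep the run
fast, then measure one simulated scratch.
"""

import numpy as np

import scratchkit as sk

plate = sk.load_preset("6well")
spec = sk.PatternSpec(mode="mesh", line_number=3, line_distance=1.6)
r_safe = sk.safe_radius(plate, spec.tip_offset)
paths = sk.generate_paths(spec, r_safe)

tip = sk.TIP_PRESETS["1000"]
mask = sk.swept_mask_from_polylines(paths, tip, pixel_size=20.0,
                                    well_diameter=plate.well_diameter)
print(f"safe radius:       {r_safe:.1f} mm")
print(f"wound area:        {mask.wound_area_mm2:.2f} mm^2 (3 chords x 1.2 mm tip)")

# measure the central line alone
single = sk.swept_mask_from_polylines(paths[1:2], tip, pixel_size=20.0,
                                      well_diameter=plate.well_diameter)
m = sk.wound_metrics(single, axis="x", end_cap_mm=tip.contact_width / 2)
print(f"mean wound width:  {m.mean_width:.0f} um (tip contact width 1200 um)")
print(f"width SD:          {m.sd_width:.1f} um (0 = perfectly straight)")

# bridge between adjacent scratches: line spacing minus tip width
mid = mask.grid[:, mask.grid.shape[1] // 2]
ys = mask.y_coords()
bridge = (~mid) & (np.abs(ys) < 1.6 / 2)
print(f"cell bridge width: {bridge.sum() * mask.pixel_mm * 1000:.0f} um "
      f"(1.6 mm spacing - 1.2 mm tip = 400 um)")
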
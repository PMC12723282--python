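# 96-well culture plate (SLAS footprint, 9 mm pitch).
name = 96well
rows = 8
cols = 12
well_diameter_mm = 6.35
pitch_x_mm = 9.0
pitch_y_mm = 9.0
a1_center_x_mm = 54.38
a1_center_y_mm = 41.24
scratch_z_mm = 1.2
travel_z_mm = 6.2
swap_xy = false
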
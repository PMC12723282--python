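# 24-well culture plate (SLAS footprint, standard 19.3 mm pitch).
name = 24well
rows = 4
cols = 6
well_diameter_mm = 15.6
pitch_x_mm = 19.3
pitch_y_mm = 19.3
a1_center_x_mm = 55.63
a1_center_y_mm = 43.79
scratch_z_mm = 1.2
travel_z_mm = 6.2
swap_xy = false
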
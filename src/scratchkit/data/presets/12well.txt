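# 12-well culture plate (SLAS footprint, standard pitch).
# travel_z_mm omitted on purpose: it defaults to scratch_z_mm + 5.
name = 12well
rows = 3
cols = 4
well_diameter_mm = 22.1
pitch_x_mm = 26.01
pitch_y_mm = 26.01
a1_center_x_mm = 64.87
a1_center_y_mm = 46.73
scratch_z_mm = 1.2
swap_xy = false
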
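# 6-well culture plate (SLAS footprint 127.76 x 85.48 mm, standard pitch).
# a1_center values assume the plate footprint corner clamped at machine (40, 30);
# replace them with your bench calibration.
name = 6well
rows = 2
cols = 3
well_diameter_mm = 34.6
pitch_x_mm = 39.12
pitch_y_mm = 39.12
a1_center_x_mm = 64.76
a1_center_y_mm = 53.18
scratch_z_mm = 1.2
travel_z_mm = 6.2
swap_xy = false
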
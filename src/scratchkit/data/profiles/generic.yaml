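# Generic Marlin-flavoured printer profile with an ethanol wash station
# parked off the plate footprint (machine mm).
name: generic-wash
homing_command: G28
leveling_command: G29
supports_autolevel: true
max_feed: 12000
wash_station:
  x: 10.0
  y: 150.0
  z: 2.0
  dwell_s: 30
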
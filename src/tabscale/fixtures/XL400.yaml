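# KORSCH XL400 production-scale rotary press, 29 dies and punch pairs.
# Vendor geometry is not published; placeholders are calibrated so that the
# theoretical dwell time at 60 min^-1 turret frequency is 12.5 ms
# (head flat 16.1 mm / (pi * 0.410 m * 1 s^-1)).
kind: rotary_press
press:
  name: XL400
  pitch_circle_diameter: 0.410   # m
  n_dies: 29
  roller_diameter: 0.300         # m
  head_flat_length: 0.0161       # m, euro D head flat
  head_radius: 0.040             # m
  fill_angle: 100.0              # deg
  die_spacing_angle: 12.413793103448276  # deg, 360/29
feeder:
  paddle_diameter: 0.20          # m
  n_spokes: 4
  clearance: 0.0025              # m
  holdup_mass: 1.5               # kg
  feed_volume: 4.0e-3            # m^3
  bulk_density: 500.0            # kg/m^3
provenance:
  n_dies: from machine configuration (29 dies)
  die_spacing_angle: derived, 360 deg / 29
  pitch_circle_diameter: placeholder, calibrated to 12.5 ms dwell at 60 min^-1
  roller_diameter: placeholder
  head_flat_length: placeholder, shared euro-D tooling across fixtures
  head_radius: placeholder
  fill_angle: placeholder
  paddle_diameter: placeholder
  n_spokes: placeholder
  clearance: placeholder
  holdup_mass: placeholder
  feed_volume: placeholder
  bulk_density: placeholder
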
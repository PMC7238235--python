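# KORSCH XL100 pilot-scale rotary press, tooled with 4 euro-D punch pairs.
# Feed-frame and turret dimensions are NOT published by the vendor; all values
# marked "placeholder" below are editable stand-ins calibrated so that
# (i) the XL100 -> StylOne paddle-frequency scaling factor reproduces the
#     known matched operating pair 60 -> 128 min^-1, and
# (ii) dwell times fall in the 10-130 ms range covered by 20-70 min^-1 runs.
kind: rotary_press
press:
  name: XL100
  pitch_circle_diameter: 0.240   # m
  n_dies: 4
  roller_diameter: 0.200         # m
  head_flat_length: 0.0161       # m, euro D head flat
  head_radius: 0.040             # m
  fill_angle: 100.0              # deg
  die_spacing_angle: 90.0        # deg, 360/4 installed dies
feeder:
  paddle_diameter: 0.18          # m
  n_spokes: 4
  clearance: 0.0025              # m
  holdup_mass: 0.85              # kg
  feed_volume: 2.5e-3            # m^3
  bulk_density: 500.0            # kg/m^3
provenance:
  n_dies: from machine configuration (4 installed punch pairs)
  die_spacing_angle: derived, 360 deg / installed dies
  pitch_circle_diameter: placeholder
  roller_diameter: placeholder
  head_flat_length: placeholder, shared euro-D tooling across fixtures
  head_radius: placeholder
  fill_angle: placeholder, calibrated jointly with StylOne feeder
  paddle_diameter: placeholder
  n_spokes: placeholder
  clearance: placeholder
  holdup_mass: placeholder, calibrated jointly with StylOne feeder
  feed_volume: placeholder
  bulk_density: placeholder
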
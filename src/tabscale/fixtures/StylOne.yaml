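# Styl'One evolution compaction simulator: a single compression station with
# a travelling paddle feed frame. The press block is nominal (one station, no
# turret); shear-number computations for the CS take turret/die/fill geometry
# from the *simulated* rotary press, and only the feeder block below from this
# fixture. Feeder placeholders are calibrated jointly with the XL100 fixture
# so the shear-matched paddle-frequency pair 60 -> 128 min^-1 is reproduced.
kind: compaction_simulator
press:
  name: StylOne
  pitch_circle_diameter: 0.250   # m, nominal (no turret)
  n_dies: 1
  roller_diameter: 0.250         # m, nominal
  head_flat_length: 0.0161       # m, euro D head flat
  head_radius: 0.040             # m
  fill_angle: 360.0              # deg, nominal (stationary die)
  die_spacing_angle: 360.0       # deg, nominal (single station)
feeder:
  paddle_diameter: 0.10          # m
  n_spokes: 12
  clearance: 0.0004              # m
  holdup_mass: 0.40              # kg
  feed_volume: 1.0e-3            # m^3
  bulk_density: 500.0            # kg/m^3
provenance:
  n_dies: from machine layout (single station)
  press block: nominal, unused by the CS-adapted shear number
  paddle_diameter: placeholder
  n_spokes: placeholder
  clearance: placeholder, calibrated jointly with XL100 feeder
  holdup_mass: placeholder, calibrated jointly with XL100 feeder
  feed_volume: placeholder
  bulk_density: placeholder
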
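# Synthetic material-response presets: relative tensile strength as a
# log-logistic function of the feed-frame shear number,
#   sigma(SN) = sigma_floor + (sigma_ref - sigma_floor) / (1 + (SN/sn50)^hill),
# evaluated at the reference compaction stress of 150 MPa.
#
# The presets are jointly calibrated against the packaged XL100/StylOne
# fixtures (shear numbers computed through shear_scaling) so that at the
# standard operating anchors:
#   - the ductile preset loses ~70% normalized tensile strength between
#     paddle frequencies 10 and 272 min^-1 (14 mm punches, plateau runtime),
#   - the intermediate preset loses ~30% under the same conditions,
#   - the brittle preset is flat (shear-insensitive),
#   - the ductile CS/rotary equilibrium ratio at the convenient-filling
#     operating point (9 mm punches, paddle 20 vs 272 min^-1) is ~35%.
# Functional form and parameter values are modeling choices of this package,
# not measured constants.
MCC_MgSt:
  deformation_class: ductile
  sigma_ref: 3.0          # MPa, unsheared tensile strength at 150 MPa
  sigma_floor: 0.54       # MPa, fully overlubricated floor (0.18 * sigma_ref)
  sn50: 3.31e+8           # shear number at the response midpoint
  hill: 0.82              # decay steepness per log10 decade of SN
  tabletability_slope: 1.0
  dwell_sensitivity: 0.0
Lactose_MgSt:
  deformation_class: intermediate
  sigma_ref: 1.5
  sigma_floor: 0.9675     # 0.645 * sigma_ref
  sn50: 3.31e+8
  hill: 0.82
  tabletability_slope: 1.0
  dwell_sensitivity: 0.0
DCP_MgSt:
  deformation_class: brittle
  sigma_ref: 1.0
  sigma_floor: 1.0        # flat: fracture exposes lubricant-free surfaces
  sn50: 3.31e+8
  hill: 0.82
  tabletability_slope: 1.0
  dwell_sensitivity: 0.0
Starch:
  deformation_class: viscoplastic
  sigma_ref: 2.0
  sigma_floor: 2.0        # shear-insensitive, but dwell-time sensitive
  sn50: 3.31e+8
  hill: 0.82
  tabletability_slope: 1.0
  dwell_sensitivity: 0.08 # fractional strength gain per log(t_dwell/40 ms)
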
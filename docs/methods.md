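# Methods

## Kinematic model

A rotary-press compaction event is modelled as a rigid punch head (flat
length `l_f`, head radius `r_h`) passing under a compression roller of
radius `R` at the constant horizontal pitch-circle velocity
`v = pi * D_pc * n_t / 60`. The vertical engagement is purely geometric:

    z(x) = (R + r_h) - sqrt((R + r_h)^2 - (|x| - l_f/2)^2)   for |x| > l_f/2
    z(x) = 0                                                 for |x| <= l_f/2

capped at the requested penetration depth. Assumptions: symmetric upper and
lower punch motion (each contributes half the engagement), a single
main-compression event (no pre-compression rollers, no ejection cam), rigid
tooling (no punch or frame deflection). Profiles are sampled on a uniform
grid with an odd sample count centred on the dwell midpoint, so simulated
profiles are exactly symmetric and the separation maximum equals the
penetration depth bit-exactly. The default sampling step of 0.1 ms resolves
the shortest dwell of practical interest (~12.5 ms at production speed) with
more than 100 samples.

Displacement-to-stress synthesis is deliberately separated from the
kinematics: `StressMaterialLaw` maps compression depth to axial stress with
a power law `sigma = sigma_full * (c / p)^k` (default exponent 2), without
hysteresis or rate dependence. It exists to shape realistic stress pulses
for the profile diagnostics, not to model in-die compressibility.

## CS execution deviations

`CsDeviationModel` imposes three departures of the compaction simulator from
the ideal rotary profile, each with a documented default:

| parameter | default | unit | role |
|---|---|---|---|
| `prolongation_coeff_stress` | 6.2e-4 | 1/MPa | time-stretch slope with peak stress |
| `prolongation_coeff_speed` | -4.0e-4 | 1/min^-1 | time-stretch slope with turret speed |
| `residual_velocity_coeff` (kappa) | 25 | mm*ms/s | dwell approach `v = -kappa / t_dwell` |
| `noise_sd_per_speed` | 0 | mm/min^-1 | additive separation noise |

The bilinear stretch `s = 1 + a*sigma + b*n_t` is validated to stay `>= 1`
over the supported operating grid (50–300 MPa, 20–70 min^-1); its corner
values give prolongations from ~0.6% (50 MPa, 60 min^-1) up to ~17.8%
(300 MPa, 20 min^-1), i.e. "up to 20%", largest at high stress and low
speed. The residual-velocity law encodes a fixed total dwell approach of
`kappa/1000` mm per event (25 um at default), so the residual speed rises
as the dwell shrinks: −0.39 mm/s at a 64 ms dwell, −2.0 mm/s at 12.5 ms.
The machine-control inertia this mimics also explains why the stress keeps
rising through the dwell phase on the CS: the generator reproduces that
signature once the power-law stress is recomputed from the perturbed
separation and rescaled to hold the target peak stress (the pair generator
keeps peaks equal to well within 0.5%).

What the generator does **not** capture: stress relaxation of the material
during dwell (real rotary profiles show slightly *falling* stress at low
stress levels; the synthetic rotary dwell stress is flat), loading/unloading
hysteresis, elastic recovery, pre-compression, and frequency content of real
machine vibration (noise is white).

## Profile diagnostics

The dwell window is the maximal contiguous interval with separation within a
tolerance of its minimum (default 10 um, on the order of position-sensor
resolution). Because the head flat meets the flank tangentially, the
detected window grows with `sqrt(tolerance)`; oracle tests that compare
against the closed form use a 1e-12 mm tolerance where the plateau is exact.
The residual dwell velocity is the unweighted least-squares slope of
separation over the window (reported in mm/s, negative when approaching),
with its standard error for confidence statements. Compression time is the
total time with stress at or above a fraction of peak (default 10%), with
linearly interpolated threshold crossings so an ideal triangular pulse
yields its exact width; prolongation is the ratio of CS to rotary
compression times minus one. The 10% threshold is a definition choice —
the underlying observation ("slightly prolonged") does not fix the metric —
and is exposed as a parameter throughout. Optional moving-average
pre-smoothing is available for noisy high-speed profiles but off by
default, since the slope fit is itself a linear regression.

## Shear numbers and the matching rule

The rotary shear number and its CS adaptation are implemented exactly as
factorised in `shear_scaling` (shear intensity x squared residence x
squared frequency ratio, times the CS correction
`(phi_fill^2 / (360 deg * phi_dies))^2` of the simulated press). All inputs
are SI plus frequencies in min^-1; the index is dimensionless and its
absolute magnitude (here ~1e6–1e9 for realistic settings) depends on that
convention. Matching solves `SN_C = SN` in closed form; tablet weight and
die count are divided out algebraically so the result is exactly
punch-size-invariant. The matched frequency is rounded to a 4 min^-1
machine step by default — an inference from the granularity of known
matched setpoint pairs (60→128, 24→52), exposed as a parameter. For the
angle convention on an under-tooled turret, `phi_dies` is defined as
360°/k_d of the *installed* punch set, consistent with using the installed
die count in the residence term.

## Fixtures and calibration

Vendors do not publish feed-frame geometry, fill angles or turret
dimensions, so the packaged XL100/XL400/StylOne fixtures carry placeholder
values (flagged per-field in their `provenance` blocks) chosen once to
satisfy the known operating anchors: the XL400's theoretical dwell of
12.5 ms at 60 min^-1, and an XL100→StylOne paddle-frequency scaling factor
of 2.1332 so that 60 min^-1 maps to 128 and 24 min^-1 to 51.2 → 52. Every
fixture file is editable; users with real machine drawings should replace
the placeholders.

## Material shear response

Equilibrium tensile strength decays log-logistically with shear number,
`sigma(SN) = sigma_floor + (sigma_ref - sigma_floor) / (1 + (SN/SN_50)^h)`
— the minimal monotone sigmoid on a log axis, chosen because the observed
behaviour is a steep loss between SN ~1e6 and ~1e9 with saturation on both
sides. Runtime behaviour is an exponential relaxation from the pre-blended
strength toward equilibrium with the ideal filling time
`t_f = V_R * rho_b / mdot` as the time constant, since the plateau is
reached on the feeder-turnover timescale; the exact kinetics are a modelling
choice. Presets: ductile (MCC-like, floor fraction 0.18), intermediate
(lactose-like, 0.645), brittle (DCP-like, flat — fracture keeps exposing
lubricant-free surface), viscoplastic (starch-like, flat in SN but scaled
by `1 + 0.08 * ln(t_dwell / 40 ms)`). Midpoint `SN_50 = 3.31e8` and
steepness `h = 0.82` per decade are calibrated jointly with the fixtures so
that the ductile preset loses ~70% and the intermediate ~30% of normalized
strength between paddle frequencies 10 and 272 min^-1 (14 mm punches,
plateau runtime), and the ductile CS/rotary ratio at the convenient-filling
point (9 mm punches, paddle 20 vs 272 min^-1) is ~35%. Tablet sampling uses
unit-mean multiplicative log-normal noise on strength (positivity), default
CV 5%, mapped to breaking forces via the diametral-compression relation;
tablet thickness follows from weight at an apparent density of 1.4 g/cm^3.

Passing tests on this generator demonstrate that the analysis pipeline
recovers the phenomenology it encodes; they do not validate the functional
forms against new experimental data.

## Problem sizes and determinism

The acceptance computation uses the 9-point operating grid (3 stresses x 3
speeds) for prolongation and 50 tablets per condition at a runtime of six
filling times (residual start-value contribution e^-6 ≈ 0.25%) for the
shear-sensitivity quantities; at a 5% CV the standard error of a 50-tablet
mean is ~0.7%, small against the ±5-percentage-point bands of interest.
All random draws go through seeded `numpy` generators; repeated runs with
one seed are bit-identical.

## Known limitations

- Shear-number matching transfers the *index*, not the physics: effects the
  index underestimates (residence-time influence for small punches,
  dosing-out shear of surplus powder, fill-level variation with flow
  properties) are out of scope and will appear as residual mismatch.
- Porosity is computed out-of-die from envelope dimensions; in-die porosity
  and pore-size distributions are not modelled.
- The kinematics ignore pre-compression and ejection; profiles cover main
  compression only.
- Fixture geometry is placeholder-calibrated, not vendor data; absolute
  shear-number magnitudes inherit that uncertainty even though ratios and
  matched frequencies are anchored.
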
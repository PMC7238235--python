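# tabscale

Tools for scaling tableting processes between **rotary tablet presses** and a
**compaction simulator (CS)** — for formulation and process engineers who
develop tablets at lab scale and need the results to transfer to pilot and
production presses (and back).

A CS replays the punch-displacement profile of a target rotary press on a
single station, but two sub-processes do not transfer for free:

1. **The compaction profile itself.** The CS's execution is slightly
   prolonged (more at high stress, less at high speed) and its punches keep
   approaching during the dwell phase, which matters for visco-plastic
   materials such as starch.
2. **Powder shearing in the feed frame.** Lubricated blends (e.g. with
   magnesium stearate) lose tensile strength with cumulative shear. The CS's
   paddle feeder, run at "convenient filling" settings, shears the powder
   roughly two orders of magnitude more than the rotary press it simulates —
   enough to halve or worse the tensile strength of ductile excipients.

## The model

Punch kinematics follow from machine geometry: with pitch-circle diameter
$D_{pc}$ and turret frequency $n_t$, the head travels at
$v = \pi D_{pc} n_t / 60$ and the dwell time is $t_d = l_f / v$ for a punch
head flat of length $l_f$. Off the flat, the engagement under a roller of
radius $R$ is $z(x) = (R + r_h) - \sqrt{(R + r_h)^2 - (|x| - l_f/2)^2}$.

Feed-frame shear exposure is indexed by the shear number

$$\mathrm{SN} = \frac{\pi d_p k_s}{c}\left(\frac{m}{w\,k_d}\right)^2\left(\frac{n_p}{n_t}\right)^2$$

(paddle diameter $d_p$, spokes $k_s$, clearance $c$, hold-up $m$, tablet
weight $w$, dies $k_d$, paddle/turret frequencies $n_p$/$n_t$). Because the
CS's paddle only runs while the feeder sits over its single die, the
effective paddle frequency is corrected by
$\varphi_{fill}^2 / (360°\,\varphi_{dies})$ of the *simulated* press:

$$\mathrm{SN}_C = \frac{\pi d_p k_s}{c}\left(\frac{m}{w\,k_d}\right)^2\left(\frac{n_p}{n_t}\cdot\frac{\varphi_{fill}^2}{360°\,\varphi_{dies}}\right)^2$$

Setting $\mathrm{SN}_C = \mathrm{SN}$ gives a closed form for the CS paddle
frequency that reproduces the rotary press's shear history — the practical
scaling rule (`match_paddle_frequency`). Tablet quality is evaluated through
the diametral-compression tensile strength $\sigma_t = 2F/(\pi h_t d_t)$,
out-of-die porosity, and stress-normalized strength; the ideal filling time
$t_f = V_R \rho_b / \dot m$ estimates the feeder residence-time scale.

Because no machine-level datasets are deposited, a first-class synthetic
generator (`tabscale.synthetic_data`) emulates the CS's profile deviations
and the shear response of ductile / intermediate / brittle / viscoplastic
materials; see `docs/methods.md` for what it does and does not capture.

## Worked example

Shear number of the pilot press (XL100 fixture, 4 dies, 300 mg tablets,
paddle and turret both at 20 min⁻¹):

```
$ tabscale shear-number --fixture XL100 --np 20 --nt 20 --tablet-mg 300
{
  "correction_factor": 1.0,
  "frequency_term": 1.0,
  "mode": "rotary",
  "residence_term": 501736.1111111112,
  "shear_intensity_term": 904.7786842338604,
  "value": 453960138.44372517
}
```

The value 4.54×10⁸ is the product of the shear-intensity term
(π·d_p·k_s/c ≈ 905), the squared residence term ((m/(w·k_d))² ≈ 5.0×10⁵) and
the frequency term ((n_p/n_t)² = 1) — inside the 10⁶–10⁹ window where
ductile lubricated blends lose strength steeply.

Which CS paddle frequency reproduces the XL100's shear history when its
paddle runs at 60 min⁻¹?

```
$ tabscale match-paddle --press XL100 --cs StylOne --np 60 --nt 20 --tablet-mg 725
{
  "paddle_frequency_cs": 128.0,
  "paddle_frequency_cs_unrounded": 127.99435362546272,
  "rounding_step": 4.0,
  "target_shear_number": 699562829.2783208
}
```

The matched setpoint of 128 min⁻¹ (from the unrounded closed form 127.99,
rounded to the 4 min⁻¹ machine step) equalizes the CS-adapted shear number
with the rotary target of 7.0×10⁸. The result is independent of tablet
weight — w cancels in the match — so 300 mg and 725 mg tooling share one
setpoint.

Other subcommands: `simulate-profile`, `analyze-profile` (dwell time,
residual dwell velocity, compression time), `compare-profiles`
(prolongation), `tabletability`, and `synth profiles` / `synth batch` for
synthetic study data.

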
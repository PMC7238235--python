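"""Punch kinematics of rotary presses and their execution on a compaction simulator.

On a rotary press the punch head travels on the turret pitch circle under a
compression roller of radius ``R``.  With the punch-head flat of length
``l_f`` and head curvature radius ``r_h``, the vertical engagement at
horizontal head-centre coordinate ``x`` (relative to the roller axis) is

    z(x) = (R + r_h) - sqrt((R + r_h)^2 - (|x| - l_f/2)^2)   for |x| > l_f/2
    z(x) = 0                                                 for |x| <= l_f/2

capped at the penetration depth.  While the flat passes under the lowest
point of the roller (``|x| <= l_f/2``) the punch separation is constant: the
dwell phase, of duration l_f / v with v the horizontal pitch-circle velocity.

A compaction simulator (CS) replays such a displacement profile on a single
stationary station.  Its execution deviates systematically from the ideal
rotary profile: the event is slightly prolonged (more so at high stress, less
at high speed), and a small residual punch approach persists through the
dwell phase, growing as the dwell time shrinks.  :func:`apply_cs_execution`
imposes these deviations, parameterised by a
:class:`~tabscale.synthetic_data.CsDeviationModel`.

Pre-compression rollers and ejection are not modelled; one profile covers a
single main-compression event with symmetric upper/lower punch motion.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING

import numpy as np

from .machine_config import PressGeometry
from .profiles import CompactionProfile, ProfileError

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .synthetic_data import CsDeviationModel

__all__ = [
    "horizontal_velocity",
    "dwell_time",
    "simulate_displacement",
    "apply_cs_execution",
    "CompactionProfile",
]

#: Default sampling step (ms); resolves the shortest relevant dwell (~12.5 ms)
#: with more than 100 samples.
DEFAULT_SAMPLING_STEP_MS = 0.1

#: Default minimum punch separation (tablet thickness at peak compression), mm.
DEFAULT_MIN_SEPARATION_MM = 2.0


def horizontal_velocity(press: PressGeometry, turret_frequency: float) -> float:
    """Horizontal punch-head velocity on the pitch circle, m/s.

    v = pi * D_pc * n_t / 60 for n_t in min^-1.
    """
    if turret_frequency <= 0:
        raise ValueError("turret frequency must be positive")
    return math.pi * press.pitch_circle_diameter * turret_frequency / 60.0


def dwell_time(press: PressGeometry, turret_frequency: float) -> float:
    """Theoretical dwell time l_f / v in ms; strictly decreasing in n_t."""
    return press.head_flat_length / horizontal_velocity(press, turret_frequency) * 1000.0


def _contact_halfwidth(press: PressGeometry, penetration_m: float) -> float:
    """Horizontal half-width (m) over which the punch head engages the roller."""
    reach = press.roller_diameter / 2.0 + press.head_radius
    if penetration_m > reach:
        raise ValueError(
            f"penetration depth {penetration_m * 1000:.2f} mm exceeds the roller-contact "
            f"limit {reach * 1000:.2f} mm"
        )
    return press.head_flat_length / 2.0 + math.sqrt(reach**2 - (reach - penetration_m) ** 2)


def simulate_displacement(
    press: PressGeometry,
    turret_frequency: float,
    penetration_depth: float,
    sampling_step: float = DEFAULT_SAMPLING_STEP_MS,
    min_separation: float = DEFAULT_MIN_SEPARATION_MM,
) -> CompactionProfile:
    """Ideal rotary-press displacement profile from geometric machine data.

    Parameters
    ----------
    turret_frequency : float
        Turret rotation frequency n_t in min^-1.
    penetration_depth : float
        Maximum punch engagement in mm (upper plus lower, symmetric split);
        must be geometrically reachable for the roller/head pairing.
    sampling_step : float
        Uniform sampling step in ms.
    min_separation : float
        Punch separation at full engagement (mm); sets the separation offset
        but not the shape.

    The returned profile is exactly symmetric about its midpoint and its
    separation plateau recovers the closed-form dwell time to within one
    sampling step.
    """
    if penetration_depth <= 0:
        raise ValueError("penetration depth must be positive")
    if sampling_step <= 0:
        raise ValueError("sampling step must be positive")
    v = horizontal_velocity(press, turret_frequency)
    p = penetration_depth / 1000.0  # m
    reach = press.roller_diameter / 2.0 + press.head_radius
    x_contact = _contact_halfwidth(press, p)
    y_contact = x_contact - press.head_flat_length / 2.0

    half_ms = x_contact / v * 1000.0
    half_ms *= 1.10  # 10% margin at fill depth on either side
    m = int(math.ceil(half_ms / sampling_step))
    t = np.arange(2 * m + 1) * sampling_step  # symmetric about index m
    x = (t - t[m]) / 1000.0 * v  # head-centre coordinate, m

    y = np.abs(x) - press.head_flat_length / 2.0
    z = np.zeros_like(x)  # lift above minimum separation, m
    on_flank = y > 0
    y_eff = np.minimum(y[on_flank], y_contact)
    z[on_flank] = reach - np.sqrt(reach**2 - y_eff**2)
    z[np.abs(x) >= x_contact] = p  # exact cap at the requested penetration

    gap_mm = min_separation + z * 1000.0
    return CompactionProfile(
        time=t,
        upper_pos=gap_mm / 2.0,
        lower_pos=-gap_mm / 2.0,
        stress=None,
        source="rotary_press",
        meta={
            "press": press.name,
            "turret_frequency": float(turret_frequency),
            "penetration_mm": float(penetration_depth),
            "min_separation_mm": float(min_separation),
            "dwell_ms": dwell_time(press, turret_frequency),
        },
    )


def _plateau_bounds(time: np.ndarray, separation: np.ndarray, tol_mm: float = 1e-6):
    """Indices (i0, i1) of the contiguous plateau around the separation minimum."""
    smin = separation.min()
    at_min = separation <= smin + tol_mm
    i_min = int(np.argmin(separation))
    i0 = i_min
    while i0 > 0 and at_min[i0 - 1]:
        i0 -= 1
    i1 = i_min
    while i1 < separation.size - 1 and at_min[i1 + 1]:
        i1 += 1
    return i0, i1


def apply_cs_execution(
    profile: CompactionProfile, deviation: "CsDeviationModel"
) -> CompactionProfile:
    """Replay a rotary-press profile the way the compaction simulator executes it.

    Three deviations are imposed, in this order:

    1. the whole event is stretched in time by a factor that grows with peak
       stress and shrinks with simulated turret speed (``>= 1`` over the
       supported operating grid);
    2. during the dwell plateau the punches keep approaching at
       ``v = -kappa / t_dwell`` (faster residual approach at shorter dwell),
       released linearly over one dwell-length afterwards;
    3. optional additive Gaussian separation noise scaled with simulated
       speed (machine-vibration stand-in).

    The stress channel, when present, is time-stretched but not re-derived
    from the perturbed separation; generators that know the
    displacement-to-stress law recompute it afterwards.
    """
    if profile.source != "rotary_press":
        raise ProfileError(
            f"apply_cs_execution expects a rotary_press profile, got {profile.source!r}"
        )
    n_t = profile.meta.get("turret_frequency")
    if n_t is None:
        raise ProfileError("profile.meta must carry 'turret_frequency'")
    peak_stress = float(profile.stress.max()) if profile.stress is not None else 0.0

    stretch = deviation.time_stretch(peak_stress, n_t)
    if stretch < 1.0 - 1e-12:
        raise ValueError(f"time stretch factor {stretch:.4f} < 1 outside the supported grid")

    dt = profile.dt
    n2 = int(round(profile.time[-1] * stretch / dt)) + 1
    t2 = np.arange(n2) * dt
    query = np.minimum(t2 / stretch, profile.time[-1])
    upper = np.interp(query, profile.time, profile.upper_pos)
    lower = np.interp(query, profile.time, profile.lower_pos)
    stress = (
        np.interp(query, profile.time, profile.stress) if profile.stress is not None else None
    )

    # residual punch approach during the (stretched) dwell plateau
    if deviation.residual_velocity_coeff > 0:
        i0, i1 = _plateau_bounds(t2, upper - lower)
        dwell_ms = t2[i1] - t2[i0]
        if dwell_ms > 0:
            v_mm_per_ms = abs(deviation.residual_velocity(dwell_ms)) / 1000.0
            delta = np.zeros_like(t2)
            in_dwell = slice(i0, i1 + 1)
            delta[in_dwell] = v_mm_per_ms * (t2[in_dwell] - t2[i0])
            total = v_mm_per_ms * dwell_ms
            after = t2 > t2[i1]
            delta[after] = total * np.clip(1.0 - (t2[after] - t2[i1]) / dwell_ms, 0.0, 1.0)
            upper = upper - delta / 2.0
            lower = lower + delta / 2.0

    noise_sd = deviation.noise_sd_per_speed * n_t
    if noise_sd > 0:
        rng = np.random.default_rng(deviation.seed)
        noise = rng.normal(0.0, noise_sd, size=n2)
        upper = upper + noise / 2.0
        lower = lower - noise / 2.0

    meta = dict(profile.meta)
    meta["time_stretch"] = float(stretch)
    return CompactionProfile(t2, upper, lower, stress, source="cs_simulated", meta=meta)
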
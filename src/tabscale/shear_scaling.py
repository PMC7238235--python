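"""Feed-frame shear numbers and the paddle-frequency matching solver.

The shear number SN is a dimensionless index of the cumulative shear a
lubricated powder experiences in a rotary-press feed frame (Narang-type
formulation), factorised as

    SN = (pi * d_p * k_s / c) * (m / (w * k_d))^2 * (n_p / n_t)^2
         `--- shear intensity --'  `- residence^2 -'  `- frequency -'

with d_p the paddle-wheel diameter, k_s the spoke count, c the spoke-to-base
clearance, m the feed-frame powder hold-up, w the tablet weight, k_d the
number of dies, and n_p / n_t the paddle and turret rotation frequencies.
The index is invariant to the frequency unit because only the ratio enters.

A compaction simulator (CS) differs in two ways from the rotary layout: its
paddle only runs while the feeder sits over the (single) die, and only one
die is under the feeder rather than several, so the powder is sheared
multiple times before it fills a die.  Both corrections rescale the
effective paddle frequency by phi_fill / 360 and phi_fill / phi_dies
respectively (angles of the simulated press), giving the CS-adapted number

    SN_C = (pi * d_p * k_s / c) * (m / (w * k_d))^2
           * (n_p / n_t * phi_fill^2 / (360 deg * phi_dies))^2

with the feeder factors taken from the CS feed frame and k_d, phi_fill,
phi_dies from the *simulated* rotary press.  Equating SN_C to the rotary SN
yields a closed form for the CS paddle frequency that reproduces the rotary
shear history -- the practical scaling rule this module solves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

from .machine_config import FeederGeometry, OperatingPoint, PressGeometry

__all__ = [
    "ShearNumberResult",
    "FillingTimeResult",
    "ideal_filling_time",
    "shear_number_rotary",
    "shear_number_cs",
    "cs_correction_factor",
    "match_paddle_frequency",
]

#: Default machine step for paddle-frequency setpoints (min^-1). Inferred from
#: the granularity of known matched operating pairs, not a vendor statement.
DEFAULT_ROUNDING_STEP = 4.0


@dataclass(frozen=True)
class ShearNumberResult:
    """A shear number with its factor decomposition.

    ``value`` always equals ``shear_intensity_term * residence_term *
    frequency_term * correction_factor`` (internal consistency oracle);
    the correction factor is 1 for a rotary press.
    """

    value: float
    shear_intensity_term: float  # pi * d_p * k_s / c
    residence_term: float  # (m / (w * k_d))^2
    frequency_term: float  # (n_p / n_t)^2
    correction_factor: float  # 1 or (phi_fill^2 / (360 * phi_dies))^2

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FillingTimeResult:
    """Ideal filling time t_f = V_R * rho_b / mdot (s), a residence-time scale.

    Assumes no dead volume in the feed system and constant bulk density.
    """

    value: float


def ideal_filling_time(feeder: FeederGeometry, op: OperatingPoint) -> FillingTimeResult:
    """t_f = V_R * rho_b / mdot with the operating point's measured mass flow."""
    if op.mass_flow is None:
        raise ValueError("operating point carries no mass flow; set OperatingPoint.mass_flow")
    return FillingTimeResult(feeder.feed_volume * feeder.bulk_density / op.mass_flow)


def _shear_intensity(feeder: FeederGeometry) -> float:
    return math.pi * feeder.paddle_diameter * feeder.n_spokes / feeder.clearance


def _residence_term(feeder: FeederGeometry, op: OperatingPoint, n_dies: int) -> float:
    return (feeder.holdup_mass / (op.tablet_weight * n_dies)) ** 2


def cs_correction_factor(press_simulated: PressGeometry) -> float:
    """(phi_fill^2 / (360 deg * phi_dies))^2 of the simulated rotary press."""
    return (
        press_simulated.fill_angle**2 / (360.0 * press_simulated.die_spacing_angle)
    ) ** 2


def shear_number_rotary(
    press: PressGeometry, feeder: FeederGeometry, op: OperatingPoint
) -> ShearNumberResult:
    """Shear number of a rotary-press feed frame (correction factor 1)."""
    intensity = _shear_intensity(feeder)
    residence = _residence_term(feeder, op, press.n_dies)
    frequency = (op.paddle_frequency / op.turret_frequency) ** 2
    return ShearNumberResult(intensity * residence * frequency, intensity, residence, frequency, 1.0)


def shear_number_cs(
    press_simulated: PressGeometry, cs_feeder: FeederGeometry, op: OperatingPoint
) -> ShearNumberResult:
    """CS-adapted shear number.

    Feeder factors (d_p, k_s, c, m) come from the CS feed frame; k_d,
    phi_fill and phi_dies from the simulated rotary press.
    """
    intensity = _shear_intensity(cs_feeder)
    residence = _residence_term(cs_feeder, op, press_simulated.n_dies)
    frequency = (op.paddle_frequency / op.turret_frequency) ** 2
    correction = cs_correction_factor(press_simulated)
    return ShearNumberResult(
        intensity * residence * frequency * correction,
        intensity,
        residence,
        frequency,
        correction,
    )


def match_paddle_frequency(
    press: PressGeometry,
    press_feeder: FeederGeometry,
    cs_feeder: FeederGeometry,
    op_press: OperatingPoint,
    rounding_step: Optional[float] = DEFAULT_ROUNDING_STEP,
) -> float:
    """CS paddle frequency (min^-1) whose SN_C matches the rotary press's SN.

    Closed form: with B = (pi * d_p * k_s / c) * (m / (w * k_d))^2 evaluated
    for each feed system (same w and simulated-press k_d on both sides, so
    both cancel),

        n_p_CS = n_p_press * sqrt(B_press / B_CS)
                 * 360 deg * phi_dies / phi_fill^2.

    The result is rounded to the nearest multiple of ``rounding_step``
    (``None`` disables rounding); the unrounded value round-trips through
    :func:`shear_number_cs` to the rotary shear number.
    """
    if op_press.paddle_frequency <= 0:
        raise ValueError("rotary paddle frequency must be positive to define a target SN")
    # tablet weight and die count cancel in B_press / B_CS; divide them out
    # algebraically so the result is exactly punch-size invariant
    ratio = (
        _shear_intensity(press_feeder)
        / _shear_intensity(cs_feeder)
        * (press_feeder.holdup_mass / cs_feeder.holdup_mass) ** 2
    )
    unrounded = (
        op_press.paddle_frequency
        * math.sqrt(ratio)
        * 360.0
        * press.die_spacing_angle
        / press.fill_angle**2
    )
    if rounding_step is None or rounding_step <= 0:
        return unrounded
    return round(unrounded / rounding_step) * rounding_step
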
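"""Synthetic study data: CS-deviated profile pairs and shear-response tablets.

No measured datasets ship with this package; instead, two generators emulate
the phenomenology the toolkit is built to analyse:

* :func:`generate_profile_pair` produces a rotary-press stress/displacement
  profile and its compaction-simulator (CS) execution, carrying the CS's
  systematic deviations -- stress- and speed-dependent prolongation of the
  event, residual punch approach during dwell, optional speed-scaled noise.
* :func:`sample_tablet_batch` draws tablet records whose tensile strengths
  follow a calibrated shear-response model: a log-logistic decay of
  equilibrium strength with feed-frame shear number, approached over runtime
  with the ideal filling time as relaxation constant (the feeder turnover
  time sets when influx, efflux and lubricant dispersion equilibrate).

Material presets (``MCC_MgSt`` ductile, ``Lactose_MgSt`` intermediate,
``DCP_MgSt`` brittle, ``Starch`` viscoplastic) are calibrated jointly with
the packaged machine fixtures; see ``fixtures/materials.yaml``.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Tuple

import numpy as np
import yaml

from .kinematics import apply_cs_execution, simulate_displacement
from .machine_config import OperatingPoint, PressGeometry
from .profiles import CompactionProfile
from .tablet_props import TabletRecord

__all__ = [
    "CsDeviationModel",
    "StressMaterialLaw",
    "MaterialResponse",
    "material_preset",
    "MATERIAL_PRESETS",
    "equilibrium_tensile_strength",
    "runtime_tensile_strength",
    "sample_tablet_batch",
    "generate_profile_pair",
    "REFERENCE_STRESS_MPA",
]

#: Compaction stress (MPa) at which material presets state their reference
#: tensile strength; the stress level of the runtime studies.
REFERENCE_STRESS_MPA = 150.0

#: Supported operating grid of the generators: target stress (MPa) and
#: simulated turret frequency (min^-1).
STRESS_RANGE_MPA = (50.0, 300.0)
SPEED_RANGE_MIN = (20.0, 70.0)

#: Reference dwell time (ms) for the viscoplastic dwell-sensitivity factor.
DWELL_REFERENCE_MS = 40.0

MATERIAL_PRESETS = ("MCC_MgSt", "Lactose_MgSt", "DCP_MgSt", "Starch")


@dataclass(frozen=True)
class CsDeviationModel:
    """Parametric model of how the CS's execution deviates from the ideal profile.

    ``time_stretch`` grows linearly with peak stress and falls with simulated
    turret speed; the defaults give at most ~18% prolongation at 300 MPa /
    20 min^-1 and stay >= 1 over the whole supported operating grid.  The
    residual dwell velocity is ``-kappa / t_dwell`` (mm/s for t_dwell in ms):
    a fixed total approach per event, hence faster residual motion at
    shorter dwell.  Separation noise is additive Gaussian with a standard
    deviation proportional to the simulated speed (default off).
    """

    prolongation_coeff_stress: float = 6.2e-4  # per MPa
    prolongation_coeff_speed: float = -4.0e-4  # per min^-1 (negative)
    residual_velocity_coeff: float = 25.0  # kappa, mm*ms/s
    noise_sd_per_speed: float = 0.0  # mm per min^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_velocity_coeff < 0:
            raise ValueError("residual_velocity_coeff must be >= 0")
        if self.noise_sd_per_speed < 0:
            raise ValueError("noise_sd_per_speed must be >= 0")
        # the stretch factor must stay >= 1 over the supported grid; its
        # extremes sit at the grid corners because the model is bilinear
        for stress in STRESS_RANGE_MPA:
            for speed in SPEED_RANGE_MIN:
                if self.time_stretch(stress, speed) < 1.0 - 1e-12:
                    raise ValueError(
                        f"time stretch < 1 at {stress} MPa, {speed} min^-1: "
                        "deviation coefficients leave the supported grid"
                    )

    @classmethod
    def identity(cls) -> "CsDeviationModel":
        """A deviation-free model: apply_cs_execution returns its input."""
        return cls(0.0, 0.0, 0.0, 0.0, 0)

    def time_stretch(self, peak_stress: float, turret_frequency: float) -> float:
        return (
            1.0
            + self.prolongation_coeff_stress * peak_stress
            + self.prolongation_coeff_speed * turret_frequency
        )

    def residual_velocity(self, dwell_ms: float) -> float:
        """Residual punch velocity during dwell, mm/s (negative: approaching)."""
        if dwell_ms <= 0:
            raise ValueError("dwell time must be positive")
        return -self.residual_velocity_coeff / dwell_ms


@dataclass(frozen=True)
class StressMaterialLaw:
    """Power-law mapping from punch engagement to axial stress for synthesis.

    sigma(c) = sigma_at_full_penetration * (c / penetration)^exponent for a
    compression depth c; a deliberately simple, hysteresis-free stand-in for
    a real in-die compressibility law, sufficient to shape stress pulses.
    """

    exponent: float = 2.0
    sigma_at_full_penetration: float = 150.0  # MPa

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        if self.sigma_at_full_penetration <= 0:
            raise ValueError("sigma_at_full_penetration must be positive")

    def stress(self, compression_mm: np.ndarray, penetration_mm: float) -> np.ndarray:
        frac = np.clip(np.asarray(compression_mm, dtype=float), 0.0, None) / penetration_mm
        return self.sigma_at_full_penetration * frac**self.exponent


@dataclass(frozen=True)
class MaterialResponse:
    """Shear-response model of one deformation class.

    Equilibrium tensile strength decays log-logistically with shear number
    from ``sigma_ref`` (unsheared, at the reference compaction stress) to
    ``sigma_floor``; ``sn50`` is the midpoint and ``hill`` the steepness per
    log10 decade.  ``dwell_sensitivity`` (viscoplastic class only) scales
    strength by ``1 + dwell_sensitivity * ln(t_dwell / 40 ms)``.
    """

    deformation_class: str  # ductile | intermediate | brittle | viscoplastic
    sigma_ref: float  # MPa
    sigma_floor: float  # MPa
    sn50: float
    hill: float
    equilibrium_time_mode: str = "ideal_filling_time"
    tabletability_slope: float = 1.0  # MPa/MPa
    dwell_sensitivity: float = 0.0  # per log(t_dwell/t_ref)

    def __post_init__(self) -> None:
        if self.deformation_class not in ("ductile", "intermediate", "brittle", "viscoplastic"):
            raise ValueError(f"unknown deformation class {self.deformation_class!r}")
        if self.sigma_floor > self.sigma_ref:
            raise ValueError("sigma_floor must not exceed sigma_ref")
        if self.sn50 <= 0 or self.hill <= 0:
            raise ValueError("sn50 and hill must be positive")
        if self.deformation_class == "brittle" and self.sigma_floor != self.sigma_ref:
            raise ValueError("brittle preset must be flat (sigma_floor == sigma_ref)")
        if self.dwell_sensitivity != 0.0 and self.deformation_class != "viscoplastic":
            raise ValueError("dwell_sensitivity is reserved for the viscoplastic class")
        if self.equilibrium_time_mode != "ideal_filling_time":
            raise ValueError("only the ideal_filling_time relaxation mode is defined")


def material_preset(name: str) -> MaterialResponse:
    """Load one of the packaged, jointly calibrated material presets."""
    raw = yaml.safe_load(
        (resources.files("tabscale") / "fixtures" / "materials.yaml").read_text()
    )
    if name not in raw:
        raise KeyError(f"unknown material preset {name!r}; available: {sorted(raw)}")
    return MaterialResponse(**raw[name])


def equilibrium_tensile_strength(mat: MaterialResponse, shear_number: float) -> float:
    """Equilibrium tensile strength (MPa) after full shear exposure at SN.

    sigma(SN) = sigma_floor + (sigma_ref - sigma_floor) / (1 + (SN/sn50)^hill);
    monotone non-increasing in SN, sigma_ref at SN = 0, the midpoint at sn50.
    """
    if shear_number < 0:
        raise ValueError("shear number must be >= 0")
    span = mat.sigma_ref - mat.sigma_floor
    return mat.sigma_floor + span / (1.0 + (shear_number / mat.sn50) ** mat.hill)


def runtime_tensile_strength(
    mat: MaterialResponse,
    shear_number: float,
    runtime: float,
    filling_time: float,
    sigma_start: Optional[float] = None,
) -> float:
    """Tensile strength (MPa) after ``runtime`` seconds of feeder operation.

    Exponential relaxation from ``sigma_start`` (default: the unsheared
    ``sigma_ref``) towards the equilibrium value, with the ideal filling
    time as the relaxation constant -- the plateau is reached once the
    feed-frame contents have turned over.
    """
    if runtime < 0:
        raise ValueError("runtime must be >= 0")
    if filling_time <= 0:
        raise ValueError("filling time must be positive")
    sigma_eq = equilibrium_tensile_strength(mat, shear_number)
    start = mat.sigma_ref if sigma_start is None else sigma_start
    return sigma_eq + (start - sigma_eq) * math.exp(-runtime / filling_time)


def _diameter_for_weight(tablet_weight_kg: float) -> float:
    """Standard punch diameter (mm) for a tablet weight (300/450/725 mg bands)."""
    mg = tablet_weight_kg * 1e6
    if mg <= 350.0:
        return 9.0
    if mg <= 550.0:
        return 11.28
    return 14.0


def sample_tablet_batch(
    mat: MaterialResponse,
    op: OperatingPoint,
    shear_number: float,
    runtime: float,
    n: int,
    cv: float = 0.05,
    seed: int = 0,
    *,
    filling_time: Optional[float] = None,
    sigma_start: Optional[float] = None,
    diameter_mm: Optional[float] = None,
    dwell_time_ms: Optional[float] = None,
) -> List[TabletRecord]:
    """Draw ``n`` synthetic tablet records for one operating condition.

    The model mean tensile strength is the runtime shear response scaled by
    ``tabletability_slope * target_stress / 150 MPa`` (linear tabletability
    around the reference stress) and, for the viscoplastic class, by the
    dwell-sensitivity factor when ``dwell_time_ms`` is given.  Individual
    strengths carry multiplicative log-normal noise of coefficient of
    variation ``cv`` (unit mean), mapped back to breaking forces through the
    diametral-compression relation.  ``filling_time`` (s) is the relaxation
    constant; when omitted, the batch is sampled at equilibrium.

    Deterministic for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("need n >= 1 tablets")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if filling_time is None:
        mean_ts = equilibrium_tensile_strength(mat, shear_number)
    else:
        mean_ts = runtime_tensile_strength(mat, shear_number, runtime, filling_time, sigma_start)
    mean_ts *= mat.tabletability_slope * op.target_stress / REFERENCE_STRESS_MPA
    if dwell_time_ms is not None and mat.dwell_sensitivity != 0.0:
        mean_ts *= 1.0 + mat.dwell_sensitivity * math.log(dwell_time_ms / DWELL_REFERENCE_MS)

    diameter = _diameter_for_weight(op.tablet_weight) if diameter_mm is None else diameter_mm
    mass_mg = op.tablet_weight * 1e6
    apparent_density = 1.4  # g/cm^3, typical compact density
    thickness_mm = mass_mg / 1000.0 / (apparent_density * math.pi * (diameter / 20.0) ** 2) * 10.0

    rng = np.random.default_rng(seed)
    if cv > 0:
        s = math.sqrt(math.log(1.0 + cv**2))
        factors = np.exp(rng.normal(-0.5 * s * s, s, size=n))
    else:
        factors = np.ones(n)
    records = []
    for f in factors:
        sigma_t = mean_ts * f
        force = sigma_t * math.pi * thickness_mm * diameter / 2.0
        records.append(
            TabletRecord(
                diameter_mm=diameter,
                thickness_mm=thickness_mm,
                breaking_force_N=force,
                mass_mg=mass_mg,
                true_density_g_cm3=1.55,
                compaction_stress_MPa=op.target_stress,
            )
        )
    return records


def _check_grid(op: OperatingPoint) -> None:
    lo_s, hi_s = STRESS_RANGE_MPA
    lo_n, hi_n = SPEED_RANGE_MIN
    if not lo_s <= op.target_stress <= hi_s:
        raise ValueError(f"target stress {op.target_stress} MPa outside supported {lo_s}-{hi_s}")
    if not lo_n <= op.turret_frequency <= hi_n:
        raise ValueError(
            f"turret frequency {op.turret_frequency} min^-1 outside supported {lo_n}-{hi_n}"
        )


def generate_profile_pair(
    press: PressGeometry,
    op: OperatingPoint,
    law: Optional[StressMaterialLaw] = None,
    deviation: Optional[CsDeviationModel] = None,
    sampling_step: float = 0.1,
    penetration_mm: float = 3.0,
    min_separation_mm: float = 2.0,
) -> Tuple[CompactionProfile, CompactionProfile]:
    """(rotary, CS) stress-carrying profile pair for one operating point.

    The rotary profile is the exact geometric displacement with stress from
    the material law; the CS profile is its deviated execution, its stress
    recomputed from the perturbed separation and rescaled to the rotary peak
    (the CS holds the target peak stress while its pulse widens and its
    dwell-phase stress drifts upward with the residual punch approach).
    """
    _check_grid(op)
    if law is None:
        law = StressMaterialLaw(sigma_at_full_penetration=op.target_stress)
    if deviation is None:
        deviation = CsDeviationModel()

    rotary = simulate_displacement(
        press, op.turret_frequency, penetration_mm, sampling_step, min_separation_mm
    )
    compression = penetration_mm - (rotary.separation - min_separation_mm)
    rotary = rotary.with_stress(law.stress(compression, penetration_mm))

    cs = apply_cs_execution(rotary, deviation)
    compression_cs = penetration_mm - (cs.separation - min_separation_mm)
    stress_cs = law.stress(compression_cs, penetration_mm)
    peak = stress_cs.max()
    if peak > 0:
        stress_cs = stress_cs * (rotary.stress.max() / peak)
    cs = CompactionProfile(
        cs.time, cs.upper_pos, cs.lower_pos, stress_cs, source="cs_simulated", meta=cs.meta
    )
    return rotary, cs
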
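"""Diagnostics extracted from measured or simulated compaction profiles.

Three quantities characterise how faithfully a compaction simulator replays a
rotary-press event:

* the **dwell window** -- the maximal contiguous interval where the punch
  separation sits within a tolerance of its minimum;
* the **residual dwell velocity** -- the least-squares slope of separation
  over the dwell window (negative when the punches keep approaching);
* the **compression-time prolongation** -- the relative excess of the CS
  profile's duration above a stress threshold over the rotary reference.

The prolongation metric is defined operationally as the ratio of durations
above a configurable fraction of peak stress (default 10%), which is robust
to baseline noise while capturing the visible widening of the stress pulse.
Threshold crossings are located by linear interpolation between samples, so
an ideal triangular pulse yields its exact analytic width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .profiles import CompactionProfile, ProfileError

__all__ = [
    "DwellWindow",
    "ProfileMetrics",
    "detect_dwell_window",
    "residual_dwell_velocity",
    "residual_dwell_velocity_fit",
    "compression_time",
    "prolongation",
    "summarize",
    "smooth",
]

#: Default dwell-detection tolerance: 10 um of separation above the minimum,
#: on the order of punch-position sensor resolution.
DEFAULT_DWELL_TOLERANCE_MM = 0.010

#: Default stress-threshold fraction for compression-time measurements.
DEFAULT_STRESS_THRESHOLD = 0.10


class DwellWindow(NamedTuple):
    """Time interval (ms) of the dwell plateau; degenerate if single-sample."""

    t_start: float
    t_end: float
    degenerate: bool

    @property
    def length(self) -> float:
        return self.t_end - self.t_start


class VelocityFit(NamedTuple):
    """Residual dwell velocity fit: slope in mm/s with its standard error."""

    velocity: float
    stderr: float
    n_samples: int


@dataclass
class ProfileMetrics:
    """Per-profile summary of the dwell-phase diagnostics."""

    dwell_time: float  # ms
    compression_time: Optional[float]  # ms, stress above threshold
    peak_stress: Optional[float]  # MPa
    residual_dwell_velocity: float  # mm/s, negative = punches approaching
    prolongation_vs_reference: Optional[float] = None  # dimensionless fraction

    def as_dict(self) -> dict:
        return {
            "dwell_time_ms": self.dwell_time,
            "compression_time_ms": self.compression_time,
            "peak_stress_MPa": self.peak_stress,
            "residual_dwell_velocity_mm_s": self.residual_dwell_velocity,
            "prolongation_vs_reference": self.prolongation_vs_reference,
        }


def smooth(profile: CompactionProfile, window: int) -> CompactionProfile:
    """Moving-average pre-smoothing for noisy high-speed profiles (optional).

    ``window`` is the box width in samples; end effects are handled by edge
    padding so the series length is preserved.
    """
    if window < 2:
        return profile
    kernel = np.ones(window) / window

    def _box(arr: np.ndarray) -> np.ndarray:
        padded = np.pad(arr, (window // 2, window - 1 - window // 2), mode="edge")
        return np.convolve(padded, kernel, mode="valid")

    return CompactionProfile(
        profile.time.copy(),
        _box(profile.upper_pos),
        _box(profile.lower_pos),
        None if profile.stress is None else _box(profile.stress),
        profile.source,
        dict(profile.meta),
    )


def detect_dwell_window(
    profile: CompactionProfile,
    separation_tolerance: float = DEFAULT_DWELL_TOLERANCE_MM,
) -> DwellWindow:
    """Maximal contiguous interval with separation <= min(separation) + tolerance.

    When several runs qualify, the longest one is returned (first on ties).
    A single-sample interval (no resolvable plateau) is flagged degenerate.
    """
    if profile.time.size < 10:
        raise ProfileError("dwell detection needs at least 10 samples")
    if separation_tolerance <= 0:
        raise ValueError("separation tolerance must be positive")
    sep = profile.separation
    mask = sep <= sep.min() + separation_tolerance
    # enumerate contiguous runs of True
    edges = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size - 1)
    lengths = [e - s for s, e in zip(starts, ends)]
    best = int(np.argmax(lengths))
    i0, i1 = starts[best], ends[best]
    return DwellWindow(float(profile.time[i0]), float(profile.time[i1]), degenerate=i1 == i0)


def _window_slice(profile: CompactionProfile, window: DwellWindow) -> np.ndarray:
    return (profile.time >= window.t_start - 1e-12) & (profile.time <= window.t_end + 1e-12)


def residual_dwell_velocity_fit(
    profile: CompactionProfile, window: DwellWindow
) -> VelocityFit:
    """Unweighted least-squares fit of separation vs time over the dwell window.

    Returns the slope converted to mm/s together with its standard error;
    negative velocities indicate a further approach of the punches.
    """
    sel = _window_slice(profile, window)
    n = int(sel.sum())
    if n < 3:
        raise ProfileError(f"dwell window holds {n} samples; need at least 3 for a fit")
    fit = stats.linregress(profile.time[sel], profile.separation[sel])
    return VelocityFit(float(fit.slope * 1000.0), float(fit.stderr * 1000.0), n)


def residual_dwell_velocity(profile: CompactionProfile, window: DwellWindow) -> float:
    """Residual punch velocity during dwell (mm/s, signed)."""
    return residual_dwell_velocity_fit(profile, window).velocity


def compression_time(
    profile: CompactionProfile,
    stress_threshold_fraction: float = DEFAULT_STRESS_THRESHOLD,
) -> float:
    """Total time (ms) with stress at or above a fraction of its peak.

    Crossing times are interpolated linearly between samples; disjoint
    super-threshold episodes (if any) are summed.
    """
    if profile.stress is None:
        raise ProfileError("profile carries no stress channel")
    if not 0.0 < stress_threshold_fraction < 1.0:
        raise ValueError("stress threshold fraction must lie in (0, 1)")
    stress = profile.stress
    peak = stress.max()
    if peak <= 0:
        raise ProfileError("all-zero stress channel: no peak to threshold against")
    thr = stress_threshold_fraction * peak
    above = stress >= thr
    if not above.any():
        return 0.0
    t = profile.time
    total = 0.0
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size - 1)
    for s, e in zip(starts, ends):
        t_enter = t[s]
        if s > 0 and stress[s] != stress[s - 1]:
            t_enter = t[s - 1] + (thr - stress[s - 1]) / (stress[s] - stress[s - 1]) * (
                t[s] - t[s - 1]
            )
        t_exit = t[e]
        if e < t.size - 1 and stress[e + 1] != stress[e]:
            t_exit = t[e] + (thr - stress[e]) / (stress[e + 1] - stress[e]) * (
                t[e + 1] - t[e]
            )
        total += t_exit - t_enter
    return float(total)


def prolongation(
    cs_profile: CompactionProfile,
    press_profile: CompactionProfile,
    stress_threshold_fraction: float = DEFAULT_STRESS_THRESHOLD,
) -> float:
    """Relative prolongation of the CS stress pulse over the rotary reference.

    ``compression_time(cs) / compression_time(press) - 1`` at a common
    threshold fraction; exactly 0 for identical profiles.
    """
    t_cs = compression_time(cs_profile, stress_threshold_fraction)
    t_press = compression_time(press_profile, stress_threshold_fraction)
    if t_press <= 0:
        raise ProfileError("reference profile has zero compression time")
    return t_cs / t_press - 1.0


def summarize(
    profile: CompactionProfile,
    reference: Optional[CompactionProfile] = None,
    separation_tolerance: float = DEFAULT_DWELL_TOLERANCE_MM,
    stress_threshold_fraction: float = DEFAULT_STRESS_THRESHOLD,
) -> ProfileMetrics:
    """Assemble the dwell/compression metrics for one profile."""
    window = detect_dwell_window(profile, separation_tolerance)
    velocity = residual_dwell_velocity(profile, window)
    has_stress = profile.stress is not None
    return ProfileMetrics(
        dwell_time=window.length,
        compression_time=compression_time(profile, stress_threshold_fraction)
        if has_stress
        else None,
        peak_stress=float(profile.stress.max()) if has_stress else None,
        residual_dwell_velocity=velocity,
        prolongation_vs_reference=(
            prolongation(profile, reference, stress_threshold_fraction)
            if reference is not None and has_stress
            else None
        ),
    )
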
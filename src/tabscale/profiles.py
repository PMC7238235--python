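"""Uniformly sampled compaction-event time series and their CSV dialect.

A :class:`CompactionProfile` holds upper/lower punch positions (mm) on a
uniform time axis (ms), with an optional axial-stress channel (MPa).  The
punch separation is derived as ``upper_pos - lower_pos`` and is the quantity
the dwell-phase diagnostics operate on.

CSV dialect (comma separated, decimal point, header required):
``time_ms, upper_pos_mm, lower_pos_mm[, stress_MPa]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["CompactionProfile", "ProfileError", "read_profile", "write_profile"]

_SOURCES = ("rotary_press", "cs_simulated", "measured")


class ProfileError(ValueError):
    """Raised for malformed or degenerate compaction profiles."""


@dataclass
class CompactionProfile:
    """One compaction event: punch positions and stress over uniform time.

    Parameters
    ----------
    time : ndarray
        Strictly increasing, uniformly spaced times in ms.
    upper_pos, lower_pos : ndarray
        Punch tip positions in mm (upper above lower; the gap is the
        separation).
    stress : ndarray, optional
        Axial compaction stress in MPa.
    source : str
        One of ``rotary_press``, ``cs_simulated``, ``measured``.
    meta : dict
        Free-form provenance (turret frequency, penetration depth, ...).
    """

    time: np.ndarray
    upper_pos: np.ndarray
    lower_pos: np.ndarray
    stress: Optional[np.ndarray] = None
    source: str = "measured"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.upper_pos = np.asarray(self.upper_pos, dtype=float)
        self.lower_pos = np.asarray(self.lower_pos, dtype=float)
        if self.stress is not None:
            self.stress = np.asarray(self.stress, dtype=float)
        n = self.time.size
        if n < 2:
            raise ProfileError("profile needs at least two samples")
        for name in ("upper_pos", "lower_pos", "stress"):
            arr = getattr(self, name)
            if arr is not None and arr.size != n:
                raise ProfileError(f"{name} length {arr.size} != time length {n}")
        steps = np.diff(self.time)
        if steps.min() <= 0:
            raise ProfileError("time must be strictly increasing")
        dt = steps.mean()
        if np.abs(steps - dt).max() > 1e-9 * max(dt, 1.0) + 1e-12:
            raise ProfileError("time must be uniformly sampled")
        if (self.upper_pos - self.lower_pos).min() < -1e-9:
            raise ProfileError("punch separation must be non-negative")
        if self.stress is not None and self.stress.min() < -1e-9:
            raise ProfileError("stress must be non-negative")
        if self.source not in _SOURCES:
            raise ProfileError(f"source must be one of {_SOURCES}, got {self.source!r}")

    @property
    def separation(self) -> np.ndarray:
        """Punch separation (mm), derived as ``upper_pos - lower_pos``."""
        return self.upper_pos - self.lower_pos

    @property
    def dt(self) -> float:
        """Sampling step in ms."""
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        """Total covered time span in ms."""
        return float(self.time[-1] - self.time[0])

    def with_stress(self, stress: np.ndarray) -> "CompactionProfile":
        """Copy of this profile with a (new) stress channel."""
        return CompactionProfile(
            self.time.copy(), self.upper_pos.copy(), self.lower_pos.copy(),
            np.asarray(stress, dtype=float), self.source, dict(self.meta),
        )


def write_profile(profile: CompactionProfile, path: str | Path) -> None:
    cols = {
        "time_ms": profile.time,
        "upper_pos_mm": profile.upper_pos,
        "lower_pos_mm": profile.lower_pos,
    }
    if profile.stress is not None:
        cols["stress_MPa"] = profile.stress
    pd.DataFrame(cols).to_csv(path, index=False)


def read_profile(path: str | Path, source: str = "measured") -> CompactionProfile:
    df = pd.read_csv(path)
    required = {"time_ms", "upper_pos_mm", "lower_pos_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ProfileError(f"profile CSV {path} missing columns {sorted(missing)}")
    stress = df["stress_MPa"].to_numpy() if "stress_MPa" in df.columns else None
    return CompactionProfile(
        df["time_ms"].to_numpy(),
        df["upper_pos_mm"].to_numpy(),
        df["lower_pos_mm"].to_numpy(),
        stress,
        source=source,
    )
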
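"""Tablet-level property calculations and tabletability-curve assembly.

Tensile strength of a round flat-faced tablet follows the diametral
compression relation sigma_t = 2 F / (pi * h_t * d_t) (Fell/Newton), in MPa
for a breaking force in N and dimensions in mm.  Porosity is computed
out-of-die from the envelope volume and the true density of the solid.
Normalizing tensile strength by the peak compaction stress removes
filling-efficiency artefacts from runtime studies, under the assumption that
tensile strength correlates linearly with compaction stress over the
affected range.

Tablet table CSV dialect: columns ``diameter_mm, thickness_mm,
breaking_force_N`` with optional ``mass_mg, true_density_g_cm3,
compaction_stress_MPa``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TabletRecord",
    "TabletabilityCurve",
    "tensile_strength",
    "porosity",
    "normalize_by_stress",
    "build_tabletability",
    "read_tablet_table",
    "write_tablet_table",
]


@dataclass(frozen=True)
class TabletRecord:
    """One tested tablet: geometry, breaking force and optional context."""

    diameter_mm: float
    thickness_mm: float
    breaking_force_N: float
    mass_mg: Optional[float] = None
    true_density_g_cm3: Optional[float] = None
    compaction_stress_MPa: Optional[float] = None

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.thickness_mm <= 0:
            raise ValueError("tablet dimensions must be positive")
        if self.breaking_force_N < 0:
            raise ValueError("breaking force must be non-negative")
        for name in ("mass_mg", "true_density_g_cm3", "compaction_stress_MPa"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")


@dataclass(frozen=True)
class TabletabilityCurve:
    """Mean/sd tensile strength per compaction-stress level, stress-sorted."""

    points: Tuple[Tuple[float, float, float, int], ...]
    # (compaction_stress_MPa, tensile_strength_mean, tensile_strength_sd, n)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points,
            columns=[
                "compaction_stress_MPa",
                "tensile_strength_mean_MPa",
                "tensile_strength_sd_MPa",
                "n",
            ],
        )


def tensile_strength(rec: TabletRecord) -> float:
    """Diametral-compression tensile strength 2F/(pi h d) in MPa."""
    return 2.0 * rec.breaking_force_N / (math.pi * rec.thickness_mm * rec.diameter_mm)


def porosity(rec: TabletRecord) -> float:
    """Out-of-die porosity 1 - rho_apparent / rho_true from envelope volume.

    Returns a value below 0 (flagged to the caller, not clipped) when the
    apparent density exceeds the stated true density.
    """
    if rec.mass_mg is None or rec.true_density_g_cm3 is None:
        raise ValueError("porosity needs mass_mg and true_density_g_cm3")
    volume_cm3 = math.pi * (rec.diameter_mm / 20.0) ** 2 * (rec.thickness_mm / 10.0)
    apparent = rec.mass_mg / 1000.0 / volume_cm3
    return 1.0 - apparent / rec.true_density_g_cm3


def normalize_by_stress(rec: TabletRecord) -> float:
    """Tensile strength divided by the tablet's peak compaction stress (MPa/MPa)."""
    if rec.compaction_stress_MPa is None:
        raise ValueError("record carries no compaction stress")
    return tensile_strength(rec) / rec.compaction_stress_MPa


def build_tabletability(
    records: Sequence[TabletRecord],
    grouping_tolerance: Optional[float] = None,
) -> TabletabilityCurve:
    """Group records by compaction stress and summarise tensile strength.

    Records within ``grouping_tolerance`` MPa of a group's first stress are
    pooled (default tolerance: 5% of that stress, absorbing press-to-press
    stress scatter around a setpoint).  Mean and sample standard deviation
    (ddof=1; 0 for singleton groups) per group, stresses ascending.
    """
    if not records:
        raise ValueError("no tablet records given")
    for rec in records:
        if rec.compaction_stress_MPa is None:
            raise ValueError("all records need compaction_stress_MPa for a tabletability curve")
    ordered = sorted(records, key=lambda r: r.compaction_stress_MPa)
    groups: List[List[TabletRecord]] = [[ordered[0]]]
    for rec in ordered[1:]:
        anchor = groups[-1][0].compaction_stress_MPa
        tol = grouping_tolerance if grouping_tolerance is not None else 0.05 * anchor
        if rec.compaction_stress_MPa - anchor <= tol:
            groups[-1].append(rec)
        else:
            groups.append([rec])
    points = []
    for group in groups:
        ts = np.array([tensile_strength(r) for r in group])
        stress = float(np.mean([r.compaction_stress_MPa for r in group]))
        sd = float(np.std(ts, ddof=1)) if ts.size > 1 else 0.0
        points.append((stress, float(ts.mean()), sd, int(ts.size)))
    return TabletabilityCurve(tuple(points))


_COLUMNS = [
    "diameter_mm",
    "thickness_mm",
    "breaking_force_N",
    "mass_mg",
    "true_density_g_cm3",
    "compaction_stress_MPa",
]


def write_tablet_table(records: Sequence[TabletRecord], path: str | Path) -> None:
    rows = [{c: getattr(r, c) for c in _COLUMNS} for r in records]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_tablet_table(path: str | Path) -> List[TabletRecord]:
    df = pd.read_csv(path)
    missing = {"diameter_mm", "thickness_mm", "breaking_force_N"} - set(df.columns)
    if missing:
        raise ValueError(f"tablet table {path} missing columns {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        kwargs = {c: row.get(c) for c in _COLUMNS}
        kwargs = {k: (None if v is None or (isinstance(v, float) and math.isnan(v)) else v)
                  for k, v in kwargs.items()}
        records.append(TabletRecord(**kwargs))
    return records
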
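"""Typed machine definitions and fixture I/O.

A tableting machine is described by the geometry of its turret/compression
station (:class:`PressGeometry`), its paddle feed frame
(:class:`FeederGeometry`), and a run-level :class:`OperatingPoint`.  The three
packaged fixtures -- the pilot-scale rotary press ``XL100`` (4 installed
dies), the production-scale ``XL400`` (29 dies), and the single-station
compaction simulator ``StylOne`` -- carry documented placeholder geometry
(see the ``provenance`` block of each fixture file): vendors do not publish
feed-frame dimensions, so the placeholders are calibrated against the known
operating anchors (theoretical dwell time, matched paddle-frequency pairs)
instead.

Angles are stored in degrees, lengths in SI metres, masses in kg and
rotation frequencies in min^-1, matching the conventions of the underlying
shear-number equations.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "PressGeometry",
    "FeederGeometry",
    "OperatingPoint",
    "MachineFixture",
    "FixtureError",
    "PACKAGED_FIXTURES",
    "load_fixture",
    "save_fixture",
]

#: Fixture ids resolvable by :func:`load_fixture` without a path.
PACKAGED_FIXTURES = ("XL100", "XL400", "StylOne")


class FixtureError(ValueError):
    """Raised when a fixture file is missing, malformed, or violates an invariant."""


class PressGeometry(BaseModel):
    """Turret, compression-roller and punch-head geometry of a (simulated) press.

    ``die_spacing_angle`` is the angular spacing of the *installed* die set
    (360deg / n_dies for an evenly under-tooled turret); ``fill_angle`` is the
    angle the feed-frame window occupies on the pitch circle.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    pitch_circle_diameter: float = Field(gt=0, description="turret pitch circle diameter (m)")
    n_dies: int = Field(ge=1, description="number of installed dies k_d")
    roller_diameter: float = Field(gt=0, description="compression roller diameter (m)")
    head_flat_length: float = Field(gt=0, description="punch head flat length l_f (m)")
    head_radius: float = Field(gt=0, description="punch head curvature radius r_h (m)")
    fill_angle: float = Field(gt=0, le=360, description="feeder fill angle phi_fill (deg)")
    die_spacing_angle: float = Field(gt=0, le=360, description="die spacing angle phi_dies (deg)")


class FeederGeometry(BaseModel):
    """Paddle-wheel geometry and powder hold-up of a feed frame."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    paddle_diameter: float = Field(gt=0, description="paddle wheel diameter d_p (m)")
    n_spokes: int = Field(ge=1, description="number of paddle spokes k_s")
    clearance: float = Field(gt=0, description="spoke-to-base clearance c (m)")
    holdup_mass: float = Field(gt=0, description="powder mass in the feed frame m (kg)")
    feed_volume: float = Field(gt=0, description="feed system volume V_R (m^3)")
    bulk_density: float = Field(gt=0, description="powder bulk density rho_b (kg/m^3)")

    @model_validator(mode="after")
    def _holdup_fits_volume(self) -> "FeederGeometry":
        if self.holdup_mass > self.feed_volume * self.bulk_density * (1 + 1e-12):
            raise ValueError(
                "holdup_mass exceeds feed_volume * bulk_density "
                f"({self.holdup_mass} > {self.feed_volume * self.bulk_density})"
            )
        return self


class OperatingPoint(BaseModel):
    """One run condition of a press or compaction simulator.

    ``mass_flow`` is optional: it is only required for the ideal-filling-time
    computation and may be measured or estimated as w * n_t * k_d / 60.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    turret_frequency: float = Field(gt=0, description="turret rotation frequency n_t (min^-1)")
    paddle_frequency: float = Field(ge=0, description="feeder paddle frequency n_p (min^-1)")
    target_stress: float = Field(gt=0, description="target compaction stress (MPa)")
    tablet_weight: float = Field(gt=0, description="single tablet weight w (kg)")
    mass_flow: Optional[float] = Field(default=None, gt=0, description="powder mass flow (kg/s)")


class MachineFixture(BaseModel):
    """A complete machine definition: press geometry, feeder, and machine kind."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    press: PressGeometry
    feeder: FeederGeometry
    kind: Literal["rotary_press", "compaction_simulator"]
    provenance: Optional[dict[str, str]] = Field(
        default=None,
        description="per-field data provenance notes (e.g. 'placeholder', 'calibrated')",
    )

    @model_validator(mode="after")
    def _cs_has_single_die(self) -> "MachineFixture":
        if self.kind == "compaction_simulator" and self.press.n_dies != 1:
            raise ValueError(
                "a compaction simulator has exactly one die position under the feeder "
                f"(n_dies={self.press.n_dies})"
            )
        return self


def default_mass_flow(op: OperatingPoint, press: PressGeometry) -> float:
    """Estimated mass flow w * n_t * k_d / 60 in kg/s (constant tablet weight)."""
    return op.tablet_weight * op.turret_frequency * press.n_dies / 60.0


def _fixture_text(name_or_path: str | Path) -> str:
    name = str(name_or_path)
    if name in PACKAGED_FIXTURES:
        return (resources.files("tabscale") / "fixtures" / f"{name}.yaml").read_text()
    path = Path(name_or_path)
    if not path.exists():
        raise FixtureError(
            f"unknown fixture {name!r}: not one of {PACKAGED_FIXTURES} and no such file"
        )
    return path.read_text()


def load_fixture(name_or_path: str | Path) -> MachineFixture:
    """Load a packaged fixture by id ("XL100", "XL400", "StylOne") or a YAML file.

    All geometric invariants are checked on load; unknown fields are rejected
    so a typo in a config file cannot silently fall back to a default.
    """
    raw = yaml.safe_load(_fixture_text(name_or_path))
    if not isinstance(raw, dict):
        raise FixtureError(f"fixture {name_or_path!r} is not a mapping")
    try:
        return MachineFixture.model_validate(raw)
    except ValidationError as exc:
        # re-raise with the offending field and constraint in one line
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise FixtureError(f"invalid fixture {name_or_path!r}: {loc}: {first['msg']}") from exc


def save_fixture(fixture: MachineFixture, path: str | Path) -> None:
    """Write a fixture as YAML such that ``load_fixture(path)`` round-trips."""
    data = fixture.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
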
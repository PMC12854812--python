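"""Species parameterization and species-area-relationship (SAR) risk math.

Extinction risk follows the power-law SAR: a species that has lost part of
its original habitat area A_O, retaining A_c, carries risk

    r = 1 - (A_c / A_O) ** z

with z the exponent governing how risk scales with habitat loss (0.25 by
convention; 0.1-0.4 for sensitivity).  Restoring area reduces risk; because
z < 1 the marginal benefit of each additional restored pixel shrinks as
A_c grows (diminishing returns).

All areas in this module are km^2.  Hectare-denominated quantities (costs,
pixel bookkeeping) are converted at module boundaries, never mixed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .geodata import RangeGeometry, read_range

logger = logging.getLogger(__name__)

DEFAULT_Z = 0.25
Z_SWEEP = (0.1, 0.25, 0.4)


@dataclass
class SpeciesProfile:
    """Everything the pipeline needs to know about one indicator species."""

    name: str
    preferred_habitat_codes: frozenset[int]
    dispersal_km: float
    current_range: RangeGeometry
    historical_range: RangeGeometry
    z: float = DEFAULT_Z
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be non-empty")
        self.preferred_habitat_codes = frozenset(int(c) for c in self.preferred_habitat_codes)
        if not self.preferred_habitat_codes:
            raise ValueError(f"{self.name}: preferred habitat codes must be non-empty")
        if self.dispersal_km < 0:
            raise ValueError(f"{self.name}: dispersal distance must be >= 0")
        if not 0 < self.z < 1:
            raise ValueError(f"{self.name}: z must lie in (0, 1), got {self.z}")
        if self.weight < 0:
            raise ValueError(f"{self.name}: weight must be >= 0")

    def initial_state(self) -> "SpeciesState":
        """SAR state from the planar areas of the range geometries."""
        return SpeciesState(
            area_current=self.current_range.area_km2,
            area_original=self.historical_range.area_km2,
        )


@dataclass
class SpeciesState:
    """Mutable SAR state: current and original habitat area in km^2.

    ``area_current`` only ever grows (restoration is permanent).
    """

    area_current: float
    area_original: float

    def __post_init__(self) -> None:
        if self.area_original <= 0:
            raise ValueError("original habitat area must be positive")
        if self.area_current < 0:
            raise ValueError("current habitat area must be non-negative")

    def add_restored(self, added_km2: float) -> None:
        if added_km2 < 0:
            raise ValueError("restored area must be non-negative")
        self.area_current += added_km2


def extinction_risk(state: SpeciesState, z: float = DEFAULT_Z) -> float:
    """Current extinction risk r0 = 1 - (A_c/A_O)^z, clamped to [0, 1].

    The clamp covers independently sourced range maps where A_c can exceed
    A_O (risk 0, with a warning); the formula itself never leaves [0, 1]
    for A_c <= A_O.
    """
    ratio = state.area_current / state.area_original
    if ratio > 1.0:
        logger.warning(
            "current area exceeds original area (ratio %.3f); risk clamped to 0", ratio
        )
        return 0.0
    return 1.0 - ratio**z


def restored_risk(state: SpeciesState, added_area_km2: float, z: float = DEFAULT_Z) -> float:
    """Risk r1 after restoring ``added_area_km2`` of preferred habitat."""
    if added_area_km2 < 0:
        raise ValueError("added area must be non-negative")
    return extinction_risk(
        SpeciesState(
            area_current=state.area_current + added_area_km2,
            area_original=state.area_original,
        ),
        z,
    )


def risk_reduction(state: SpeciesState, pixel_area_km2: float, z: float = DEFAULT_Z) -> float:
    """Risk reduction r0 - r1 from restoring one pixel of preferred habitat.

    Non-negative; strictly decreasing in A_c for fixed pixel area
    (diminishing returns under z < 1).
    """
    return extinction_risk(state, z) - restored_risk(state, pixel_area_km2, z)


# ---------------------------------------------------------------------------
# Species table I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "name",
    "preferred_habitat_codes",
    "dispersal_km",
    "z",
    "weight",
    "current_range_path",
    "historical_range_path",
)


def load_species_table(
    path: str | Path, known_habitat_codes: set[int] | None = None
) -> list[SpeciesProfile]:
    """Load species profiles from a CSV table.

    Columns: name, preferred_habitat_codes (semicolon-separated integers),
    dispersal_km, z, weight, current_range_path, historical_range_path
    (GeoJSON paths, resolved relative to the table's directory).
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if table["name"].duplicated().any():
        dupes = table.loc[table["name"].duplicated(), "name"].tolist()
        raise ValueError(f"{path}: duplicate species names {dupes}")
    profiles = []
    for idx, row in table.iterrows():
        try:
            codes = frozenset(
                int(tok) for tok in str(row["preferred_habitat_codes"]).split(";") if tok.strip()
            )
            if known_habitat_codes is not None and not codes <= set(known_habitat_codes):
                raise ValueError(
                    f"unknown habitat codes {sorted(codes - set(known_habitat_codes))}"
                )
            profile = SpeciesProfile(
                name=str(row["name"]),
                preferred_habitat_codes=codes,
                dispersal_km=float(row["dispersal_km"]),
                z=float(row["z"]),
                weight=float(row["weight"]),
                current_range=read_range(path.parent / row["current_range_path"], "current"),
                historical_range=read_range(
                    path.parent / row["historical_range_path"], "historical"
                ),
            )
        except (ValueError, OSError) as exc:
            raise ValueError(f"{path}: row {idx} ({row.get('name', '?')}): {exc}") from exc
        profiles.append(profile)
    return profiles
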
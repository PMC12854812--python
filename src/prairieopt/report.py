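"""Scenario accounting: costs, restored area by habitat, risk improvement.

Conventions match the tool's reporting style: total cost is the sum of
per-pixel acquisition costs (USD/ha times pixel area); the average cost
per hectare is total cost divided by restored hectares, display-rounded
to the nearest $10 with round-half-to-even; internal values stay at full
float64 precision.  Risk improvements are reported in percentage points
of extinction risk, at the configured SAR exponent and across the
sensitivity sweep z in {0.1, 0.25, 0.4}.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .benefit import AvailableArea
from .geodata import ContinuousSurface, Grid, pixel_area_ha, pixel_area_km2
from .species import Z_SWEEP, SpeciesProfile, SpeciesState, extinction_risk

if TYPE_CHECKING:  # pragma: no cover
    from .optimizer import ScenarioConfig, Selection

logger = logging.getLogger(__name__)


def round_to_ten(value: float) -> int:
    """Display rounding to the nearest $10 (round-half-to-even at ties)."""
    return int(round(value / 10.0)) * 10


def cost_summary(
    selection: "Selection", cost: ContinuousSurface, grid: Grid
) -> tuple[float, float]:
    """(total USD, average USD/ha) over the chosen pixels.

    ``cost`` must be in USD/ha.  An empty selection yields zeros with a
    warning rather than an error.
    """
    chosen_flat = selection.flat_indices[selection.chosen]
    if chosen_flat.size == 0:
        logger.warning("cost summary of an empty selection")
        return 0.0, 0.0
    area_ha = pixel_area_ha(grid)
    per_ha = cost.values.ravel()[chosen_flat]
    total = float(per_ha.sum() * area_ha)
    avg = total / (chosen_flat.size * area_ha)
    return total, avg


def habitat_area_summary(
    selection: "Selection", available: AvailableArea
) -> dict[int, float]:
    """Restored area per habitat class in km^2 (pixel counts times area)."""
    area_km2 = pixel_area_km2(available.grid)
    chosen_flat = selection.flat_indices[selection.chosen]
    codes = available.surface.codes.ravel()[chosen_flat]
    return {
        int(c): float((codes == c).sum() * area_km2)
        for c in np.unique(available.surface.codes[available.mask])
    }


def risk_improvement_summary(
    profiles: list[SpeciesProfile],
    states_before: dict[str, SpeciesState],
    states_after: dict[str, SpeciesState],
    z_values: tuple[float, ...] = Z_SWEEP,
) -> pd.DataFrame:
    """Per-species extinction-risk improvement across the z sweep.

    Returns one row per (species, z) with risk before/after and the
    reduction in percentage points; a species with no restored pixels
    reports 0.
    """
    rows = []
    for p in profiles:
        before, after = states_before[p.name], states_after[p.name]
        for z in z_values:
            r0 = extinction_risk(before, z)
            r1 = extinction_risk(after, z)
            rows.append(
                {
                    "species": p.name,
                    "z": z,
                    "risk_before": r0,
                    "risk_after": r1,
                    "risk_reduction_pct": (r0 - r1) * 100.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ScenarioReport:
    """Machine-readable summary of one scenario run."""

    total_cost: float
    average_cost_per_ha: float
    average_cost_per_ha_display: int
    area_by_habitat_km2: dict[int, float]
    risk_table: pd.DataFrame
    config_echo: dict
    n_selected: int

    def summary_dict(self) -> dict:
        return {
            "total_cost_usd": self.total_cost,
            "average_cost_per_ha_usd": self.average_cost_per_ha,
            "average_cost_per_ha_usd_display": self.average_cost_per_ha_display,
            "area_by_habitat_km2": {str(k): v for k, v in self.area_by_habitat_km2.items()},
            "n_selected_pixels": self.n_selected,
            "config": self.config_echo,
        }

    def write(self, directory: str | Path, stem: str = "scenario") -> list[Path]:
        """Write the JSON summary and the per-species risk CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        json_path = directory / f"{stem}_summary.json"
        csv_path = directory / f"{stem}_species_risk.csv"
        with open(json_path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
        self.risk_table.to_csv(csv_path, index=False)
        return [json_path, csv_path]


def _config_echo(config: "ScenarioConfig") -> dict:
    echo = dataclasses.asdict(config)
    echo["dispersal_mode"] = config.dispersal_mode.value
    echo["restorable_landcover_codes"] = sorted(config.restorable_landcover_codes)
    return echo


def build_scenario_report(
    selection: "Selection",
    cost: ContinuousSurface,
    available: AvailableArea,
    profiles: list[SpeciesProfile],
    states_before: dict[str, SpeciesState],
    states_after: dict[str, SpeciesState],
    config: "ScenarioConfig",
) -> ScenarioReport:
    z_values = tuple(sorted({config.z, *Z_SWEEP}))
    total, avg = cost_summary(selection, cost, available.grid)
    return ScenarioReport(
        total_cost=total,
        average_cost_per_ha=avg,
        average_cost_per_ha_display=round_to_ten(avg),
        area_by_habitat_km2=habitat_area_summary(selection, available),
        risk_table=risk_improvement_summary(profiles, states_before, states_after, z_values),
        config_echo=_config_echo(config),
        n_selected=selection.count,
    )
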
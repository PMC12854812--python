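"""Per-pixel restoration-benefit surfaces.

For species j and pixel i the benefit is

    b_ij = c_ij * w_ij * (r0_j - r1_j)

where r0 - r1 is the SAR risk reduction from restoring one pixel of
preferred habitat (spatially constant within an iteration, since every
candidate pixel adds the same area), c_ij is an optional climate
suitability weight in [0, 1], and w_ij a dispersal weight determined by
whether the pixel lies within the species' dispersal buffer around its
current range.  b_ij is zero outside the triple intersection of the
historical range, the preferred habitat classes, and the available
(restorable) area.  The total benefit B_xi is the (optionally weighted)
sum of b_ij across species.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .geodata import (
    CategoricalSurface,
    ContinuousSurface,
    Grid,
    GridAlignmentError,
    buffer_range,
    pixel_area_km2,
    rasterize_range,
)
from .species import SpeciesProfile, SpeciesState, risk_reduction

logger = logging.getLogger(__name__)

#: tolerated numeric excursion of suitability values outside [0, 1]
_SUITABILITY_EPS = 1e-6


class DispersalMode(enum.Enum):
    """Benefit weight given to eligible pixels beyond the dispersal buffer.

    Pixels inside the buffer (current range expanded by the dispersal
    distance) always weigh 1.
    """

    NONE = "none"  # distance ignored: weight 1 everywhere
    INTERMEDIATE = "intermediate"  # outside-buffer weight 0.5
    NATURAL = "natural"  # outside-buffer weight 0

    @property
    def outside_weight(self) -> float:
        return {"none": 1.0, "intermediate": 0.5, "natural": 0.0}[self.value]


@dataclass
class AvailableArea:
    """Habitat codes on restorable land; nodata everywhere else."""

    surface: CategoricalSurface
    restorable_landcover_codes: frozenset[int] = frozenset({81, 82})

    @property
    def grid(self) -> Grid:
        return self.surface.grid

    @property
    def mask(self) -> np.ndarray:
        return self.surface.valid_mask


@dataclass
class SpeciesBenefitSurface:
    species: str
    surface: ContinuousSurface


@dataclass
class TotalBenefitSurface:
    surface: ContinuousSurface


def compute_available_area(
    habitat: CategoricalSurface,
    landcover: CategoricalSurface,
    restorable_codes: set[int] = frozenset({81, 82}),
) -> AvailableArea:
    """Mask the historical habitat map to restorable land-cover cells.

    A cell keeps its habitat class code iff its current land cover is one
    of the restorable classes (cropland/pasture by default, NLCD 81/82)
    and the habitat map has a class there; all other cells become nodata.
    """
    if habitat.grid != landcover.grid:
        raise GridAlignmentError("habitat and land-cover maps must share one grid")
    keep = habitat.valid_mask & np.isin(landcover.codes, list(restorable_codes))
    codes = np.where(keep, habitat.codes, habitat.grid.nodata_code)
    if not keep.any():
        logger.warning("no restorable cells: available area is empty")
    return AvailableArea(
        surface=CategoricalSurface(grid=habitat.grid, codes=codes),
        restorable_landcover_codes=frozenset(restorable_codes),
    )


def dispersal_weight_surface(
    profile: SpeciesProfile, mode: DispersalMode, grid: Grid
) -> ContinuousSurface:
    """Weight raster: 1 inside the dispersal buffer, mode-dependent outside.

    In the distance-blind mode the buffer is not even computed; the weight
    is uniformly 1.
    """
    if mode is DispersalMode.NONE:
        return ContinuousSurface(grid=grid, values=np.ones(grid.shape), units="")
    buffered = buffer_range(profile.current_range, profile.dispersal_km)
    inside = rasterize_range(buffered, grid).codes == 1
    values = np.where(inside, 1.0, mode.outside_weight)
    return ContinuousSurface(grid=grid, values=values, units="")


def species_benefit_surface(
    profile: SpeciesProfile,
    state: SpeciesState,
    available: AvailableArea,
    weights: ContinuousSurface,
    suitability: ContinuousSurface | None = None,
) -> SpeciesBenefitSurface:
    """Benefit raster b_ij for one species at its current SAR state.

    Eligibility (historical range ∩ preferred habitat ∩ available area) is
    applied first; eligible cells get suitability x dispersal weight x the
    per-pixel risk reduction, which is one number per species per
    iteration.  Suitability outside [0, 1] beyond numeric noise is an
    error; noise-level excursions are clamped.
    """
    grid = available.grid
    if weights.grid != grid or (suitability is not None and suitability.grid != grid):
        raise GridAlignmentError("benefit inputs must share the available-area grid")
    if suitability is None:
        suit = np.ones(grid.shape)
    else:
        suit = suitability.values.copy()
        finite = ~np.isnan(suit)
        if np.any((suit[finite] < -_SUITABILITY_EPS) | (suit[finite] > 1 + _SUITABILITY_EPS)):
            raise ValueError(
                f"{profile.name}: suitability values outside [0, 1]"
            )
        np.clip(suit, 0.0, 1.0, out=suit)

    historical = rasterize_range(profile.historical_range, grid).codes == 1
    preferred = np.isin(available.surface.codes, list(profile.preferred_habitat_codes))
    eligible = historical & preferred & available.mask

    delta = risk_reduction(state, pixel_area_km2(grid), profile.z)
    values = np.where(eligible, suit * weights.values * delta, 0.0)
    return SpeciesBenefitSurface(
        species=profile.name,
        surface=ContinuousSurface(grid=grid, values=values, units="risk reduction"),
    )


def aggregate_benefit(
    surfaces: list[SpeciesBenefitSurface],
    weights: dict[str, float] | None = None,
) -> TotalBenefitSurface:
    """Cell-wise weighted sum across species: B_xi = sum_j w_j * b_ij."""
    if not surfaces:
        raise ValueError("at least one species benefit surface is required")
    grid = surfaces[0].surface.grid
    total = np.zeros(grid.shape)
    for sbs in surfaces:
        if sbs.surface.grid != grid:
            raise GridAlignmentError("benefit surfaces must share one grid")
        w = 1.0 if weights is None else weights.get(sbs.species, 1.0)
        total += w * sbs.surface.values
    return TotalBenefitSurface(
        surface=ContinuousSurface(grid=grid, values=total, units="risk reduction")
    )
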
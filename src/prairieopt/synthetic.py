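"""Seeded synthetic input bundles for testing and demonstration.

The generator emulates the structure of the real inputs the pipeline was
designed around — a banded mosaic of prairie community types (the
west-to-east shortgrass/mixed/tallgrass gradient), a cropland/pasture
land-cover mask, a spatially autocorrelated lognormal land-value surface
stored in ln USD/ha, nested current-within-historical species ranges
built from blob unions, and smooth [0, 1] climate-suitability fields.
It makes no claim of statistical realism beyond those structural
features.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning, so identical seeds give
bit-identical bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from shapely.geometry import Point, box

from .geodata import (
    CategoricalSurface,
    ContinuousSurface,
    Grid,
    LandscapeBundle,
    RangeGeometry,
)
from .species import SpeciesProfile

logger = logging.getLogger(__name__)

RESTORABLE_CODES = (81, 82)  # cropland / pasture
NONRESTORABLE_CODE = 71  # herbaceous, not a restoration candidate


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic landscape + species set.

    Defaults describe the study conditions the tool targets: three
    prairie community types in longitudinal bands, roughly a third of the
    landscape in restorable cropland/pasture, lognormal land values
    centered near $2,500/ha, five indicator species that each retain
    about half of their historical range, and dispersal distances
    spanning sedentary to wide-ranging taxa.
    """

    seed: int = 0
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 960.0
    n_habitat_classes: int = 3
    habitat_patch_scale: float = 10.0  # cells; tessellation seed-point density scale
    restorable_fraction: float = 0.35
    cost_log_mean: float = float(np.log(2500.0))  # ln USD/ha
    cost_log_sd: float = 0.5
    cost_autocorr_scale: float = 6.0  # cells
    n_species: int = 5
    species_area_ratio: float = 0.5  # current / historical range area
    species_n_blobs: int = 3
    species_blob_radius_cells: float = 22.0
    dispersal_km: tuple[float, ...] = (3.0, 8.0, 15.0, 30.0, 5.0)
    suitability_smoothness: float = 12.0  # cells
    habitat_layout: str = "banded"  # or "random"

    def __post_init__(self) -> None:
        if not 2 <= self.n_habitat_classes <= 4:
            raise ValueError("n_habitat_classes must be in 2..4")
        if not 0.0 < self.restorable_fraction < 1.0:
            raise ValueError("restorable_fraction must lie in (0, 1)")
        if not 0.0 < self.species_area_ratio <= 1.0:
            raise ValueError("species_area_ratio must lie in (0, 1]")
        for name in ("habitat_patch_scale", "cost_autocorr_scale", "suitability_smoothness",
                     "species_blob_radius_cells", "cell_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.habitat_layout not in ("banded", "random"):
            raise ValueError(f"unknown habitat_layout {self.habitat_layout!r}")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized (mean 0, sd 1) smoothed Gaussian noise field."""
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=sigma, mode="reflect")
    return (smooth - smooth.mean()) / smooth.std()


def _habitat_surface(rng: np.random.Generator, spec: SyntheticSpec, grid: Grid) -> CategoricalSurface:
    """Nearest-seed-point tessellation; classes in longitudinal bands by default."""
    n_seeds = max(spec.n_habitat_classes * 4,
                  int(spec.n_rows * spec.n_cols / spec.habitat_patch_scale**2))
    pts = rng.uniform(0, 1, size=(n_seeds, 2)) * [spec.n_rows, spec.n_cols]
    if spec.habitat_layout == "banded":
        # class follows the seed point's longitudinal band (wiggly bands)
        band_width = spec.n_cols / spec.n_habitat_classes
        classes = np.minimum((pts[:, 1] // band_width).astype(int), spec.n_habitat_classes - 1)
    else:
        classes = rng.integers(0, spec.n_habitat_classes, size=n_seeds)
    rows, cols = np.mgrid[0 : spec.n_rows, 0 : spec.n_cols]
    cells = np.column_stack([rows.ravel() + 0.5, cols.ravel() + 0.5])
    _, nearest = cKDTree(pts).query(cells)
    codes = (classes[nearest] + 1).reshape(grid.shape).astype(np.int64)
    return CategoricalSurface(grid=grid, codes=codes)


def _landcover_surface(rng: np.random.Generator, spec: SyntheticSpec, grid: Grid) -> CategoricalSurface:
    field_ = _smooth_field(rng, grid.shape, spec.habitat_patch_scale / 2)
    cut = np.quantile(field_, 1.0 - spec.restorable_fraction)
    restorable = field_ > cut
    codes = np.full(grid.shape, NONRESTORABLE_CODE, dtype=np.int64)
    codes[restorable] = rng.choice(RESTORABLE_CODES, size=int(restorable.sum()))
    return CategoricalSurface(grid=grid, codes=codes)


def _cost_surface(rng: np.random.Generator, spec: SyntheticSpec, grid: Grid) -> ContinuousSurface:
    field_ = _smooth_field(rng, grid.shape, spec.cost_autocorr_scale)
    values = spec.cost_log_mean + spec.cost_log_sd * field_
    return ContinuousSurface(grid=grid, values=values, units="ln USD/ha")


def _blob_union(rng: np.random.Generator, spec: SyntheticSpec, grid: Grid,
                center_cols: tuple[float, float]) -> shapely.Geometry:
    """Union of random disks, centers biased to a longitudinal column band."""
    width = grid.n_cols * grid.cell_size
    height = grid.n_rows * grid.cell_size
    blobs = []
    for _ in range(spec.species_n_blobs):
        cx = rng.uniform(center_cols[0], center_cols[1]) * grid.cell_size
        cy = rng.uniform(0.15, 0.85) * height
        r = rng.uniform(0.6, 1.4) * spec.species_blob_radius_cells * grid.cell_size
        blobs.append(Point(cx, cy).buffer(r, quad_segs=16))
    geom = shapely.union_all(blobs)
    return geom.intersection(box(0, 0, width, height))


def _erode_to_ratio(geom: shapely.Geometry, ratio: float) -> shapely.Geometry:
    """Negative-buffer the geometry until area/original-area hits ``ratio``."""
    if ratio >= 1.0:
        return geom
    target = geom.area * ratio
    lo, hi = 0.0, float(np.sqrt(geom.area))  # erosion by sqrt(area) always empties a blob set
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        area = geom.buffer(-mid).area
        if area > target:
            lo = mid
        else:
            hi = mid
    eroded = geom.buffer(-lo)
    if eroded.is_empty:  # pathological shapes: fall back to the last non-empty erosion
        eroded = geom.buffer(-lo * 0.5)
    return eroded


def _species_profiles(
    seeds: list[np.random.SeedSequence],
    spec: SyntheticSpec,
    grid: Grid,
    habitat: CategoricalSurface,
    available_mask: np.ndarray,
    available_codes: np.ndarray,
) -> list[SpeciesProfile]:
    from .geodata import rasterize_range  # local: avoids cluttering module top

    profiles = []
    classes = list(range(1, spec.n_habitat_classes + 1))
    band_width = grid.n_cols / spec.n_habitat_classes
    for j in range(spec.n_species):
        # one or two preferred classes, cycling across species
        first = classes[j % len(classes)]
        second = classes[(j + 1) % len(classes)]
        preferred = frozenset({first} if j % 2 == 0 else {first, second})
        # bias range blobs toward the bands of the preferred classes
        bands = sorted(c - 1 for c in preferred)
        col_lo = bands[0] * band_width
        col_hi = (bands[-1] + 1) * band_width
        dispersal = spec.dispersal_km[j % len(spec.dispersal_km)]
        for attempt, sub in enumerate(seeds[j].spawn(10)):
            rng = np.random.default_rng(sub)
            historical = _blob_union(rng, spec, grid, (col_lo, col_hi))
            if historical.is_empty:
                continue
            hist_mask = rasterize_range(RangeGeometry(historical, "historical"), grid).codes == 1
            eligible = hist_mask & available_mask & np.isin(available_codes, list(preferred))
            if not eligible.any():
                continue
            current = _erode_to_ratio(historical, spec.species_area_ratio)
            if current.is_empty:
                continue
            profiles.append(
                SpeciesProfile(
                    name=f"species_{j + 1}",
                    preferred_habitat_codes=preferred,
                    dispersal_km=dispersal,
                    current_range=RangeGeometry(current, "current"),
                    historical_range=RangeGeometry(historical, "historical"),
                )
            )
            break
        else:
            raise RuntimeError(
                f"species_{j + 1}: no eligible habitat after 10 regeneration attempts"
            )
    return profiles


def generate_bundle(spec: SyntheticSpec) -> tuple[LandscapeBundle, list[SpeciesProfile]]:
    """Generate a complete co-registered input bundle plus species profiles.

    The cost layer is emitted in ln USD/ha (exercising the exp transform
    downstream); suitability surfaces are generated for every species and
    used only when a scenario turns climate weighting on.
    """
    grid = Grid(
        n_rows=spec.n_rows,
        n_cols=spec.n_cols,
        origin_x=0.0,
        origin_y=0.0,
        cell_size=spec.cell_size,
    )
    root = np.random.SeedSequence(spec.seed)
    s_habitat, s_landcover, s_cost, s_species, s_suit = root.spawn(5)

    habitat = _habitat_surface(np.random.default_rng(s_habitat), spec, grid)
    landcover = _landcover_surface(np.random.default_rng(s_landcover), spec, grid)
    cost = _cost_surface(np.random.default_rng(s_cost), spec, grid)

    restorable = np.isin(landcover.codes, RESTORABLE_CODES)
    if not restorable.any():
        raise ValueError("restorable fraction produced no restorable cells")
    available_mask = restorable & habitat.valid_mask
    profiles = _species_profiles(
        s_species.spawn(spec.n_species), spec, grid, habitat, available_mask, habitat.codes
    )
    suit_rng = np.random.default_rng(s_suit)
    suitability = {}
    for p in profiles:
        field_ = _smooth_field(suit_rng, grid.shape, spec.suitability_smoothness)
        lo, hi = field_.min(), field_.max()
        suitability[p.name] = ContinuousSurface(
            grid=grid, values=(field_ - lo) / (hi - lo), units="suitability"
        )
    bundle = LandscapeBundle(
        habitat=habitat, landcover=landcover, cost=cost, suitability=suitability
    )
    return bundle, profiles


def generate_worked_example() -> tuple[LandscapeBundle, list[SpeciesProfile]]:
    """A fixed 6x6, 3-habitat, 2-species bundle with integer costs.

    Layout (row 0 is the north edge; cell size 1,000 m, so each pixel is
    100 ha = 1 km^2):

    * habitat: three vertical bands of two columns each — code 1
      (columns 0-1), code 2 (columns 2-3), code 3 (columns 4-5);
    * land cover: cropland (81) everywhere except four non-restorable
      cells (71) at (row, col) = (5, 0), (5, 1), (0, 3), (0, 4), leaving
      32 available pixels;
    * cost (USD/ha): 1000 + 100 * (6 * row + col), i.e. 1000 in the
      north-west corner rising by 100 in reading order to 4500;
    * species east: prefers habitat {1, 2}, dispersal 2 km, historical
      range x in [0, 4000] (24 km^2), current range x in [0, 2000],
      y in [2000, 6000] (8 km^2);
    * species west: prefers habitat {3}, dispersal 1 km, historical
      range x in [3000, 6000] (18 km^2), current range x in [4000,
      6000], y in [0, 2000] (4 km^2).
    """
    grid = Grid(n_rows=6, n_cols=6, origin_x=0.0, origin_y=0.0, cell_size=1000.0)
    habitat = CategoricalSurface(
        grid=grid, codes=np.repeat([[1, 1, 2, 2, 3, 3]], 6, axis=0).astype(np.int64)
    )
    landcover_codes = np.full((6, 6), 81, dtype=np.int64)
    for r, c in [(5, 0), (5, 1), (0, 3), (0, 4)]:
        landcover_codes[r, c] = NONRESTORABLE_CODE
    landcover = CategoricalSurface(grid=grid, codes=landcover_codes)
    cost_values = 1000.0 + 100.0 * (6 * np.arange(6)[:, None] + np.arange(6)[None, :])
    cost = ContinuousSurface(grid=grid, values=cost_values, units="USD/ha")

    sp_a = SpeciesProfile(
        name="grassland_a",
        preferred_habitat_codes=frozenset({1, 2}),
        dispersal_km=2.0,
        current_range=RangeGeometry(box(0, 2000, 2000, 6000), "current"),
        historical_range=RangeGeometry(box(0, 0, 4000, 6000), "historical"),
    )
    sp_b = SpeciesProfile(
        name="grassland_b",
        preferred_habitat_codes=frozenset({3}),
        dispersal_km=1.0,
        current_range=RangeGeometry(box(4000, 0, 6000, 2000), "current"),
        historical_range=RangeGeometry(box(3000, 0, 6000, 6000), "historical"),
    )
    bundle = LandscapeBundle(habitat=habitat, landcover=landcover, cost=cost, suitability={})
    return bundle, [sp_a, sp_b]
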
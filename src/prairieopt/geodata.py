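"""Grid and vector data model shared by every stage of the pipeline.

All analysis happens on a single projected equal-area grid (square cells,
meters).  Rasters are read and written as single-band ESRI ASCII grids
(``.asc``) with an optional ``.prj`` sidecar holding the CRS identifier;
vectors are GeoJSON (multi)polygons handled through shapely.  Geographic
(lat/lon) inputs are rejected rather than silently reprojected, so pixel
area is a constant of the grid.

Nodata conventions: categorical surfaces use the grid's integer sentinel
(``nodata_code``); continuous surfaces use NaN in memory and the sentinel
on disk.  A pixel missing in any one layer of a bundle is excluded from
the analyzable set of the whole bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

DEFAULT_CRS = "EPSG:5070"  # NAD83 / Conus Albers, equal-area
DEFAULT_NODATA = -9999

#: CRS identifiers (or WKT tokens) recognised as geographic and refused.
_GEOGRAPHIC_MARKERS = ("EPSG:4326", "EPSG:4269", "EPSG:4267", "GEOGCS", "longlat")


class RasterFormatError(ValueError):
    """Raised when a raster file violates the expected single-band format."""


class GridAlignmentError(ValueError):
    """Raised when surfaces that must share a grid do not."""


def _check_projected(crs_id: str) -> None:
    up = crs_id.upper()
    for marker in _GEOGRAPHIC_MARKERS:
        if marker.upper() in up:
            raise ValueError(
                f"geographic CRS {crs_id!r} is not supported; supply data in a "
                "projected equal-area CRS (e.g. EPSG:5070)"
            )


@dataclass(frozen=True)
class Grid:
    """Geometry of a regular raster: shape, lower-left origin, square cell size."""

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    cell_size: float
    crs_id: str = DEFAULT_CRS
    nodata_code: int = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        _check_projected(self.crs_id)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates as 2-D arrays; row 0 is the top row."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)


def pixel_area_ha(grid: Grid) -> float:
    """Area of one pixel in hectares (cell_size squared over 10^4)."""
    return grid.cell_size**2 / 1.0e4


def pixel_area_km2(grid: Grid) -> float:
    """Area of one pixel in square kilometers."""
    return grid.cell_size**2 / 1.0e6


@dataclass
class CategoricalSurface:
    """Integer class codes on a grid (habitat community or land-cover classes)."""

    grid: Grid
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if not np.issubdtype(codes.dtype, np.integer):
            raise RasterFormatError("categorical surface requires integer codes")
        if codes.shape != self.grid.shape:
            raise GridAlignmentError(
                f"codes shape {codes.shape} != grid shape {self.grid.shape}"
            )
        self.codes = codes.astype(np.int64, copy=False)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != self.grid.nodata_code

    def classes(self) -> list[int]:
        """Sorted distinct non-nodata codes present on the surface."""
        return sorted(int(c) for c in np.unique(self.codes[self.valid_mask]))


@dataclass
class ContinuousSurface:
    """Real values on a grid; NaN marks nodata.  ``units`` is free text."""

    grid: Grid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != self.grid.shape:
            raise GridAlignmentError(
                f"values shape {values.shape} != grid shape {self.grid.shape}"
            )
        self.values = values

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class RangeGeometry:
    """A species range as a planar (multi)polygon in the analysis CRS.

    ``role`` records whether this is the species' current or historical
    range.  Invalid geometries are repaired on construction.
    """

    geometry: BaseGeometry
    role: str = "current"

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise ValueError("range geometry must be non-empty")
        if self.role not in ("current", "historical"):
            raise ValueError(f"unknown range role {self.role!r}")
        if not self.geometry.is_valid:
            self.geometry = make_valid(self.geometry)

    @property
    def area_km2(self) -> float:
        return self.geometry.area / 1.0e6


# ---------------------------------------------------------------------------
# ASCII-grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _prj_path(path: Path) -> Path:
    return path.with_suffix(".prj")


def _read_asc(path: str | Path) -> tuple[Grid, np.ndarray, float]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _HEADER_KEYS + ("nodata_value",):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise RasterFormatError(f"{path}: missing header keys {missing}")
    nodata = header.get("nodata_value", float(DEFAULT_NODATA))
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    try:
        values = np.loadtxt(data_lines, dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: unparseable band data: {exc}") from exc
    if values.shape != (n_rows, n_cols):
        values = values.reshape(n_rows, n_cols)
    crs_id = DEFAULT_CRS
    prj = _prj_path(path)
    if prj.exists():
        crs_id = prj.read_text().strip()
    grid = Grid(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        crs_id=crs_id,
        nodata_code=int(nodata) if float(nodata).is_integer() else DEFAULT_NODATA,
    )
    return grid, values, nodata


def read_categorical(path: str | Path) -> CategoricalSurface:
    """Read a single-band integer raster.  Non-integer values are a format error."""
    grid, values, nodata = _read_asc(path)
    valid = values != nodata
    if not np.all(np.isfinite(values[valid])) or np.any(values[valid] != np.floor(values[valid])):
        raise RasterFormatError(f"{path}: non-integer values in a categorical band")
    codes = np.where(valid, values, grid.nodata_code).astype(np.int64)
    return CategoricalSurface(grid=grid, codes=codes)


def read_continuous(path: str | Path, units: str = "") -> ContinuousSurface:
    """Read a single-band real raster; the nodata sentinel becomes NaN."""
    grid, values, nodata = _read_asc(path)
    values = np.where(values == nodata, np.nan, values)
    surface = ContinuousSurface(grid=grid, values=values, units=units)
    if not surface.valid_mask.any():
        logger.warning("%s: raster has no analyzable (non-nodata) cells", path)
    return surface


def write_surface(surface: CategoricalSurface | ContinuousSurface, path: str | Path) -> None:
    """Write a surface as an ESRI ASCII grid plus a ``.prj`` CRS sidecar.

    Continuous values are written with 17 significant digits so a
    read-back reproduces the float64 payload bit-for-bit.
    """
    path = Path(path)
    grid = surface.grid
    if isinstance(surface, CategoricalSurface):
        body = surface.codes
        fmt = "%d"
        nodata: float | int = grid.nodata_code
    else:
        nodata = float(grid.nodata_code)
        body = np.where(np.isnan(surface.values), nodata, surface.values)
        fmt = "%.17g"
    with open(path, "w") as fh:
        fh.write(
            f"ncols {grid.n_cols}\nnrows {grid.n_rows}\n"
            f"xllcorner {grid.origin_x!r}\nyllcorner {grid.origin_y!r}\n"
            f"cellsize {grid.cell_size!r}\nNODATA_value {nodata}\n"
        )
        np.savetxt(fh, body, fmt=fmt)
    _prj_path(path).write_text(grid.crs_id + "\n")


def read_range(path: str | Path, role: str = "current") -> RangeGeometry:
    """Read a GeoJSON (multi)polygon as a range geometry."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in doc["features"]]
        geometry = shapely.union_all(geoms)
    elif doc.get("type") == "Feature":
        geometry = shape(doc["geometry"])
    else:
        geometry = shape(doc)
    return RangeGeometry(geometry=geometry, role=role)


def write_range(rng: RangeGeometry, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"type": "Feature", "properties": {"role": rng.role}, "geometry": mapping(rng.geometry)},
            fh,
        )


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def exp_transform_cost(cost_ln: ContinuousSurface) -> ContinuousSurface:
    """Convert a land-value layer from ln USD/ha to USD/ha (cell-wise exp)."""
    return ContinuousSurface(
        grid=cost_ln.grid, values=np.exp(cost_ln.values), units="USD/ha"
    )


def _block_slices(n: int, factor: int) -> list[slice]:
    # trailing partial blocks aggregate over whatever cells exist
    return [slice(i, min(i + factor, n)) for i in range(0, n, factor)]


def coarsen(
    surface: CategoricalSurface | ContinuousSurface, factor: int
) -> CategoricalSurface | ContinuousSurface:
    """Aggregate to a coarser resolution by an integer factor.

    Continuous cells take the mean of non-nodata fine cells in the block;
    categorical cells take the modal code, ties broken toward the lowest
    code.  An all-nodata block stays nodata.  Trailing partial blocks (a
    non-divisible factor) aggregate over the cells that exist.
    """
    if factor < 2:
        raise ValueError("coarsening factor must be >= 2")
    grid = surface.grid
    row_blocks = _block_slices(grid.n_rows, factor)
    col_blocks = _block_slices(grid.n_cols, factor)
    out_shape = (len(row_blocks), len(col_blocks))
    # origin stays at the lower-left of the ORIGINAL extent only when the
    # factor divides evenly; padded blocks extend the top/right edge, so the
    # lower-left corner is recomputed from the top-left anchor.
    top_y = grid.origin_y + grid.n_rows * grid.cell_size
    new_cell = grid.cell_size * factor
    new_grid = Grid(
        n_rows=out_shape[0],
        n_cols=out_shape[1],
        origin_x=grid.origin_x,
        origin_y=top_y - out_shape[0] * new_cell,
        cell_size=new_cell,
        crs_id=grid.crs_id,
        nodata_code=grid.nodata_code,
    )
    if isinstance(surface, ContinuousSurface):
        out = np.full(out_shape, np.nan)
        for i, rs in enumerate(row_blocks):
            for j, cs in enumerate(col_blocks):
                block = surface.values[rs, cs]
                good = ~np.isnan(block)
                if good.any():
                    out[i, j] = block[good].mean()
        return ContinuousSurface(grid=new_grid, values=out, units=surface.units)
    out = np.full(out_shape, grid.nodata_code, dtype=np.int64)
    for i, rs in enumerate(row_blocks):
        for j, cs in enumerate(col_blocks):
            block = surface.codes[rs, cs]
            block = block[block != grid.nodata_code]
            if block.size:
                codes, counts = np.unique(block, return_counts=True)
                out[i, j] = codes[counts == counts.max()].min()
    return CategoricalSurface(grid=new_grid, codes=out)


def rasterize_range(rng: RangeGeometry, grid: Grid) -> CategoricalSurface:
    """Binary 0/1 raster of a range polygon under the cell-center rule."""
    if rng.geometry.is_empty:
        raise ValueError("cannot rasterize an empty geometry")
    x, y = grid.cell_centers()
    shapely.prepare(rng.geometry)
    inside = shapely.contains_xy(rng.geometry, x.ravel(), y.ravel())
    codes = inside.reshape(grid.shape).astype(np.int64)
    return CategoricalSurface(grid=grid, codes=codes)


def buffer_range(rng: RangeGeometry, distance_km: float) -> RangeGeometry:
    """Euclidean buffer of a range by a dispersal distance in kilometers."""
    if distance_km < 0:
        raise ValueError("buffer distance must be non-negative")
    if distance_km == 0:
        return rng
    return RangeGeometry(
        geometry=rng.geometry.buffer(distance_km * 1000.0, quad_segs=32), role=rng.role
    )


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class LandscapeBundle:
    """Co-registered analysis layers: habitat, land cover, cost, suitability.

    ``cost`` must be in USD/ha (apply :func:`exp_transform_cost` first when
    the source is ln USD/ha).  ``suitability`` maps species name to a [0,1]
    surface; species without an entry get uniform suitability 1.
    """

    habitat: CategoricalSurface
    landcover: CategoricalSurface
    cost: ContinuousSurface
    suitability: dict[str, ContinuousSurface] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = [self.habitat.grid, self.landcover.grid, self.cost.grid]
        grids += [s.grid for s in self.suitability.values()]
        for g in grids[1:]:
            if g != grids[0]:
                raise GridAlignmentError("all bundle layers must share one grid")

    @property
    def grid(self) -> Grid:
        return self.habitat.grid

    def analyzable_mask(self) -> np.ndarray:
        """Cells valid in every layer (intersection-of-valid rule)."""
        mask = self.habitat.valid_mask & self.landcover.valid_mask & self.cost.valid_mask
        for s in self.suitability.values():
            mask &= s.valid_mask
        return mask
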
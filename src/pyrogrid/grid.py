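"""Analysis lattice, point-to-cell fire aggregation, and raster utilities.

The analysis runs on a regular longitude/latitude lattice (1 degree by
default, spanning western and boreal North America).  Point fire records are
summed into cell-year totals of annual area burned (AAB), a small
redistribution filter smears 5% of each cell's AAB into its eight neighbours
to soften boundary artefacts from fires mapped near cell edges, and AAB is
log-transformed before regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

#: Default study domain: 170-52 degrees W, 25-72 degrees N.
DEFAULT_DOMAIN = (-170.0, -52.0, 25.0, 72.0)

SEASONS = {"winter": (0, 1, 2), "spring": (3, 4, 5), "summer": (6, 7, 8)}

# 5% redistribution kernel: focal keeps 95%, each orthogonal neighbour
# receives 1%, each diagonal neighbour 0.25%.
NEIGHBOR_KERNEL = np.array(
    [
        [0.0025, 0.01, 0.0025],
        [0.01, 0.95, 0.01],
        [0.0025, 0.01, 0.0025],
    ]
)


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat lattice with row-major integer cell ids.

    Cells are half-open intervals [west, east) x [south, north); a point on
    an interior boundary belongs to the cell to its northeast.  Cell id
    ``row * n_lon + col`` with row 0 at the southern edge.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = 1.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("degenerate bounds: zero-area domain")
        for span, name in ((self.lon_max - self.lon_min, "lon"),
                           (self.lat_max - self.lat_min, "lat")):
            n = span / self.resolution
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} span is not a multiple of resolution")

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    def cell_of(self, lon, lat):
        """Vectorized (lon, lat) -> cell id; -1 for points outside the domain."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        row = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        inside = (col >= 0) & (col < self.n_lon) & (row >= 0) & (row < self.n_lat)
        out = np.where(inside, row * self.n_lon + col, -1)
        if out.ndim == 0:
            return int(out)
        return out

    def cell_center(self, cell_id):
        """Cell id -> (lon, lat) of the cell centre."""
        cell_id = np.asarray(cell_id)
        row, col = np.divmod(cell_id, self.n_lon)
        lon = self.lon_min + (col + 0.5) * self.resolution
        lat = self.lat_min + (row + 0.5) * self.resolution
        return lon, lat

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """Cell id -> (west, east, south, north)."""
        row, col = divmod(int(cell_id), self.n_lon)
        west = self.lon_min + col * self.resolution
        south = self.lat_min + row * self.resolution
        return west, west + self.resolution, south, south + self.resolution

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.resolution


def make_grid(bounds: tuple[float, float, float, float] = DEFAULT_DOMAIN,
              resolution: float = 1.0) -> GridSpec:
    """Build the analysis lattice from (lon_min, lon_max, lat_min, lat_max)."""
    lon_min, lon_max, lat_min, lat_max = bounds
    return GridSpec(lon_min, lon_max, lat_min, lat_max, resolution)


@dataclass
class AnnualField:
    """One value per (cell, year) of a named variable; NaN marks missing.

    ``values`` has shape (n_cells, n_years), row index = cell id.
    """

    grid: GridSpec
    years: np.ndarray
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cells, len(self.years)):
            raise ValueError("values must be (n_cells, n_years)")

    def year_index(self, year: int) -> int:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in field")
        return int(idx[0])

    def series(self, cell_id: int) -> np.ndarray:
        return self.values[cell_id]

    def as_raster(self, year: int) -> np.ndarray:
        """(n_lat, n_lon) array for one year, row 0 at the southern edge."""
        return self.values[:, self.year_index(year)].reshape(
            self.grid.n_lat, self.grid.n_lon
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with columns cell_id, year, value."""
        cells = np.repeat(np.arange(self.grid.n_cells), len(self.years))
        years = np.tile(self.years, self.grid.n_cells)
        return pd.DataFrame(
            {"cell_id": cells, "year": years, "value": self.values.ravel()}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, grid: GridSpec,
                   name: str = "", units: str = "") -> "AnnualField":
        years = np.sort(frame["year"].unique())
        values = np.full((grid.n_cells, len(years)), np.nan)
        yi = {y: i for i, y in enumerate(years)}
        for cid, yr, val in frame[["cell_id", "year", "value"]].itertuples(index=False):
            values[int(cid), yi[int(yr)]] = val
        return cls(grid, years, values, name=name, units=units)

    def copy_with(self, values: np.ndarray, name: str | None = None,
                  units: str | None = None) -> "AnnualField":
        return AnnualField(
            self.grid, self.years, values,
            name=self.name if name is None else name,
            units=self.units if units is None else units,
        )


@dataclass
class MonthlySeries:
    """Per (cell, year, month) temperature (degC) or precipitation (mm)."""

    grid: GridSpec
    years: np.ndarray
    values: np.ndarray  # (n_cells, n_years, 12)
    variable: str = "temperature"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cells, len(self.years), 12):
            raise ValueError("values must be (n_cells, n_years, 12)")
        if self.variable == "precipitation" and np.nanmin(self.values) < 0:
            raise ValueError("precipitation must be non-negative")


def assign_fires_to_cells(records: pd.DataFrame, grid: GridSpec,
                          years: tuple[int, int],
                          min_area_ha: float = 0.0) -> AnnualField:
    """Sum point fire areas into cell-year AAB totals (hectares).

    ``records`` needs columns lon, lat, year, area_ha.  Out-of-domain or
    out-of-period records are dropped with a warning; negative areas raise.
    Cell-years with no fires are zero, not missing.
    """
    if (records["area_ha"] < 0).any():
        raise ValueError("fire record with negative area")
    y0, y1 = years
    yrs = np.arange(y0, y1 + 1)
    kept = records
    if min_area_ha > 0:
        kept = kept[kept["area_ha"] >= min_area_ha]
    cell = grid.cell_of(kept["lon"].to_numpy(), kept["lat"].to_numpy())
    cell = np.atleast_1d(cell)
    in_dom = cell >= 0
    in_per = kept["year"].to_numpy().astype(int)
    ok_per = (in_per >= y0) & (in_per <= y1)
    n_drop = int((~in_dom).sum() + (in_dom & ~ok_per).sum())
    if n_drop:
        warnings.warn(f"dropped {n_drop} fire records outside domain or period")
    keep = in_dom & ok_per
    values = np.zeros((grid.n_cells, len(yrs)))
    np.add.at(values, (cell[keep], in_per[keep] - y0), kept["area_ha"].to_numpy()[keep])
    return AnnualField(grid, yrs, values, name="AAB", units="ha")


def neighbor_filter(aab: AnnualField) -> AnnualField:
    """Redistribute 5% of each cell's AAB to its eight neighbours, per year.

    Focal cells keep 95%; orthogonal neighbours receive 1% each, diagonal
    0.25% each.  Zero padding at the domain edge: mass leaving the domain is
    dropped, so the filter never increases the total.
    """
    if np.nanmin(aab.values) < 0:
        raise ValueError("neighbor_filter requires a non-negative field")
    out = np.empty_like(aab.values)
    for j in range(len(aab.years)):
        raster = aab.values[:, j].reshape(aab.grid.n_lat, aab.grid.n_lon)
        filled = np.nan_to_num(raster)
        smooth = ndimage.convolve(filled, NEIGHBOR_KERNEL, mode="constant", cval=0.0)
        smooth[np.isnan(raster)] = np.nan
        out[:, j] = smooth.ravel()
    return aab.copy_with(out)


def log_transform_aab(aab: AnnualField, offset: float = 1.0) -> AnnualField:
    """log-AAB = ln(AAB + offset); zero-AAB years map to ln(offset)."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    if np.nanmin(aab.values) < 0:
        raise ValueError("AAB must be non-negative")
    return aab.copy_with(np.log(aab.values + offset), name="logAAB", units=f"ln(ha+{offset:g})")


def inverse_log_transform(values, offset: float = 1.0):
    """Back-transform log-AAB to hectares, floored at zero."""
    return np.maximum(np.exp(np.asarray(values, dtype=float)) - offset, 0.0)


def bilinear_regrid(src_raster: np.ndarray, src_grid: GridSpec,
                    dst_grid: GridSpec) -> np.ndarray:
    """Regrid one (n_lat, n_lon) raster onto another lattice.

    Exactly nested 2x finer sources (e.g. 0.5 -> 1 degree) are block-averaged
    over the 4 covered source cells; anything else is bilinearly interpolated
    at destination cell centres.  Destination cells outside the source domain
    are NaN; no overlap at all raises.
    """
    src_raster = np.asarray(src_raster, dtype=float)
    if src_raster.shape != (src_grid.n_lat, src_grid.n_lon):
        raise ValueError("source raster shape does not match source grid")
    nested = (
        abs(dst_grid.resolution - 2 * src_grid.resolution) < 1e-9
        and abs((dst_grid.lon_min - src_grid.lon_min) / src_grid.resolution % 1) < 1e-9
        and abs((dst_grid.lat_min - src_grid.lat_min) / src_grid.resolution % 1) < 1e-9
    )
    out = np.full((dst_grid.n_lat, dst_grid.n_lon), np.nan)
    if nested:
        col0 = int(round((dst_grid.lon_min - src_grid.lon_min) / src_grid.resolution))
        row0 = int(round((dst_grid.lat_min - src_grid.lat_min) / src_grid.resolution))
        any_overlap = False
        for r in range(dst_grid.n_lat):
            for c in range(dst_grid.n_lon):
                sr, sc = row0 + 2 * r, col0 + 2 * c
                if 0 <= sr and sr + 2 <= src_grid.n_lat and 0 <= sc and sc + 2 <= src_grid.n_lon:
                    out[r, c] = src_raster[sr:sr + 2, sc:sc + 2].mean()
                    any_overlap = True
        if not any_overlap:
            raise ValueError("no overlap between source and destination grids")
        return out
    interp = RegularGridInterpolator(
        (src_grid.lat_centers(), src_grid.lon_centers()),
        src_raster, bounds_error=False, fill_value=np.nan,
    )
    lon, lat = np.meshgrid(dst_grid.lon_centers(), dst_grid.lat_centers())
    out = interp(np.column_stack([lat.ravel(), lon.ravel()])).reshape(out.shape)
    if np.all(np.isnan(out)):
        raise ValueError("no overlap between source and destination grids")
    return out


def seasonal_aggregate(monthly: MonthlySeries) -> dict[str, AnnualField]:
    """Seasonal aggregates: JFM winter, AMJ spring, JAS summer.

    Temperature is averaged over the season's three months, precipitation
    accumulated.  A season with any missing month is missing for that
    cell-year.
    """
    is_temp = monthly.variable.startswith("t")
    out: dict[str, AnnualField] = {}
    for season, months in SEASONS.items():
        block = monthly.values[:, :, list(months)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            agg = np.mean(block, axis=2) if is_temp else np.sum(block, axis=2)
        agg = np.where(np.isnan(block).any(axis=2), np.nan, agg)
        out[season] = AnnualField(
            monthly.grid, monthly.years, agg,
            name=f"{'T' if is_temp else 'P'}_{season}",
            units="degC" if is_temp else "mm",
        )
    return out


def lag_field(field: AnnualField, lag: int = 1) -> AnnualField:
    """Prior-year version of an annual field on the same year axis.

    value(cell, year) = field(cell, year - lag); the first ``lag`` years are
    missing.
    """
    shifted = np.full_like(field.values, np.nan)
    if lag < len(field.years):
        shifted[:, lag:] = field.values[:, : len(field.years) - lag]
    return field.copy_with(shifted, name=f"{field.name}_prev{lag if lag != 1 else ''}")
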
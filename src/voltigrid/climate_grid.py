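"""Gridded daily temperature container, NetCDF/CSV I/O, regridding, extraction.

All temperatures are handled internally in degrees Celsius on regular
latitude/longitude grids (cell centers, WGS84 degrees, ascending axes).
Time is carried as parallel integer ``year`` / ``doy`` (day-of-year,
1-based) vectors rather than datetime objects, which keeps the 365-day
("noleap") model calendar and the proleptic Gregorian calendar on the
same footing without a special-purpose time library.
"""

from __future__ import annotations

import calendar as _pycal
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

VALID_CALENDARS = ("noleap", "gregorian")


def days_in_year(year: int, calendar: str) -> int:
    """Length of a calendar year: always 365 for noleap, 365/366 for Gregorian."""
    if calendar == "noleap":
        return 365
    return 366 if _pycal.isleap(year) else 365


@dataclass
class DailyTemperatureSeries:
    """One cell's daily mean temperature for a single calendar year.

    ``values[i-1]`` is the mean temperature on day ``i`` (1-based day of
    year).  Length is 365 or 366 depending on the calendar.
    """

    year: int
    values: np.ndarray
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) not in (365, 366):
            raise ValueError(
                f"daily series must have 365 or 366 values, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("daily series contains non-finite temperatures")

    @property
    def day_index(self) -> np.ndarray:
        return np.arange(1, len(self.values) + 1)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ClimateGrid:
    """A lat x lon x day cube of daily mean temperature with calendar metadata.

    Attributes
    ----------
    lat, lon : 1-D ascending cell-center coordinates (degrees N / E).
    year, doy : parallel integer time vectors (doy is 1-based).
    tas : (ntime, nlat, nlon) daily mean temperature, degC.
    elevation : optional (nlat, nlon) static elevation, metres.
    calendar : "noleap" or "gregorian".
    provenance : free label ("observed", a member name, or "ensemble").
    """

    lat: np.ndarray
    lon: np.ndarray
    year: np.ndarray
    doy: np.ndarray
    tas: np.ndarray
    elevation: np.ndarray | None = None
    calendar: str = "noleap"
    provenance: str = "observed"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.year = np.asarray(self.year, dtype=int)
        self.doy = np.asarray(self.doy, dtype=int)
        self.tas = np.asarray(self.tas, dtype=float)
        if self.calendar not in VALID_CALENDARS:
            raise ValueError(f"calendar must be one of {VALID_CALENDARS}, got {self.calendar!r}")
        for name, ax in (("lat", self.lat), ("lon", self.lon)):
            if ax.ndim != 1 or len(ax) == 0 or not np.all(np.isfinite(ax)):
                raise ValueError(f"{name} axis must be 1-D, non-empty and finite")
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} axis must be strictly ascending")
        if self.tas.shape != (len(self.year), len(self.lat), len(self.lon)):
            raise ValueError(
                f"tas shape {self.tas.shape} does not match "
                f"(time={len(self.year)}, lat={len(self.lat)}, lon={len(self.lon)})"
            )
        # strictly increasing time: (year, doy) lexicographic
        key = self.year.astype(np.int64) * 1000 + self.doy.astype(np.int64)
        if len(key) > 1 and not np.all(np.diff(key) > 0):
            raise ValueError("time axis (year, doy) must be strictly increasing")
        if self.elevation is not None:
            self.elevation = np.asarray(self.elevation, dtype=float)
            if self.elevation.shape != (len(self.lat), len(self.lon)):
                raise ValueError(
                    f"elevation shape {self.elevation.shape} not conformable with "
                    f"grid ({len(self.lat)}, {len(self.lon)})"
                )

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tas.shape

    def years(self) -> np.ndarray:
        """Unique calendar years present, ascending."""
        return np.unique(self.year)

    def complete_years(self) -> np.ndarray:
        """Years for which every day of the calendar year is present."""
        out = []
        for y in self.years():
            n = int(np.sum(self.year == y))
            if n == days_in_year(int(y), self.calendar):
                out.append(int(y))
        return np.asarray(out, dtype=int)

    def select_years(self, start: int, end: int) -> "ClimateGrid":
        """Subset to calendar years in [start, end] (inclusive)."""
        m = (self.year >= start) & (self.year <= end)
        if not np.any(m):
            raise ValueError(f"no time steps in years {start}-{end}")
        return replace(self, year=self.year[m], doy=self.doy[m], tas=self.tas[m])

    def domain_mean_series(self) -> np.ndarray:
        """Spatial (unweighted) mean over cells for each time step."""
        return self.tas.reshape(len(self.year), -1).mean(axis=1)

    def annual_mean(self) -> pd.Series:
        """Domain-mean annual mean temperature per complete year."""
        dm = self.domain_mean_series()
        out = {}
        for y in self.complete_years():
            out[int(y)] = float(dm[self.year == y].mean())
        return pd.Series(out, name="tas_annual_mean_c")


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style; scipy backend, classic NetCDF)
# ---------------------------------------------------------------------------

def write_grid(grid: ClimateGrid, path) -> None:
    """Write a ClimateGrid to NetCDF (dimensions time/lat/lon, variable tas in degC)."""
    ds = xr.Dataset(
        {
            "tas": (("time", "lat", "lon"), grid.tas, {"units": "degC", "long_name": "daily mean air temperature"}),
            "year": (("time",), grid.year.astype("int32")),
            "doy": (("time",), grid.doy.astype("int32")),
        },
        coords={
            "time": ("time", np.arange(len(grid.year), dtype="int32"), {"long_name": "day index"}),
            "lat": ("lat", grid.lat, {"units": "degrees_north"}),
            "lon": ("lon", grid.lon, {"units": "degrees_east"}),
        },
        attrs={"calendar": grid.calendar, "provenance": grid.provenance, **grid.attrs},
    )
    if grid.elevation is not None:
        ds["elevation"] = (("lat", "lon"), grid.elevation, {"units": "m"})
    ds.to_netcdf(path, engine="scipy")


def read_grid(path) -> ClimateGrid:
    """Read a ClimateGrid from NetCDF.

    Accepts temperature in degC or K (Kelvin is converted with a logged
    note).  The temperature variable is located as ``tas`` or, failing
    that, any variable whose units declare a temperature.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if "tas" in ds:
        var = ds["tas"]
    else:
        candidates = [v for v in ds.data_vars if str(ds[v].attrs.get("units", "")).lower() in ("degc", "celsius", "k", "kelvin")]
        if not candidates:
            raise ValueError(
                f"no temperature variable found; available variables: {sorted(ds.data_vars)}"
            )
        var = ds[candidates[0]]
    units = str(var.attrs.get("units", "")).strip()
    if units == "":
        raise ValueError("temperature variable declares no units")
    values = np.asarray(var.values, dtype=float)
    if units.lower() in ("k", "kelvin"):
        logger.info("converting temperature from Kelvin to degC")
        values = values - 273.15
    elif units.lower() not in ("degc", "celsius", "c", "degrees_celsius"):
        raise ValueError(f"unsupported temperature units {units!r}; expected degC or K")
    elevation = np.asarray(ds["elevation"].values, dtype=float) if "elevation" in ds else None
    return ClimateGrid(
        lat=np.asarray(ds["lat"].values, dtype=float),
        lon=np.asarray(ds["lon"].values, dtype=float),
        year=np.asarray(ds["year"].values, dtype=int),
        doy=np.asarray(ds["doy"].values, dtype=int),
        tas=values,
        elevation=elevation,
        calendar=str(ds.attrs.get("calendar", "noleap")),
        provenance=str(ds.attrs.get("provenance", "observed")),
    )


def grid_to_csv(grid: ClimateGrid, path) -> None:
    """Long-format CSV export: columns date, lat, lon, temperature_c."""
    ny, nlat, nlon = grid.shape
    lat2, lon2 = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    rows = {
        "year": np.repeat(grid.year, nlat * nlon),
        "doy": np.repeat(grid.doy, nlat * nlon),
        "lat": np.tile(lat2.ravel(), ny),
        "lon": np.tile(lon2.ravel(), ny),
        "temperature_c": grid.tas.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Regridding
# ---------------------------------------------------------------------------

def _bilinear_weights(src: np.ndarray, tgt: np.ndarray):
    """Bracketing indices and linear weights of tgt points on the src axis.

    Points outside [src[0], src[-1]] are flagged for masking (no
    extrapolation).
    """
    idx = np.searchsorted(src, tgt, side="right") - 1
    outside = (tgt < src[0]) | (tgt > src[-1])
    idx = np.clip(idx, 0, len(src) - 2) if len(src) > 1 else np.zeros_like(idx)
    if len(src) == 1:
        return np.zeros(len(tgt), dtype=int), np.zeros(len(tgt), dtype=int), np.zeros(len(tgt)), outside
    i0 = idx
    i1 = idx + 1
    frac = (tgt - src[i0]) / (src[i1] - src[i0])
    frac = np.clip(frac, 0.0, 1.0)
    return i0, i1, frac, outside


def _target_centers(lo: float, hi: float, res: float) -> np.ndarray:
    """Cell centers of a res-degree grid spanning [lo, hi] (inclusive of edges)."""
    n = int(np.floor((hi - lo) / res + 1e-9)) + 1
    return lo + res * np.arange(n)


def regrid_bilinear(grid: ClimateGrid, resolution: float) -> ClimateGrid:
    """Bilinearly interpolate a grid onto a finer/coarser regular grid.

    Target cell centers span the source extent at the requested
    resolution; centers outside the source convex hull would be masked,
    but by construction the targets here always fall inside.  Elevation,
    when present, is regridded the same way.
    """
    if resolution <= 0:
        raise ValueError("target resolution must be positive")
    span_lat = grid.lat[-1] - grid.lat[0]
    span_lon = grid.lon[-1] - grid.lon[0]
    if len(grid.lat) > 1 and resolution > span_lat and resolution > span_lon:
        raise ValueError(
            f"target resolution {resolution} deg exceeds source extent "
            f"({span_lat:.3f} x {span_lon:.3f} deg)"
        )
    new_lat = _target_centers(grid.lat[0], grid.lat[-1], resolution)
    new_lon = _target_centers(grid.lon[0], grid.lon[-1], resolution)
    la0, la1, fla, out_la = _bilinear_weights(grid.lat, new_lat)
    lo0, lo1, flo, out_lo = _bilinear_weights(grid.lon, new_lon)
    if np.all(out_la) or np.all(out_lo):
        raise ValueError("target grid lies entirely outside the source grid")

    def interp(cube: np.ndarray) -> np.ndarray:
        # cube (..., nlat, nlon) -> (..., n_new_lat, n_new_lon)
        a = cube[..., la0, :][..., :, lo0]
        b = cube[..., la0, :][..., :, lo1]
        c = cube[..., la1, :][..., :, lo0]
        d = cube[..., la1, :][..., :, lo1]
        wla = fla[:, None]
        wlo = flo[None, :]
        return (
            a * (1 - wla) * (1 - wlo)
            + b * (1 - wla) * wlo
            + c * wla * (1 - wlo)
            + d * wla * wlo
        )

    new_tas = interp(grid.tas)
    mask = out_la[:, None] | out_lo[None, :]
    if mask.any():
        new_tas = np.where(mask[None, :, :], np.nan, new_tas)
    new_elev = interp(grid.elevation) if grid.elevation is not None else None
    return ClimateGrid(
        lat=new_lat,
        lon=new_lon,
        year=grid.year,
        doy=grid.doy,
        tas=new_tas,
        elevation=new_elev,
        calendar=grid.calendar,
        provenance=grid.provenance,
        attrs={**grid.attrs, "regridded_to_deg": resolution},
    )


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------

def _haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    r = 6371.0
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(a))


def extract_series(grid: ClimateGrid, lat: float, lon: float, year: int) -> DailyTemperatureSeries:
    """Nearest-cell-center daily series for one calendar year.

    Nearest is by great-circle distance; exact ties resolve to the
    south-west (lower-left) cell.
    """
    if not (grid.lat[0] <= lat <= grid.lat[-1]) or not (grid.lon[0] <= lon <= grid.lon[-1]):
        raise ValueError(
            f"point ({lat}, {lon}) outside grid bounds "
            f"lat [{grid.lat[0]}, {grid.lat[-1]}], lon [{grid.lon[0]}, {grid.lon[-1]}]"
        )
    if year not in grid.years():
        raise ValueError(f"year {year} not present in grid (years {grid.years().tolist()})")
    lat2, lon2 = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    d = _haversine_km(lat, lon, lat2, lon2)
    tie = d <= d.min() + 1e-9
    ii, jj = np.nonzero(tie)
    k = np.lexsort((jj, ii))[0]  # smallest lat, then smallest lon: south-west
    i, j = int(ii[k]), int(jj[k])
    m = grid.year == year
    return DailyTemperatureSeries(
        year=int(year), values=grid.tas[m, i, j], lat=float(grid.lat[i]), lon=float(grid.lon[j])
    )
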
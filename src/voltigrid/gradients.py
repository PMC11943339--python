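"""Elevation/latitude stratification, decadal trends and warming regressions.

The study domain is stratified into three elevation bands (<500 m,
500-1000 m, >1000 m) and five latitude bands ((34.5-35], (35-36],
(36-37], (37-38], (38-38.5] degN, left-open right-closed).  Within each
band the module computes unweighted cell means over period years,
ordinary-least-squares decadal trends of annual series ("per 10a"), and
regressions of voltinism change on warming (generations per degC), with
predicted changes at the +1 / +1.5 / +2 degC reporting points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

DEFAULT_ELEVATION_EDGES_M = (500.0, 1000.0)
DEFAULT_LATITUDE_EDGES_DEG = (34.5, 35.0, 36.0, 37.0, 38.0, 38.5)

#: Warming levels (degC) at which predicted voltinism changes are reported.
REPORTING_WARMING_LEVELS_C = (1.0, 1.5, 2.0)


def _elevation_labels(edges) -> list[str]:
    lo, hi = edges
    return [f"<{lo:g} m", f"{lo:g}-{hi:g} m", f">{hi:g} m"]


def _latitude_labels(edges) -> list[str]:
    return [f"({a:g}-{b:g}] degN" for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class GradientBinning:
    """Bin edges and labels for the two stratification axes.

    Elevation intervals are [0, lo), [lo, hi], (hi, inf); latitude
    intervals are left-open, right-closed.
    """

    elevation_edges_m: tuple = DEFAULT_ELEVATION_EDGES_M
    latitude_edges_deg: tuple = DEFAULT_LATITUDE_EDGES_DEG
    elevation_labels: list[str] = field(default_factory=list)
    latitude_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.elevation_edges_m) != 2 or not self.elevation_edges_m[0] < self.elevation_edges_m[1]:
            raise ValueError("elevation edges must be two ascending values")
        if len(self.latitude_edges_deg) < 2 or not np.all(np.diff(self.latitude_edges_deg) > 0):
            raise ValueError("latitude edges must be ascending")
        if not self.elevation_labels:
            self.elevation_labels = _elevation_labels(self.elevation_edges_m)
        if not self.latitude_labels:
            self.latitude_labels = _latitude_labels(self.latitude_edges_deg)

    def elevation_bin(self, elev_m: np.ndarray) -> np.ndarray:
        """Integer bin per cell: 0 for [0, lo), 1 for [lo, hi], 2 for (hi, inf)."""
        elev_m = np.asarray(elev_m, dtype=float)
        lo, hi = self.elevation_edges_m
        return np.where(elev_m < lo, 0, np.where(elev_m <= hi, 1, 2))

    def latitude_bin(self, lat_deg: np.ndarray) -> np.ndarray:
        """Integer bin per latitude, left-open right-closed; -1 outside all bins."""
        lat_deg = np.asarray(lat_deg, dtype=float)
        edges = np.asarray(self.latitude_edges_deg)
        # (a, b] membership: a < lat <= b
        idx = np.searchsorted(edges, lat_deg, side="left") - 1
        out = np.where((lat_deg > edges[0]) & (lat_deg <= edges[-1]), idx, -1)
        return out


def assign_bins(
    elevation: np.ndarray, lat: np.ndarray, binning: GradientBinning | None = None
) -> pd.DataFrame:
    """Per-cell bin membership table.

    Returns one row per grid cell (row-major over lat x lon) with the
    elevation and latitude bin labels.  Cells whose latitude falls
    outside every latitude bin get a null latitude label and a warning.
    """
    binning = binning or GradientBinning()
    elevation = np.asarray(elevation, dtype=float)
    lat = np.asarray(lat, dtype=float)
    nlat, nlon = elevation.shape
    lat2 = np.broadcast_to(lat[:, None], (nlat, nlon))
    ebin = binning.elevation_bin(elevation)
    lbin = binning.latitude_bin(lat2)
    if np.any(lbin < 0):
        warnings.warn(
            f"{int(np.sum(lbin < 0))} cells fall outside every latitude bin and are masked"
        )
    ii, jj = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
    return pd.DataFrame(
        {
            "cell_lat_index": ii.ravel(),
            "cell_lon_index": jj.ravel(),
            "lat": lat2.ravel(),
            "elevation_m": elevation.ravel(),
            "elevation_bin": [binning.elevation_labels[b] for b in ebin.ravel()],
            "latitude_bin": [
                binning.latitude_labels[b] if b >= 0 else None for b in lbin.ravel()
            ],
        }
    )


def bin_period_mean(
    values: np.ndarray,
    years: np.ndarray,
    membership: pd.DataFrame,
    bin_column: str,
    period: tuple[int, int],
) -> pd.Series:
    """Unweighted mean of a (nyears, nlat, nlon) field per bin over a period.

    Cells are near-equal-area at this domain extent, so no cos-latitude
    weighting is applied (a documented choice).
    """
    y0, y1 = period
    m = (years >= y0) & (years <= y1)
    if not np.any(m):
        raise ValueError(f"no years in period {y0}-{y1}")
    flat = values[m].reshape(int(m.sum()), -1)  # (nyears_in, ncells) row-major
    out = {}
    for label, rows in membership.groupby(bin_column, sort=False):
        idx = rows.index.to_numpy()
        out[label] = float(flat[:, idx].mean())
    return pd.Series(out, name=f"mean_{y0}_{y1}")


@dataclass
class TrendEstimate:
    """OLS trend of an annual series, expressed per decade."""

    slope_per_decade: float
    intercept: float
    ci_low: float
    ci_high: float
    r_squared: float
    n_years: int


def decadal_trend(years: np.ndarray, values: np.ndarray, alpha: float = 0.05) -> TrendEstimate:
    """OLS of annual values on calendar year; slope and CI reported x10 (per decade).

    A zero-variance (constant) series returns slope 0 with R^2 = 0 by
    convention.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 years for a trend")
    if np.allclose(values, values[0]):
        return TrendEstimate(0.0, float(values[0]), 0.0, 0.0, 0.0, len(years))
    X = sm.add_constant(years)
    fit = sm.OLS(values, X).fit()
    ci = fit.conf_int(alpha=alpha)[1]
    return TrendEstimate(
        slope_per_decade=float(fit.params[1] * 10),
        intercept=float(fit.params[0]),
        ci_low=float(ci[0] * 10),
        ci_high=float(ci[1] * 10),
        r_squared=float(fit.rsquared),
        n_years=len(years),
    )


@dataclass
class RegressionFit:
    """OLS fit of voltinism change on warming, generations per degC."""

    slope_per_degc: float
    intercept: float
    r_squared: float
    n_points: int
    predicted_dn: dict = field(default_factory=dict)


def voltinism_temperature_regression(
    delta_t: np.ndarray, delta_n: np.ndarray
) -> RegressionFit:
    """Regress voltinism change on annual-mean warming (both vs the baseline).

    Points are annual bin means pooled over projection years for one bin
    and scenario.  Besides the slope (generations per degC) the fit
    reports the predicted change at the +1, +1.5 and +2 degC warming
    levels.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    delta_n = np.asarray(delta_n, dtype=float)
    if len(delta_t) != len(delta_n):
        raise ValueError("delta_t and delta_n must be the same length")
    if len(delta_t) < 3:
        raise ValueError("need at least 3 (delta_t, delta_n) points")
    res = sps.linregress(delta_t, delta_n)
    pred = {
        level: float(res.intercept + res.slope * level)
        for level in REPORTING_WARMING_LEVELS_C
    }
    return RegressionFit(
        slope_per_degc=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(delta_t),
        predicted_dn=pred,
    )
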
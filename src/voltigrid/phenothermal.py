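"""Degree-day phenothermal core: CGDD, voltinism, and projected changes.

The model is the classical linear growing-degree-day model for the pine
caterpillar (*Dendrolimus* spp.).  For one calendar year with daily mean
temperatures T_i,

    CGDD = sum_i max(T_i - T0, 0)

with developmental zero T0, and voltinism (generations per year)

    N = CGDD / K

where K is the effective temperature accumulation required to complete
one full generation (egg to adult).  N is continuous — fractional
generations are meaningful and are not floored.  There is deliberately
no upper developmental threshold and no diapause/photoperiod switch.

Default parameters (rearing-experiment estimates for the pine
caterpillar: T0 = 9.95 +/- 0.61 degC, K = 1698.18 +/- 48.18 degree-days,
with per-stage values) ship with the package as CSV and can be replaced
by the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .climate_grid import ClimateGrid, DailyTemperatureSeries

logger = logging.getLogger(__name__)

COMPLETE_GENERATION = "complete_generation"
STAGE_ORDER = (
    "larvae_after_overwintering",
    "pupae",
    "egg",
    "larvae_before_overwintering",
)

#: Tolerance (degree-days) for the stage-sum vs whole-generation K check.
STAGE_SUM_TOLERANCE_DD = 0.02


@dataclass
class DevelopmentalParameters:
    """Stage-wise and whole-generation developmental zeros and degree-day sums.

    ``table`` is indexed by stage name with columns t0_c, t0_se, k_dd,
    k_se.  The whole-generation row drives CGDD/voltinism; the stage
    rows are retained for the internal-consistency check.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"t0_c", "t0_se", "k_dd", "k_se"}
        if not required <= set(self.table.columns):
            raise ValueError(f"parameter table must have columns {sorted(required)}")
        if COMPLETE_GENERATION not in self.table.index:
            raise ValueError(f"parameter table must contain a {COMPLETE_GENERATION!r} row")
        if (self.table["k_dd"] <= 0).any():
            raise ValueError("every K must be positive")
        if (self.table[["t0_se", "k_se"]] < 0).any().any():
            raise ValueError("standard errors must be >= 0")

    @classmethod
    def defaults(cls) -> "DevelopmentalParameters":
        src = resources.files("voltigrid.data").joinpath("developmental_parameters.csv")
        with src.open() as fh:
            return cls(pd.read_csv(fh, index_col="stage"))

    @classmethod
    def from_csv(cls, path) -> "DevelopmentalParameters":
        return cls(pd.read_csv(path, index_col="stage"))

    @property
    def t0(self) -> float:
        return float(self.table.loc[COMPLETE_GENERATION, "t0_c"])

    @property
    def t0_se(self) -> float:
        return float(self.table.loc[COMPLETE_GENERATION, "t0_se"])

    @property
    def k(self) -> float:
        return float(self.table.loc[COMPLETE_GENERATION, "k_dd"])

    @property
    def k_se(self) -> float:
        return float(self.table.loc[COMPLETE_GENERATION, "k_se"])


def compute_cgdd(series: DailyTemperatureSeries | np.ndarray, t0: float) -> float:
    """Cumulative growing degree days of one calendar year.

    Sums the positive exceedances max(T_i - t0, 0) over every day; no
    upper cutoff is applied.  Non-finite temperatures are an error, not
    silently skipped.
    """
    values = series.values if isinstance(series, DailyTemperatureSeries) else np.asarray(series, dtype=float)
    if values.size == 0:
        raise ValueError("empty temperature series")
    if not np.all(np.isfinite(values)):
        raise ValueError("temperature series contains non-finite values")
    return float(np.sum(np.maximum(values - t0, 0.0)))


def compute_voltinism(cgdd: float, params: DevelopmentalParameters | float) -> float:
    """Voltinism N = CGDD / K, continuous (not floored)."""
    k = params.k if isinstance(params, DevelopmentalParameters) else float(params)
    if k <= 0:
        raise ValueError("K must be positive")
    if cgdd < 0:
        raise ValueError("CGDD must be >= 0")
    return cgdd / k


@dataclass
class VoltinismField:
    """Per-cell, per-year CGDD and voltinism on a lat/lon grid."""

    lat: np.ndarray
    lon: np.ndarray
    years: np.ndarray
    cgdd: np.ndarray  # (nyears, nlat, nlon) degree-days
    voltinism: np.ndarray  # (nyears, nlat, nlon) generations/year
    elevation: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = (len(self.years), len(self.lat), len(self.lon))
        if self.cgdd.shape != expected or self.voltinism.shape != expected:
            raise ValueError("cgdd/voltinism shapes do not match (years, lat, lon)")
        if np.nanmin(self.cgdd) < 0:
            raise ValueError("CGDD must be nonnegative")

    def period_mean(self, start: int, end: int) -> np.ndarray:
        """Per-cell mean voltinism over calendar years [start, end]."""
        m = (self.years >= start) & (self.years <= end)
        if not np.any(m):
            raise ValueError(f"no complete years in period {start}-{end}")
        return self.voltinism[m].mean(axis=0)

    def annual_domain_mean(self) -> pd.DataFrame:
        """Domain-mean CGDD and voltinism per year."""
        return pd.DataFrame(
            {
                "year": self.years,
                "cgdd": self.cgdd.reshape(len(self.years), -1).mean(axis=1),
                "voltinism": self.voltinism.reshape(len(self.years), -1).mean(axis=1),
            }
        )


def cgdd_field(grid: ClimateGrid, params: DevelopmentalParameters) -> VoltinismField:
    """Annual CGDD and voltinism per cell for every complete calendar year.

    Partial years at the edges of the grid's time axis are dropped with
    a logged warning.
    """
    complete = grid.complete_years()
    dropped = sorted(set(grid.years().tolist()) - set(complete.tolist()))
    if dropped:
        logger.warning("dropping partial calendar years at grid edges: %s", dropped)
    if len(complete) == 0:
        raise ValueError("grid contains no complete calendar year")
    exceed = np.maximum(grid.tas - params.t0, 0.0)
    cgdd = np.stack([exceed[grid.year == y].sum(axis=0) for y in complete])
    return VoltinismField(
        lat=grid.lat.copy(),
        lon=grid.lon.copy(),
        years=complete,
        cgdd=cgdd,
        voltinism=cgdd / params.k,
        elevation=None if grid.elevation is None else grid.elevation.copy(),
    )


def delta_voltinism(future_mean: np.ndarray, baseline_mean: np.ndarray) -> np.ndarray:
    """Per-cell change in voltinism: future period mean minus baseline mean.

    Positive values denote an increase in generations per year.
    """
    future_mean = np.asarray(future_mean, dtype=float)
    baseline_mean = np.asarray(baseline_mean, dtype=float)
    if future_mean.shape != baseline_mean.shape:
        raise ValueError(
            f"grid mismatch: future {future_mean.shape} vs baseline {baseline_mean.shape}"
        )
    return future_mean - baseline_mean


def parameter_uncertainty_band(
    series: DailyTemperatureSeries, params: DevelopmentalParameters
) -> tuple[float, float, float]:
    """(N_low, N_point, N_high) from shifting T0 and K by their SEs.

    The low bound recomputes CGDD with t0 + SE and divides by K + SE
    (slowest development); the high bound uses t0 - SE and K - SE.  The
    SE-shifted t0 enters the degree-day sum itself, not a post-hoc
    correction.  With zero SEs the band collapses onto the point
    estimate.
    """
    n_point = compute_voltinism(compute_cgdd(series, params.t0), params.k)
    n_low = compute_voltinism(compute_cgdd(series, params.t0 + params.t0_se), params.k + params.k_se)
    n_high = compute_voltinism(compute_cgdd(series, params.t0 - params.t0_se), params.k - params.k_se)
    return n_low, n_point, n_high


@dataclass
class StageConsistencyReport:
    stage_sum_dd: float
    complete_generation_dd: float
    abs_difference_dd: float
    passed: bool


def stage_table_consistency(params: DevelopmentalParameters) -> StageConsistencyReport:
    """Check that the four stage K values sum to the whole-generation K.

    Passes when the absolute difference is within 0.02 degree-days
    (rounding of the published per-stage values).
    """
    stages = [s for s in params.table.index if s != COMPLETE_GENERATION]
    stage_sum = float(params.table.loc[stages, "k_dd"].sum())
    diff = abs(stage_sum - params.k)
    return StageConsistencyReport(
        stage_sum_dd=stage_sum,
        complete_generation_dd=params.k,
        abs_difference_dd=diff,
        passed=diff <= STAGE_SUM_TOLERANCE_DD,
    )
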
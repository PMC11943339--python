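"""Seeded synthetic climate: baseline grids and pseudo-GCM scenario members.

The generator produces gridded daily mean temperature with the
statistical structure the downstream analysis assumes for a temperate
mid-latitude study area:

* a spatial annual-mean field = reference mean + meridional gradient x
  (lat - lat_ref) + lapse rate x elevation,
* a sinusoidal seasonal cycle with its minimum in mid-January,
* AR(1) daily weather noise and a shared interannual year effect,
* a linear baseline warming trend, and
* per-scenario warming ramps (linear from 2015) anchored so the
  2081-2100 mean anomaly relative to the baseline period equals the
  configured end-of-century warming.

Pseudo-GCM members add a constant bias, a seasonal-amplitude inflation
factor and independent member noise on top of the same underlying model,
so that ensemble evaluation and selection have real structure to detect.

Every random stream is seeded per (seed, year), which makes a member's
historical years bit-identical to the observed generator for the same
seed, and makes output independent of which year range was requested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from .climate_grid import ClimateGrid, days_in_year

logger = logging.getLogger(__name__)

#: Day of year at which the seasonal sinusoid attains its minimum (mid-January).
SEASONAL_MINIMUM_DOY = 15

#: First year of the scenario (future) period.
SCENARIO_START_YEAR = 2015

#: The 2090s window over which scenario warming targets are defined.
SCENARIO_TARGET_WINDOW = (2081, 2100)

#: Default end-of-century warming (degC over baseline) per SSP scenario.
DEFAULT_SCENARIO_WARMING = {
    "SSP1-2.6": 2.37,
    "SSP2-4.5": 3.45,
    "SSP3-7.0": 4.35,
    "SSP5-8.5": 5.49,
}


@dataclass
class SyntheticClimateConfig:
    """Configuration of the synthetic study area and climate model.

    Defaults mirror a roughly 4 deg x 8 deg temperate coastal province
    (34.5-38.5 N, 114.5-122.75 E) whose domain-mean annual temperature
    sits in the 11-14 degC band, with central uplands reaching above
    1000 m.
    """

    lat_min: float = 34.5
    lat_max: float = 38.5
    lon_min: float = 114.5
    lon_max: float = 122.75
    resolution_deg: float = 0.25
    year_start: int = 1979
    year_end: int = 2018
    calendar: str = "noleap"
    #: Annual-mean temperature (degC) at (lat_min, sea level), mid-baseline.
    reference_annual_mean_c: float = 15.0
    #: degC per degree latitude; negative = cooler northward.
    meridional_gradient_c_per_deg: float = -0.55
    #: degC per km elevation; negative = cooler aloft.
    lapse_rate_c_per_km: float = -6.5
    seasonal_amplitude_c: float = 14.0
    daily_noise_sd_c: float = 2.0
    daily_noise_ar1: float = 0.7
    interannual_sd_c: float = 0.35
    #: Baseline linear warming, degC per decade, anchored at mid-baseline.
    warming_rate_c_per_decade: float = 0.3
    # Synthetic DEM shape: a low coastal plain with a central massif.
    dem_base_elevation_m: float = 60.0
    dem_relief_amplitude_m: float = 1300.0
    dem_ridge_lat: float = 36.3
    dem_ridge_lon: float = 117.8
    dem_ridge_sigma_lat_deg: float = 0.7
    dem_ridge_sigma_lon_deg: float = 1.1
    dem_noise_sd_m: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution_deg <= 0:
            raise ValueError("resolution must be positive")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("domain bounds must satisfy max > min")
        if self.seasonal_amplitude_c < 0:
            raise ValueError("seasonal amplitude must be >= 0")
        if self.daily_noise_sd_c < 0 or self.interannual_sd_c < 0:
            raise ValueError("noise SDs must be >= 0")
        if not abs(self.daily_noise_ar1) < 1:
            raise ValueError("|lag-1 autocorrelation| must be < 1")
        if self.calendar not in ("noleap", "gregorian"):
            raise ValueError("calendar must be 'noleap' or 'gregorian'")

    # -- grid axes --------------------------------------------------------

    def lat_axis(self) -> np.ndarray:
        n = int(np.floor((self.lat_max - self.lat_min) / self.resolution_deg + 1e-9)) + 1
        return self.lat_min + self.resolution_deg * np.arange(n)

    def lon_axis(self) -> np.ndarray:
        n = int(np.floor((self.lon_max - self.lon_min) / self.resolution_deg + 1e-9)) + 1
        return self.lon_min + self.resolution_deg * np.arange(n)

    @property
    def baseline_mid_year(self) -> float:
        return 0.5 * (self.year_start + self.year_end)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticClimateConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed (no silent default)")
        return cls(**raw)


@dataclass
class ScenarioSpec:
    """A forcing scenario: end-of-century warming over the baseline."""

    name: str
    warming_2090s_c: float
    trajectory: str = "linear"

    def __post_init__(self) -> None:
        if not np.isfinite(self.warming_2090s_c):
            raise ValueError("scenario warming must be finite")
        if self.trajectory not in ("linear", "quadratic"):
            raise ValueError("trajectory must be 'linear' or 'quadratic'")

    @classmethod
    def default(cls, name: str) -> "ScenarioSpec":
        if name not in DEFAULT_SCENARIO_WARMING:
            raise ValueError(
                f"unknown scenario {name!r}; valid names: {sorted(DEFAULT_SCENARIO_WARMING)}"
            )
        return cls(name=name, warming_2090s_c=DEFAULT_SCENARIO_WARMING[name])


def default_scenarios() -> list[ScenarioSpec]:
    return [ScenarioSpec.default(n) for n in DEFAULT_SCENARIO_WARMING]


@dataclass
class PseudoGCMSpec:
    """A synthetic climate-model member: bias, variance inflation, extra noise."""

    name: str
    bias_c: float = 0.0
    variance_inflation: float = 1.0
    noise_sd_c: float = 0.0
    seed_offset: int = 1

    def __post_init__(self) -> None:
        if self.variance_inflation <= 0:
            raise ValueError("variance inflation must be > 0")


def default_members(n: int = 5) -> list[PseudoGCMSpec]:
    """A small ensemble spanning good-to-poor skill (biases and noise grow)."""
    specs = []
    for i in range(n):
        specs.append(
            PseudoGCMSpec(
                name=f"pgcm{i + 1:02d}",
                bias_c=0.25 * i * (-1) ** i,
                variance_inflation=1.0 + 0.06 * i,
                noise_sd_c=0.4 + 0.5 * i,
                seed_offset=100 + i,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# DEM
# ---------------------------------------------------------------------------

def generate_dem(config: SyntheticClimateConfig) -> np.ndarray:
    """Synthetic elevation surface (m): coastal plain plus a central massif.

    Deterministic for a fixed seed.  At the default domain size the
    surface contains cells in each of the <500 m, 500-1000 m and
    >1000 m elevation bands.
    """
    lat = config.lat_axis()
    lon = config.lon_axis()
    if len(lat) == 1 and len(lon) == 1:
        warnings.warn("single-cell domain: elevation/latitude gradient bins will be empty")
    lat2, lon2 = np.meshgrid(lat, lon, indexing="ij")
    ridge = np.exp(
        -(
            (lat2 - config.dem_ridge_lat) ** 2 / (2 * config.dem_ridge_sigma_lat_deg**2)
            + (lon2 - config.dem_ridge_lon) ** 2 / (2 * config.dem_ridge_sigma_lon_deg**2)
        )
    )
    elev = config.dem_base_elevation_m + config.dem_relief_amplitude_m * ridge
    if config.dem_noise_sd_m > 0 and config.dem_relief_amplitude_m != 0:
        rng = np.random.default_rng([config.seed, 777])
        elev = elev + config.dem_noise_sd_m * rng.standard_normal(elev.shape)
    return np.maximum(elev, 0.0)


# ---------------------------------------------------------------------------
# Temperature fields
# ---------------------------------------------------------------------------

def _seasonal_cycle(doy: np.ndarray, n_days: int, amplitude: float) -> np.ndarray:
    """Sinusoid with minimum -amplitude at SEASONAL_MINIMUM_DOY, mean ~0."""
    return -amplitude * np.cos(2 * np.pi * (doy - SEASONAL_MINIMUM_DOY) / n_days)


def _ar1_noise(rng: np.random.Generator, n_days: int, shape: tuple, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise, SD ``sd``, lag-1 autocorrelation ``rho``.

    The chain is initialised from its stationary distribution, so each
    year restarts independently with the correct marginal variance.
    """
    if sd == 0:
        return np.zeros((n_days, *shape))
    z = rng.standard_normal((n_days, *shape))
    e = np.empty_like(z)
    e[0] = sd * z[0]
    innov = sd * np.sqrt(1 - rho**2)
    for t in range(1, n_days):
        e[t] = rho * e[t - 1] + innov * z[t]
    return e


def _interannual_effect(config: SyntheticClimateConfig, year: int) -> float:
    if config.interannual_sd_c == 0:
        return 0.0
    rng = np.random.default_rng([config.seed, 31, year])
    return float(config.interannual_sd_c * rng.standard_normal())


def _annual_mean_field(config: SyntheticClimateConfig, dem: np.ndarray) -> np.ndarray:
    lat = config.lat_axis()
    lat2 = np.broadcast_to(lat[:, None], dem.shape)
    return (
        config.reference_annual_mean_c
        + config.meridional_gradient_c_per_deg * (lat2 - config.lat_min)
        + config.lapse_rate_c_per_km * dem / 1000.0
    )


def _baseline_trend(config: SyntheticClimateConfig, year: int) -> float:
    """Linear warming (degC) at ``year``, zero at the baseline midpoint."""
    return config.warming_rate_c_per_decade * (year - config.baseline_mid_year) / 10.0


def scenario_warming_at(config: SyntheticClimateConfig, scenario: ScenarioSpec, year: int) -> float:
    """Scenario-period warming (degC over baseline mean) at a given year.

    Zero before SCENARIO_START_YEAR.  The ramp starts at the
    extrapolated baseline trend in 2015 (continuity) and is anchored so
    that its 2081-2100 mean equals the configured end-of-century
    warming.
    """
    if year < SCENARIO_START_YEAR:
        return _baseline_trend(config, year)
    c0 = _baseline_trend(config, SCENARIO_START_YEAR)
    w0, w1 = SCENARIO_TARGET_WINDOW
    span_mid = 0.5 * (w0 + w1) - SCENARIO_START_YEAR
    t = year - SCENARIO_START_YEAR
    if scenario.trajectory == "linear":
        slope = (scenario.warming_2090s_c - c0) / span_mid
        return c0 + slope * t
    # quadratic ramp: w(t) = c0 + a t^2, a set by the window-mean anomaly
    yrs = np.arange(w0, w1 + 1) - SCENARIO_START_YEAR
    a = (scenario.warming_2090s_c - c0) / float(np.mean(yrs**2))
    return c0 + a * t**2


def _daily_field_for_year(
    config: SyntheticClimateConfig,
    dem: np.ndarray,
    year: int,
    warming_c: float,
) -> np.ndarray:
    n_days = days_in_year(year, config.calendar)
    doy = np.arange(1, n_days + 1)
    base = _annual_mean_field(config, dem)  # (nlat, nlon)
    season = _seasonal_cycle(doy, n_days, config.seasonal_amplitude_c)  # (n_days,)
    iav = _interannual_effect(config, year)
    rng = np.random.default_rng([config.seed, year])
    noise = _ar1_noise(rng, n_days, dem.shape, config.daily_noise_sd_c, config.daily_noise_ar1)
    return base[None, :, :] + season[:, None, None] + warming_c + iav + noise


def generate_observed_climate(
    config: SyntheticClimateConfig, dem: np.ndarray
) -> ClimateGrid:
    """Synthetic "observed" baseline grid over the configured year range."""
    expected = (len(config.lat_axis()), len(config.lon_axis()))
    if dem.shape != expected:
        raise ValueError(f"dem shape {dem.shape} does not match config grid {expected}")
    years = range(config.year_start, config.year_end + 1)
    blocks, yy, dd = [], [], []
    for y in years:
        f = _daily_field_for_year(config, dem, y, _baseline_trend(config, y))
        blocks.append(f)
        n = f.shape[0]
        yy.append(np.full(n, y))
        dd.append(np.arange(1, n + 1))
    return ClimateGrid(
        lat=config.lat_axis(),
        lon=config.lon_axis(),
        year=np.concatenate(yy),
        doy=np.concatenate(dd),
        tas=np.concatenate(blocks, axis=0),
        elevation=dem,
        calendar=config.calendar,
        provenance="observed",
    )


def generate_gcm_member(
    config: SyntheticClimateConfig,
    dem: np.ndarray,
    member: PseudoGCMSpec,
    scenario: ScenarioSpec | None,
    years: tuple[int, int],
) -> ClimateGrid:
    """Pseudo-GCM daily temperature for ``years`` (inclusive range).

    Historical years follow the observed-style model (identical to the
    observed generator when the member has zero bias/noise and unit
    inflation); scenario years additionally carry the scenario warming
    ramp.  Scenario years require a ScenarioSpec.
    """
    expected = (len(config.lat_axis()), len(config.lon_axis()))
    if dem.shape != expected:
        raise ValueError(f"dem shape {dem.shape} does not match config grid {expected}")
    y0, y1 = years
    if y1 >= SCENARIO_START_YEAR and scenario is None:
        raise ValueError(
            f"years reach the scenario period (>= {SCENARIO_START_YEAR}) "
            "but no scenario was given"
        )
    blocks, yy, dd = [], [], []
    for y in range(y0, y1 + 1):
        if y >= SCENARIO_START_YEAR:
            warming = scenario_warming_at(config, scenario, y)
        else:
            warming = _baseline_trend(config, y)
        f = _daily_field_for_year(config, dem, y, warming)
        n_days = f.shape[0]
        if member.variance_inflation != 1.0:
            doy = np.arange(1, n_days + 1)
            extra = (member.variance_inflation - 1.0) * _seasonal_cycle(
                doy, n_days, config.seasonal_amplitude_c
            )
            f = f + extra[:, None, None]
        if member.bias_c != 0.0:
            f = f + member.bias_c
        if member.noise_sd_c > 0:
            mrng = np.random.default_rng([config.seed, member.seed_offset, y])
            f = f + member.noise_sd_c * mrng.standard_normal(f.shape)
        blocks.append(f)
        yy.append(np.full(n_days, y))
        dd.append(np.arange(1, n_days + 1))
    return ClimateGrid(
        lat=config.lat_axis(),
        lon=config.lon_axis(),
        year=np.concatenate(yy),
        doy=np.concatenate(dd),
        tas=np.concatenate(blocks, axis=0),
        elevation=dem,
        calendar=config.calendar,
        provenance=member.name,
    )
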
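import numpy as np
import pytest

from voltigrid import (
    ClimateGrid,
    SyntheticClimateConfig,
    generate_dem,
    generate_observed_climate,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale synthetic domain: 0.5 deg, 5 years, default physics."""
    return SyntheticClimateConfig(resolution_deg=0.5, year_start=2000, year_end=2004, seed=11)


@pytest.fixture(scope="session")
def quiet_config():
    """Same domain with all noise and trend switched off (analytic tests)."""
    return SyntheticClimateConfig(
        resolution_deg=0.5,
        year_start=2000,
        year_end=2004,
        daily_noise_sd_c=0.0,
        interannual_sd_c=0.0,
        warming_rate_c_per_decade=0.0,
        dem_noise_sd_m=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dem(small_config):
    return generate_dem(small_config)


@pytest.fixture(scope="session")
def small_obs(small_config, small_dem):
    return generate_observed_climate(small_config, small_dem)


def make_grid(tas, lat=None, lon=None, years=None, elevation=None, calendar="noleap", provenance="observed"):
    """Build a ClimateGrid from a (ntime, nlat, nlon) cube with 365-day years."""
    tas = np.asarray(tas, dtype=float)
    nt, nlat, nlon = tas.shape
    lat = np.arange(nlat, dtype=float) if lat is None else np.asarray(lat, dtype=float)
    lon = np.arange(nlon, dtype=float) if lon is None else np.asarray(lon, dtype=float)
    if years is None:
        ny, rem = divmod(nt, 365)
        if rem:
            year = np.full(nt, 2000)
            doy = np.arange(1, nt + 1)
        else:
            year = np.repeat(2000 + np.arange(ny), 365)
            doy = np.tile(np.arange(1, 366), ny)
    else:
        year = np.asarray(years)
        doy = np.empty(nt, dtype=int)
        for y in np.unique(year):
            m = year == y
            doy[m] = np.arange(1, m.sum() + 1)
    return ClimateGrid(
        lat=lat, lon=lon, year=year, doy=doy, tas=tas,
        elevation=elevation, calendar=calendar, provenance=provenance,
    )
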
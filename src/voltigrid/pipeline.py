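"""End-to-end orchestration: synth -> evaluate -> ensemble -> regrid ->
degree-days/voltinism -> gradients -> report, with a reproducibility
manifest.

The pipeline is deterministic for a fixed (config, seed): rerunning the
same RunConfig yields byte-identical artifacts, and the manifest records
every parameter and artifact checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate_synth as synth
from .climate_grid import ClimateGrid, regrid_bilinear, write_grid
from .gcm_ensemble import EnsembleSpec, ensemble_mean, rank_and_select, taylor_statistics, taylor_table
from .gradients import (
    GradientBinning,
    assign_bins,
    bin_period_mean,
    decadal_trend,
    voltinism_temperature_regression,
)
from .phenothermal import DevelopmentalParameters, VoltinismField, cgdd_field, delta_voltinism

logger = logging.getLogger(__name__)

#: The paper-style future reporting windows.
DEFAULT_FUTURE_PERIODS = {
    "2030s": (2021, 2040),
    "2050s": (2041, 2060),
    "2070s": (2061, 2080),
    "2090s": (2081, 2100),
}


@dataclass
class RunConfig:
    """Everything one end-to-end run needs, with an explicit seed."""

    seed: int
    climate: synth.SyntheticClimateConfig = None
    scenarios: list = field(default_factory=synth.default_scenarios)
    n_members: int = 5
    n_select: int = 3
    analysis_resolution_deg: float = 0.05
    future_periods: dict = field(default_factory=lambda: dict(DEFAULT_FUTURE_PERIODS))
    future_year_end: int = 2100
    params_csv: str | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("run config must set an explicit seed")
        if self.climate is None:
            self.climate = synth.SyntheticClimateConfig(seed=self.seed)
        spans = sorted(self.future_periods.values())
        for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
            if b0 <= a1:
                raise ValueError(f"future periods overlap: {(a0, a1)} and {(b0, b1)}")

    @classmethod
    def test_profile(cls, seed: int) -> "RunConfig":
        """Desk-scale profile: 0.5 deg grid, short periods, 3 members."""
        climate = synth.SyntheticClimateConfig(
            resolution_deg=0.5, year_start=2000, year_end=2014, seed=seed
        )
        return cls(
            seed=seed,
            climate=climate,
            n_members=3,
            n_select=2,
            analysis_resolution_deg=0.5,
            future_periods={"2030s": (2021, 2030), "2090s": (2091, 2100)},
            future_year_end=2100,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("run config must set an explicit seed")
        if "climate" in raw:
            raw["climate"] = synth.SyntheticClimateConfig(**{**raw["climate"], "seed": raw["climate"].get("seed", raw["seed"])})
        if "scenarios" in raw:
            raw["scenarios"] = [
                synth.ScenarioSpec(**s) if isinstance(s, dict) else synth.ScenarioSpec.default(s)
                for s in raw["scenarios"]
            ]
        if "future_periods" in raw:
            raw["future_periods"] = {k: tuple(v) for k, v in raw["future_periods"].items()}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _annual_mean_cube(grid: ClimateGrid) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell annual-mean temperature for every complete year."""
    years = grid.complete_years()
    cube = np.stack([grid.tas[grid.year == y].mean(axis=0) for y in years])
    return years, cube


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "stages": {},
        "artifacts": {},
    }
    cc = config.climate
    baseline = (cc.year_start, cc.year_end)

    # -- stage: synth ------------------------------------------------------
    t0 = time.perf_counter()
    dem = synth.generate_dem(cc)
    obs = synth.generate_observed_climate(cc, dem)
    write_grid(obs, out / "observed.nc")
    members = synth.default_members(config.n_members)
    hist_grids = {
        m.name: synth.generate_gcm_member(cc, dem, m, None, (cc.year_start, min(cc.year_end, synth.SCENARIO_START_YEAR - 1)))
        for m in members
    }
    manifest["stages"]["synth"] = {"seconds": round(time.perf_counter() - t0, 3)}

    # -- stage: evaluate ---------------------------------------------------
    t0 = time.perf_counter()
    stats = [taylor_statistics(g, obs) for g in hist_grids.values()]
    selected = rank_and_select(stats, config.n_select)
    taylor_table(stats, selected).to_csv(out / "taylor.csv", index=False)
    manifest["stages"]["evaluate"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "selected": selected,
    }

    # -- stage: ensemble + regrid + voltinism per scenario -----------------
    params = (
        DevelopmentalParameters.from_csv(config.params_csv)
        if config.params_csv
        else DevelopmentalParameters.defaults()
    )
    member_specs = {m.name: m for m in members}
    obs_a = regrid_bilinear(obs, config.analysis_resolution_deg)
    base_field = cgdd_field(obs_a, params)
    _write_voltinism_csv(base_field, out / "voltinism_baseline.csv")

    binning = GradientBinning()
    membership = assign_bins(obs_a.elevation, obs_a.lat, binning)
    membership.to_csv(out / "bins.csv", index=False)
    base_n_mean = base_field.period_mean(*baseline)
    base_years_t, base_t_cube = _annual_mean_cube(obs_a)
    base_t_mean = base_t_cube.mean(axis=0)

    trends_rows = []
    reg_rows = []
    summary_rows = []
    adm = base_field.annual_domain_mean()
    tr_c = decadal_trend(adm["year"], adm["cgdd"])
    tr_n = decadal_trend(adm["year"], adm["voltinism"])
    trends_rows.append(_trend_row("domain_cgdd", "baseline", tr_c))
    trends_rows.append(_trend_row("domain_voltinism", "baseline", tr_n))
    summary_rows.append(
        {
            "scope": "domain",
            "scenario": "baseline",
            "period": f"{baseline[0]}-{baseline[1]}",
            "voltinism_mean": float(adm["voltinism"].mean()),
            "voltinism_sd": float(adm["voltinism"].std(ddof=1)),
            "cgdd_mean": float(adm["cgdd"].mean()),
            "delta_voltinism": "",
        }
    )

    for scen in config.scenarios:
        t0 = time.perf_counter()
        sel_grids = [
            synth.generate_gcm_member(
                cc, dem, member_specs[name], scen,
                (synth.SCENARIO_START_YEAR, config.future_year_end),
            )
            for name in selected
        ]
        ens = ensemble_mean(sel_grids, EnsembleSpec(members=list(selected)))
        ens_a = regrid_bilinear(ens, config.analysis_resolution_deg)
        ens_a.elevation = obs_a.elevation
        write_grid(ens_a, out / f"ensemble_{scen.name}.nc")
        fut_field = cgdd_field(ens_a, params)
        _write_voltinism_csv(fut_field, out / f"voltinism_{scen.name}.csv")

        fadm = fut_field.annual_domain_mean()
        trends_rows.append(_trend_row("domain_cgdd", scen.name, decadal_trend(fadm["year"], fadm["cgdd"])))
        trends_rows.append(_trend_row("domain_voltinism", scen.name, decadal_trend(fadm["year"], fadm["voltinism"])))

        fut_years_t, fut_t_cube = _annual_mean_cube(ens_a)
        for pname, period in config.future_periods.items():
            dmean = delta_voltinism(fut_field.period_mean(*period), base_n_mean)
            pm = (fut_field.years >= period[0]) & (fut_field.years <= period[1])
            ann = fadm[fadm["year"].isin(fut_field.years[pm])]
            summary_rows.append(
                {
                    "scope": "domain",
                    "scenario": scen.name,
                    "period": pname,
                    "voltinism_mean": float(ann["voltinism"].mean()),
                    "voltinism_sd": float(ann["voltinism"].std(ddof=1)),
                    "cgdd_mean": float(ann["cgdd"].mean()),
                    "delta_voltinism": float(dmean.mean()),
                }
            )

        # bin-level dN vs dT regressions pooled over projection years
        for axis in ("elevation_bin", "latitude_bin"):
            for label, rows in membership.dropna(subset=[axis]).groupby(axis, sort=False):
                idx = rows.index.to_numpy()
                n_flat = fut_field.voltinism.reshape(len(fut_field.years), -1)[:, idx].mean(axis=1)
                t_flat = fut_t_cube.reshape(len(fut_years_t), -1)[:, idx].mean(axis=1)
                dn = n_flat - float(base_n_mean.ravel()[idx].mean())
                dt = t_flat - float(base_t_mean.ravel()[idx].mean())
                fit = voltinism_temperature_regression(dt, dn)
                reg_rows.append(
                    {
                        "bin": label,
                        "axis": axis,
                        "scenario": scen.name,
                        "slope_per_degC": fit.slope_per_degc,
                        "r2": fit.r_squared,
                        "n": fit.n_points,
                        "dN_at_1C": fit.predicted_dn[1.0],
                        "dN_at_1.5C": fit.predicted_dn[1.5],
                        "dN_at_2C": fit.predicted_dn[2.0],
                    }
                )
        manifest["stages"][f"scenario_{scen.name}"] = {
            "seconds": round(time.perf_counter() - t0, 3)
        }

    pd.DataFrame(trends_rows).to_csv(out / "trends.csv", index=False)
    pd.DataFrame(reg_rows).to_csv(out / "regressions.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "summary.csv", index=False)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.suffix in (".nc", ".csv"):
            manifest["artifacts"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["scenarios"] = [dataclasses.asdict(s) for s in config.scenarios]
    return d


def _trend_row(scope: str, scenario: str, tr) -> dict:
    return {
        "scope": scope,
        "scenario": scenario,
        "slope_per_decade": tr.slope_per_decade,
        "ci_low": tr.ci_low,
        "ci_high": tr.ci_high,
        "r2": tr.r_squared,
        "n_years": tr.n_years,
    }


def _write_voltinism_csv(fieldv: VoltinismField, path) -> None:
    fieldv.annual_domain_mean().to_csv(path, index=False)


def report_summary(out_dir) -> pd.DataFrame:
    """Assemble the run's summary table from the stage CSVs, unchanged."""
    out = Path(out_dir)
    summary = pd.read_csv(out / "summary.csv")
    return summary.sort_values(["scenario", "period"]).reset_index(drop=True)
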
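"""Taylor-statistic evaluation, skill ranking and multi-model averaging.

Members are compared with the observed baseline on the domain-mean daily
temperature series over the overlap of their periods (after aligning
calendars on (year, day-of-year)).  Pattern agreement is summarized by
the usual Taylor-diagram triple — Pearson correlation, standard
deviations, and centered RMSE — plus the overall mean bias, and ranked
with the standard Taylor skill score

    S = (1 + r)^4 / (4 (sigma_hat + 1/sigma_hat)^2),

where sigma_hat is the simulated/observed SD ratio.  S lies in (0, 1]
and equals 1 exactly when r = 1 and sigma_hat = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate_grid import ClimateGrid


@dataclass
class TaylorStats:
    """Pattern statistics of one simulated series against the observations."""

    member: str
    r: float
    sd_sim: float
    sd_obs: float
    crmse: float
    bias: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")
        if self.sd_sim < 0 or self.sd_obs < 0:
            raise ValueError("standard deviations must be >= 0")

    @property
    def sd_norm(self) -> float:
        """Normalized SD (sim/obs ratio)."""
        return self.sd_sim / self.sd_obs

    @property
    def crmse_norm(self) -> float:
        """Centered RMSE divided by the observed SD (Taylor-diagram scale)."""
        return self.crmse / self.sd_obs

    @property
    def skill(self) -> float:
        s = self.sd_norm
        return (1.0 + self.r) ** 4 / (4.0 * (s + 1.0 / s) ** 2)


def _overlap_series(sim: ClimateGrid, obs: ClimateGrid) -> tuple[np.ndarray, np.ndarray]:
    """Domain-mean daily series of both grids on their common (year, doy) steps."""
    sk = sim.year.astype(np.int64) * 1000 + sim.doy.astype(np.int64)
    ok = obs.year.astype(np.int64) * 1000 + obs.doy.astype(np.int64)
    common, si, oi = np.intersect1d(sk, ok, return_indices=True)
    if len(common) < 2:
        raise ValueError(
            f"fewer than 2 overlapping time steps between simulated "
            f"({sim.provenance}) and observed periods"
        )
    return sim.domain_mean_series()[si], obs.domain_mean_series()[oi]


def taylor_statistics(
    sim: ClimateGrid,
    obs: ClimateGrid,
    period: tuple[int, int] | None = None,
) -> TaylorStats:
    """Taylor statistics of a member against the observed baseline.

    ``period`` optionally restricts the comparison to calendar years
    [start, end]; otherwise the full overlap is used.  Statistics use
    population (1/n) variances; the centered RMSE then satisfies
    cRMSE^2 = sd_sim^2 + sd_obs^2 - 2 sd_sim sd_obs r.
    """
    if sim.tas.shape[1:] != obs.tas.shape[1:]:
        raise ValueError(
            f"grids differ: sim {sim.tas.shape[1:]} vs obs {obs.tas.shape[1:]}; "
            "regrid to a common grid first"
        )
    if period is not None:
        sim = sim.select_years(*period)
        obs = obs.select_years(*period)
    s, o = _overlap_series(sim, obs)
    sd_s = float(np.std(s))
    sd_o = float(np.std(o))
    sc, oc = s - s.mean(), o - o.mean()
    if sd_s == 0 or sd_o == 0:
        raise ValueError("zero-variance series: Taylor statistics undefined")
    r = float(np.mean(sc * oc) / (sd_s * sd_o))
    crmse = float(np.sqrt(np.mean((sc - oc) ** 2)))
    return TaylorStats(
        member=sim.provenance,
        r=r,
        sd_sim=sd_s,
        sd_obs=sd_o,
        crmse=crmse,
        bias=float(s.mean() - o.mean()),
    )


def rank_and_select(members: list[TaylorStats], k: int) -> list[str]:
    """Names of the top-k members by skill score; ties break alphabetically."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(members):
        raise ValueError(f"k={k} exceeds the {len(members)} evaluated members")
    ranked = sorted(members, key=lambda m: (-m.skill, m.member))
    return [m.member for m in ranked[:k]]


@dataclass
class EnsembleSpec:
    """Which members enter the multi-model mean and with what weights."""

    members: list[str]
    mode: str = "equal"
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("equal", "skill-weighted"):
            raise ValueError("mode must be 'equal' or 'skill-weighted'")
        if len(set(self.members)) != len(self.members):
            raise ValueError("member names must be unique")
        if self.weights is None:
            self.weights = np.full(len(self.members), 1.0 / len(self.members))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.members):
            raise ValueError("weights and members length mismatch")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be nonnegative and sum to 1")

    @classmethod
    def skill_weighted(cls, stats: list[TaylorStats]) -> "EnsembleSpec":
        s = np.array([m.skill for m in stats])
        return cls(members=[m.member for m in stats], mode="skill-weighted", weights=s / s.sum())


def ensemble_mean(members: list[ClimateGrid], spec: EnsembleSpec) -> ClimateGrid:
    """Per-cell, per-day weighted mean of member fields."""
    if len(members) != len(spec.members):
        raise ValueError("number of grids does not match spec members")
    ref = members[0]
    for g in members[1:]:
        same = (
            g.tas.shape == ref.tas.shape
            and np.array_equal(g.lat, ref.lat)
            and np.array_equal(g.lon, ref.lon)
            and np.array_equal(g.year, ref.year)
            and np.array_equal(g.doy, ref.doy)
        )
        if not same:
            raise ValueError(f"member {g.provenance!r} is not on the common grid/period")
    tas = sum(w * g.tas for w, g in zip(spec.weights, members))
    return ClimateGrid(
        lat=ref.lat.copy(),
        lon=ref.lon.copy(),
        year=ref.year.copy(),
        doy=ref.doy.copy(),
        tas=tas,
        elevation=None if ref.elevation is None else ref.elevation.copy(),
        calendar=ref.calendar,
        provenance="ensemble",
        attrs={"members": ",".join(spec.members), "weighting": spec.mode},
    )


def taylor_table(stats: list[TaylorStats], selected: list[str]) -> pd.DataFrame:
    """Evaluation table: one row per member, flagging the selected ones."""
    rows = [
        {
            "member": m.member,
            "r": m.r,
            "sd_sim": m.sd_sim,
            "sd_obs": m.sd_obs,
            "sd_norm": m.sd_norm,
            "crmse": m.crmse,
            "crmse_norm": m.crmse_norm,
            "bias": m.bias,
            "skill": m.skill,
            "selected": m.member in selected,
        }
        for m in stats
    ]
    return pd.DataFrame(rows).sort_values("skill", ascending=False).reset_index(drop=True)
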
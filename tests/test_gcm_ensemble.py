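"""Taylor statistics, skill ranking and multi-model averaging."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voltigrid import (
    EnsembleSpec,
    PseudoGCMSpec,
    TaylorStats,
    ensemble_mean,
    generate_gcm_member,
    generate_observed_climate,
    rank_and_select,
    taylor_statistics,
)

from conftest import make_grid


def brute_taylor(sim, obs):
    """Independent implementation of the Taylor triple from the defining sums."""
    n = len(sim)
    ms, mo = sum(sim) / n, sum(obs) / n
    sd_s = math.sqrt(sum((x - ms) ** 2 for x in sim) / n)
    sd_o = math.sqrt(sum((x - mo) ** 2 for x in obs) / n)
    r = sum((s - ms) * (o - mo) for s, o in zip(sim, obs)) / (n * sd_s * sd_o)
    crmse = math.sqrt(sum(((s - ms) - (o - mo)) ** 2 for s, o in zip(sim, obs)) / n)
    return r, sd_s, sd_o, crmse, ms - mo


def series_grid(values, provenance="sim"):
    v = np.asarray(values, dtype=float)
    return make_grid(v.reshape(-1, 1, 1), lat=[35.0], lon=[115.0], provenance=provenance)


class TestTaylorStatistics:
    def test_identical_fields_give_perfect_statistics(self, small_obs):
        ts = taylor_statistics(small_obs, small_obs)
        assert ts.r == pytest.approx(1.0, abs=1e-12)
        assert ts.crmse == pytest.approx(0.0, abs=1e-9)
        assert ts.sd_norm == pytest.approx(1.0, abs=1e-12)
        assert ts.bias == pytest.approx(0.0, abs=1e-12)
        assert ts.skill == pytest.approx(1.0, abs=1e-12)

    def test_constant_bias_leaves_centered_statistics_perfect(self, small_obs):
        sim = dataclasses.replace(small_obs, tas=small_obs.tas + 2.0, provenance="warm")
        ts = taylor_statistics(sim, small_obs)
        assert ts.r == pytest.approx(1.0, abs=1e-12)
        assert ts.crmse == pytest.approx(0.0, abs=1e-9)
        assert ts.bias == pytest.approx(2.0, abs=1e-9)

    def test_four_point_series_matches_hand_computed_sums(self):
        obs_v, sim_v = [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 2.0, 5.0]
        ts = taylor_statistics(series_grid(sim_v), series_grid(obs_v, "observed"))
        r, sd_s, sd_o, crmse, bias = brute_taylor(sim_v, obs_v)
        assert ts.r == pytest.approx(r, abs=1e-12)
        assert ts.sd_sim == pytest.approx(sd_s, abs=1e-12)
        assert ts.sd_obs == pytest.approx(sd_o, abs=1e-12)
        assert ts.crmse == pytest.approx(crmse, abs=1e-12)
        assert ts.bias == pytest.approx(bias, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_centered_rmse_law_holds(self, seed):
        rng = np.random.default_rng(seed)
        obs_v = rng.normal(10, 3, 50)
        sim_v = obs_v + rng.normal(0, 2, 50)
        ts = taylor_statistics(series_grid(sim_v), series_grid(obs_v, "observed"))
        law = ts.sd_sim**2 + ts.sd_obs**2 - 2 * ts.sd_sim * ts.sd_obs * ts.r
        assert ts.crmse**2 == pytest.approx(law, abs=1e-9)

    def test_too_short_overlap_errors(self):
        a = series_grid(np.arange(365.0))
        b = make_grid(np.zeros((365, 1, 1)), lat=[35.0], lon=[115.0])
        b = dataclasses.replace(b, year=b.year + 50)
        with pytest.raises(ValueError, match="overlap"):
            taylor_statistics(a, b)

    def test_comparison_period_restricts_years(self, small_obs):
        ts = taylor_statistics(small_obs, small_obs, period=(2000, 2001))
        assert ts.r == pytest.approx(1.0)


class TestRankAndSelect:
    def make_stats(self, name, r, sd_norm):
        return TaylorStats(member=name, r=r, sd_sim=sd_norm, sd_obs=1.0, crmse=0.5, bias=0.0)

    def test_perfect_member_ranks_first(self):
        stats = [
            self.make_stats("noisy1", 0.7, 1.4),
            self.make_stats("perfect", 1.0, 1.0),
            self.make_stats("noisy2", 0.85, 0.8),
        ]
        assert rank_and_select(stats, 1) == ["perfect"]

    def test_k_equals_n_returns_all_sorted_by_skill(self):
        stats = [
            self.make_stats("a", 0.5, 1.2),
            self.make_stats("b", 0.95, 1.05),
            self.make_stats("c", 0.8, 0.9),
        ]
        ranked = rank_and_select(stats, 3)
        skills = {s.member: s.skill for s in stats}
        assert ranked == sorted(skills, key=lambda m: -skills[m])

    def test_three_member_ordering_matches_brute_force_skill_formula(self):
        cases = [("m1", 0.9, 1.1), ("m2", 0.93, 0.9), ("m3", 0.6, 1.0)]
        stats = [self.make_stats(*c) for c in cases]
        brute = sorted(
            cases,
            key=lambda c: -((1 + c[1]) ** 4 / (4 * (c[2] + 1 / c[2]) ** 2)),
        )
        assert rank_and_select(stats, 3) == [c[0] for c in brute]

    def test_ties_break_alphabetically(self):
        stats = [self.make_stats("zeta", 0.9, 1.0), self.make_stats("alpha", 0.9, 1.0)]
        assert rank_and_select(stats, 2) == ["alpha", "zeta"]

    def test_invalid_k_errors(self):
        stats = [self.make_stats("a", 0.9, 1.0)]
        with pytest.raises(ValueError):
            rank_and_select(stats, 0)
        with pytest.raises(ValueError):
            rank_and_select(stats, 2)

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(-0.999, 1.0),
        st.floats(0.05, 5.0),
    )
    def test_skill_score_bounded_in_unit_interval(self, r, sd_norm):
        s = self.make_stats("m", r, sd_norm).skill
        assert 0.0 < s <= 1.0
        assert s < 1.0 or (r == 1.0 and sd_norm == 1.0)


class TestEnsembleMean:
    def test_identical_members_equal_weight_returns_member(self, small_obs):
        spec = EnsembleSpec(members=["a", "b"])
        out = ensemble_mean([small_obs, dataclasses.replace(small_obs, provenance="b")], spec)
        assert np.allclose(out.tas, small_obs.tas)
        assert out.provenance == "ensemble"

    def test_degenerate_weights_select_first_member_exactly(self, small_obs):
        other = dataclasses.replace(small_obs, tas=small_obs.tas + 3.0, provenance="b")
        spec = EnsembleSpec(members=["a", "b"], weights=[1.0, 0.0])
        out = ensemble_mean([small_obs, other], spec)
        assert np.array_equal(out.tas, small_obs.tas)

    def test_two_constant_members_average_to_midpoint(self):
        a = make_grid(np.full((10, 2, 2), 10.0), provenance="a")
        b = make_grid(np.full((10, 2, 2), 14.0), provenance="b")
        out = ensemble_mean([a, b], EnsembleSpec(members=["a", "b"]))
        assert np.allclose(out.tas, 12.0)

    def test_mean_bounded_by_member_envelope(self, small_obs):
        rng = np.random.default_rng(4)
        members = [
            dataclasses.replace(small_obs, tas=small_obs.tas + rng.normal(0, 1, small_obs.tas.shape), provenance=f"m{i}")
            for i in range(3)
        ]
        out = ensemble_mean(members, EnsembleSpec(members=["m0", "m1", "m2"]))
        lo = np.min([m.tas for m in members], axis=0)
        hi = np.max([m.tas for m in members], axis=0)
        assert np.all(out.tas >= lo - 1e-12) and np.all(out.tas <= hi + 1e-12)

    def test_grid_mismatch_names_offending_member(self, small_obs):
        other = make_grid(np.zeros((10, 2, 2)), provenance="odd")
        with pytest.raises(ValueError, match="odd"):
            ensemble_mean([small_obs, other], EnsembleSpec(members=["a", "odd"]))

    def test_weights_must_be_normalized(self):
        with pytest.raises(ValueError, match="sum to 1"):
            EnsembleSpec(members=["a", "b"], weights=[0.7, 0.7])


class TestSkillReflectsConfiguredQuality:
    def test_lower_bias_and_noise_member_wins_in_expectation(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, daily_noise_sd_c=1.5, interannual_sd_c=0.3)
        good = PseudoGCMSpec(name="good", bias_c=0.1, noise_sd_c=0.3, seed_offset=50)
        bad = PseudoGCMSpec(name="bad", bias_c=1.5, noise_sd_c=2.5, variance_inflation=1.4, seed_offset=60)
        wins = 0
        for seed in range(20):
            c = dataclasses.replace(cfg, seed=seed)
            from voltigrid import generate_dem

            dem = generate_dem(c)
            obs = generate_observed_climate(c, dem)
            gg = generate_gcm_member(c, dem, good, None, (2000, 2004))
            gb = generate_gcm_member(c, dem, bad, None, (2000, 2004))
            sg = taylor_statistics(gg, obs)
            sb = taylor_statistics(gb, obs)
            wins += sg.skill > sb.skill
        assert wins >= 15
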
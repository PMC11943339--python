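"""Degree-day accumulation, voltinism, change fields and parameter checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voltigrid import (
    DailyTemperatureSeries,
    DevelopmentalParameters,
    cgdd_field,
    compute_cgdd,
    compute_voltinism,
    delta_voltinism,
    extract_series,
    parameter_uncertainty_band,
    stage_table_consistency,
)

from conftest import make_grid

PARAMS = DevelopmentalParameters.defaults()


def year_series(values):
    return DailyTemperatureSeries(year=2000, values=np.asarray(values, dtype=float))


class TestComputeCgdd:
    def test_year_at_threshold_accumulates_nothing(self):
        assert compute_cgdd(year_series(np.full(365, PARAMS.t0)), PARAMS.t0) == 0.0

    def test_year_one_degree_above_threshold_accumulates_365(self):
        s = year_series(np.full(365, PARAMS.t0 + 1.0))
        assert compute_cgdd(s, PARAMS.t0) == pytest.approx(365.0, abs=1e-9)

    def test_hand_loop_on_four_days(self):
        # exceedances of (8, 10, 12, 14) over 9.95: 0 + 0.05 + 2.05 + 4.05
        assert compute_cgdd(np.array([8.0, 10.0, 12.0, 14.0]), 9.95) == pytest.approx(6.15, abs=1e-12)

    def test_empty_series_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compute_cgdd(np.array([]), 9.95)

    def test_non_finite_temperature_errors_not_skipped(self):
        v = np.full(365, 15.0)
        v[100] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            compute_cgdd(v, 9.95)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_daily_increments_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(12, 8, 365)
        bump = rng.uniform(0, 2, 365)
        c0 = compute_cgdd(base, 9.95)
        assert compute_cgdd(base + bump, 9.95) >= c0
        assert compute_cgdd(rng.permutation(base), 9.95) == pytest.approx(c0, abs=1e-9)

    def test_uniform_shift_of_all_above_threshold_year_adds_365_dt(self):
        base = np.full(365, 20.0)
        dt = 1.7
        dc = compute_cgdd(base + dt, 9.95) - compute_cgdd(base, 9.95)
        assert dc == pytest.approx(365 * dt, abs=1e-9)


class TestComputeVoltinism:
    def test_one_generation_at_exactly_k(self):
        assert compute_voltinism(1698.18, PARAMS) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "cgdd,expected",
        [(2132.93, 1.26), (2651.25, 1.56)],
        ids=["current-period-min", "current-period-max"],
    )
    def test_current_period_extremes_match_published_values(self, cgdd, expected):
        assert round(compute_voltinism(cgdd, PARAMS), 2) == expected

    def test_nonpositive_k_errors(self):
        with pytest.raises(ValueError):
            compute_voltinism(100.0, 0.0)

    def test_negative_cgdd_errors(self):
        with pytest.raises(ValueError):
            compute_voltinism(-1.0, PARAMS)


class TestCgddField:
    def test_field_at_threshold_is_all_zero(self):
        g = make_grid(np.full((365, 2, 2), PARAMS.t0))
        f = cgdd_field(g, PARAMS)
        assert np.all(f.cgdd == 0.0) and np.all(f.voltinism == 0.0)

    def test_uniform_ten_degrees_above_threshold(self):
        g = make_grid(np.full((365, 2, 2), PARAMS.t0 + 10.0))
        f = cgdd_field(g, PARAMS)
        assert np.allclose(f.cgdd, 3650.0, atol=1e-9)
        assert np.allclose(f.voltinism, 3650.0 / 1698.18, atol=1e-9)

    def test_field_matches_per_cell_series_oracle(self, small_obs):
        f = cgdd_field(small_obs, PARAMS)
        rng = np.random.default_rng(2)
        for _ in range(5):
            i = rng.integers(len(small_obs.lat))
            j = rng.integers(len(small_obs.lon))
            for y in (2000, 2002, 2004):
                s = extract_series(small_obs, float(small_obs.lat[i]), float(small_obs.lon[j]), y)
                yi = int(np.nonzero(f.years == y)[0][0])
                assert f.cgdd[yi, i, j] == pytest.approx(compute_cgdd(s, PARAMS.t0), abs=1e-9)

    def test_partial_years_dropped_with_warning(self, caplog):
        tas = np.full((365 + 50, 1, 1), 20.0)
        years = np.r_[np.full(365, 2000), np.full(50, 2001)]
        g = make_grid(tas, years=years)
        with caplog.at_level("WARNING"):
            f = cgdd_field(g, PARAMS)
        assert f.years.tolist() == [2000]
        assert "partial" in caplog.text

    def test_vectorized_field_equals_naive_loop_on_random_series(self):
        rng = np.random.default_rng(9)
        tas = rng.normal(12, 9, (2 * 365, 5, 5))
        g = make_grid(tas)
        f = cgdd_field(g, PARAMS)
        for yi, y in enumerate(f.years):
            block = tas[yi * 365 : (yi + 1) * 365]
            for i in range(5):
                for j in range(5):
                    naive = sum(max(t - PARAMS.t0, 0.0) for t in block[:, i, j])
                    assert f.cgdd[yi, i, j] == pytest.approx(naive, abs=1e-9)


class TestDeltaVoltinism:
    def test_identical_fields_give_zero_change(self):
        a = np.full((3, 3), 1.4)
        assert np.all(delta_voltinism(a, a) == 0.0)

    def test_published_domain_means_differ_by_0p79(self):
        assert delta_voltinism(np.array(2.19), np.array(1.40)) == pytest.approx(0.79, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(1, 3, (4, 4)), rng.uniform(1, 3, (4, 4))
        assert np.allclose(delta_voltinism(a, b), -delta_voltinism(b, a))

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            delta_voltinism(np.zeros((2, 2)), np.zeros((3, 3)))


class TestUncertaintyBand:
    def test_zero_standard_errors_collapse_band(self):
        t = PARAMS.table.copy()
        t[["t0_se", "k_se"]] = 0.0
        p0 = DevelopmentalParameters(t)
        s = year_series(np.full(365, 20.0))
        lo, point, hi = parameter_uncertainty_band(s, p0)
        assert lo == point == hi

    def test_k_se_only_band_is_exact_ratio(self):
        t = PARAMS.table.copy()
        t["t0_se"] = 0.0
        p = DevelopmentalParameters(t)
        s = year_series(np.full(365, 20.0))
        lo, point, hi = parameter_uncertainty_band(s, p)
        assert hi / point == pytest.approx(p.k / (p.k - p.k_se), abs=1e-12)
        assert lo / point == pytest.approx(p.k / (p.k + p.k_se), abs=1e-12)

    def test_default_band_brackets_point_estimate(self, small_obs):
        s = extract_series(small_obs, 36.0, 118.0, 2002)
        lo, point, hi = parameter_uncertainty_band(s, PARAMS)
        assert lo < point < hi


class TestStageTable:
    def test_published_stage_sum_is_internally_consistent(self):
        rep = stage_table_consistency(PARAMS)
        assert rep.stage_sum_dd == pytest.approx(1698.19, abs=1e-9)
        assert rep.abs_difference_dd == pytest.approx(0.01, abs=1e-9)
        assert rep.passed

    def test_exact_stage_sum_passes(self):
        t = PARAMS.table.copy()
        t["k_dd"] = [1.0, 1.0, 1.0, 1.0, 4.0]
        assert stage_table_consistency(DevelopmentalParameters(t)).passed

    def test_half_degree_day_discrepancy_fails(self):
        t = PARAMS.table.copy()
        t.loc["complete_generation", "k_dd"] += 0.5
        assert not stage_table_consistency(DevelopmentalParameters(t)).passed

    def test_defaults_expose_published_parameters(self):
        assert PARAMS.t0 == 9.95 and PARAMS.t0_se == 0.61
        assert PARAMS.k == 1698.18 and PARAMS.k_se == 48.18
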
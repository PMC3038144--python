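import numpy as np
import pandas as pd
import pytest

from infant_ee.processing import (
    CalorimetryConfig,
    DegenerateActivityError,
    SMRUndeterminableError,
    clock_from_minute_of_day,
    compute_ee24,
    compute_rmr,
    compute_smr,
    ee_from_gas,
    in_clock_window,
    process_trace,
    summarize,
)
from infant_ee.records import InfantRecord
from infant_ee.synthetic import simulate_trace

from .test_synthetic import quiet_params


def make_trace(n, start_clock_minute=570, vo2=0.05, vco2=0.045, pa=1.0,
               interaction=False, asleep=False, feeding=False):
    """Hand-built minute trace with scalar or per-minute columns."""
    def col(x):
        return np.full(n, x) if np.isscalar(x) else np.asarray(x)

    return pd.DataFrame(
        {
            "minute_index": np.arange(n),
            "clock": [
                clock_from_minute_of_day(start_clock_minute + i) for i in range(n)
            ],
            "vo2_l_min": col(vo2),
            "vco2_l_min": col(vco2),
            "pa_index": col(pa),
            "interaction": col(interaction).astype(bool),
            "asleep": col(asleep).astype(bool),
            "feeding": col(feeding).astype(bool),
        }
    )


class TestEEFromGas:
    def test_weir_value(self):
        assert ee_from_gas(0.05, 0.045) == pytest.approx(0.24682, abs=1e-9)

    def test_zero_vco2_single_term(self):
        assert ee_from_gas(0.07, 0.0) == pytest.approx(3.941 * 0.07)

    def test_nonpositive_vo2_rejected(self):
        with pytest.raises(ValueError):
            ee_from_gas(0.0, 0.01)

    def test_custom_coefficients(self):
        cfg = CalorimetryConfig(o2_coef=3.9, co2_coef=1.1)
        assert ee_from_gas(0.1, 0.1, cfg) == pytest.approx(0.5)


class TestClockWindow:
    def test_wraps_midnight_half_open(self):
        w = ("23:30", "05:30")
        assert in_clock_window(1410, w)  # 23:30
        assert in_clock_window(0, w)
        assert in_clock_window(329, w)  # 05:29
        assert not in_clock_window(330, w)  # 05:30 excluded
        assert not in_clock_window(1409, w)


class TestSummarize:
    def test_counts_full_day(self):
        periods = summarize(make_trace(1440))
        assert len(periods) == 288

    def test_single_interaction_minute_censors_whole_period(self):
        inter = np.zeros(5, dtype=bool)
        inter[3] = True
        periods = summarize(make_trace(5, interaction=inter))
        assert len(periods) == 1
        assert bool(periods["censored_interaction"].iloc[0])

    def test_period_rq_is_ratio_of_sums(self):
        periods = summarize(make_trace(5, vo2=0.05, vco2=0.044))
        assert periods["rq"].iloc[0] == pytest.approx(0.88)

    def test_all_asleep_requires_every_minute(self):
        asleep = np.ones(5, dtype=bool)
        asleep[0] = False
        periods = summarize(make_trace(5, asleep=asleep))
        assert not bool(periods["all_asleep"].iloc[0])

    def test_window_membership_requires_whole_period(self):
        # 20 minutes starting 23:20 -> periods at 23:20, 23:25, 23:30, 23:35
        periods = summarize(make_trace(20, start_clock_minute=1400))
        assert periods["in_smr_window"].tolist() == [False, False, True, True]

    def test_gap_in_minutes_rejected(self):
        trace = make_trace(10)
        trace.loc[5:, "minute_index"] += 1
        with pytest.raises(ValueError, match="contiguous"):
            summarize(trace)

    def test_length_must_divide(self):
        with pytest.raises(ValueError):
            summarize(make_trace(7))


def periods_from(ee, pa, censored=None, asleep=True, in_window=True):
    n = len(ee)
    return pd.DataFrame(
        {
            "start_minute": np.arange(n) * 5,
            "ee": ee,
            "pa": pa,
            "rq": 0.88,
            "censored_interaction": np.zeros(n, bool) if censored is None else censored,
            "all_asleep": np.full(n, asleep),
            "in_smr_window": np.full(n, in_window),
        }
    )


class TestRMR:
    def test_recovers_exact_linear_relation(self):
        pa = np.linspace(0.0, 6.0, 40)
        periods = periods_from(0.33 + 0.01 * pa, pa)
        rmr, diag = compute_rmr(periods, weight_kg=7.2)
        assert rmr == pytest.approx(66.0, rel=1e-9)
        assert diag.slope == pytest.approx(0.01, rel=1e-6)
        assert diag.r_squared == pytest.approx(1.0)

    def test_constant_ee_gives_zero_slope(self):
        pa = np.linspace(0.5, 4.0, 20)
        rmr, diag = compute_rmr(periods_from(np.full(20, 0.3), pa), weight_kg=7.2)
        assert rmr == pytest.approx(0.3 * 1440 / 7.2)
        assert diag.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        pa = rng.uniform(0, 5, 200)
        ee = 0.3 + 0.02 * pa + rng.normal(0, 0.01, 200)
        rmr, diag = compute_rmr(periods_from(ee, pa), weight_kg=7.0)
        sxx = np.sum((pa - pa.mean()) ** 2)
        slope = np.sum((pa - pa.mean()) * (ee - ee.mean())) / sxx
        intercept = ee.mean() - slope * pa.mean()
        assert diag.intercept == pytest.approx(intercept, abs=1e-9)
        assert diag.slope == pytest.approx(slope, abs=1e-9)

    def test_censored_periods_excluded(self):
        pa = np.linspace(0, 4, 20)
        ee = 0.3 + 0.01 * pa
        censored = np.zeros(20, bool)
        censored[:5] = True
        ee = ee.copy()
        ee[:5] = 9.9  # garbage that must be ignored
        rmr, _ = compute_rmr(periods_from(ee, pa, censored=censored), weight_kg=7.2)
        assert rmr == pytest.approx(0.3 * 1440 / 7.2, rel=1e-9)

    def test_degenerate_activity_raises(self):
        with pytest.raises(DegenerateActivityError):
            compute_rmr(periods_from(np.ones(10) * 0.3, np.ones(10)), weight_kg=7.0)

    def test_negative_intercept_flagged_not_hidden(self):
        pa = np.linspace(1, 5, 30)
        rmr, diag = compute_rmr(periods_from(0.05 * pa - 0.01, pa), weight_kg=7.0)
        assert diag.negative_intercept
        assert rmr < 0


class TestSMR:
    def test_constant_sleeping_ee(self):
        periods = periods_from(np.full(10, 0.325), np.full(10, 0.5))
        smr, n = compute_smr(periods, weight_kg=7.2)
        assert smr == pytest.approx(65.0)
        assert n == 10

    def test_single_qualifying_period(self):
        periods = periods_from(np.array([0.3]), np.array([0.4]))
        smr, n = compute_smr(periods, weight_kg=7.0)
        assert smr == pytest.approx(0.3 * 1440 / 7.0)
        assert n == 1

    def test_high_activity_sleep_excluded(self):
        ee = np.array([0.3, 0.9])
        pa = np.array([0.5, 3.0])  # second period over the activity cutoff
        smr, n = compute_smr(periods_from(ee, pa), weight_kg=7.0)
        assert n == 1
        assert smr == pytest.approx(0.3 * 1440 / 7.0)

    def test_no_qualifying_period_is_explicit_error(self):
        periods = periods_from(np.full(4, 0.3), np.full(4, 0.5), asleep=False)
        with pytest.raises(SMRUndeterminableError, match="undeterminable"):
            compute_smr(periods, weight_kg=7.0)


class TestEE24:
    def test_censoring_of_equal_values_is_invisible(self):
        censored = np.zeros(10, bool)
        censored[:5] = True
        periods = periods_from(np.full(10, 0.4), np.linspace(0, 4, 10), censored=censored)
        assert compute_ee24(periods, 7.2) == pytest.approx(0.4 * 1440 / 7.2)

    def test_full_mode_uses_all_periods(self):
        censored = np.array([True, False])
        periods = periods_from(np.array([0.6, 0.2]), np.array([1.0, 2.0]), censored=censored)
        assert compute_ee24(periods, 7.2, mode="censored") == pytest.approx(0.2 * 200.0)
        assert compute_ee24(periods, 7.2, mode="full") == pytest.approx(0.4 * 200.0)

    def test_all_censored_is_error(self):
        periods = periods_from(np.full(4, 0.3), np.zeros(4), censored=np.ones(4, bool))
        with pytest.raises(ValueError):
            compute_ee24(periods, 7.0)


@pytest.fixture(scope="module")
def infant():
    return InfantRecord(id="p", sex="male", age_months=5, length_cm=68.8, bmi=15.5)


class TestProcessTrace:

    def test_constant_latent_ee_collapses_outputs(self, infant):
        trace, truth = simulate_trace(infant, quiet_params(), seed=6)
        profile = process_trace(trace, infant)
        assert profile.ee24 == pytest.approx(66.0, rel=1e-9)
        assert profile.rmr == pytest.approx(66.0, rel=1e-9)
        assert profile.smr == pytest.approx(66.0, rel=1e-9)

    def test_pipeline_is_linear_in_gas(self, infant):
        trace, _ = simulate_trace(infant, seed=7)
        scaled = trace.copy()
        scaled["vo2_l_min"] *= 3.0
        scaled["vco2_l_min"] *= 3.0
        p1 = process_trace(trace, infant)
        p3 = process_trace(scaled, infant)
        assert p3.ee24 == pytest.approx(3 * p1.ee24, rel=1e-9)
        assert p3.rmr == pytest.approx(3 * p1.rmr, rel=1e-9)
        assert p3.smr == pytest.approx(3 * p1.smr, rel=1e-9)

    def test_adding_interaction_only_removes_periods(self, infant):
        trace, _ = simulate_trace(infant, seed=8)
        more = trace.copy()
        more.loc[100:160, "interaction"] = True
        kept = summarize(trace)
        kept_more = summarize(more)
        retained = set(kept.loc[~kept["censored_interaction"], "start_minute"])
        retained_more = set(
            kept_more.loc[~kept_more["censored_interaction"], "start_minute"]
        )
        assert retained_more <= retained

    def test_sleepless_trace_surfaces_smr_error(self, infant):
        trace, _ = simulate_trace(infant, seed=9)
        trace = trace.copy()
        trace["asleep"] = False
        profile = process_trace(trace, infant)
        assert np.isnan(profile.smr)
        assert "undeterminable" in profile.smr_error
        assert profile.rmr > 0  # other estimates still produced

    def test_censoring_counters_consistent(self, infant, default_study=None):
        trace, _ = simulate_trace(infant, seed=10)
        profile = process_trace(trace, infant)
        assert profile.n_periods_total == 288
        assert 0 < profile.n_censored < 288
        assert profile.n_smr_used <= profile.n_periods_total - profile.n_censored
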
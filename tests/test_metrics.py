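"""Glycemic metrics: MPG windows, MAGE vs a brute-force oracle, AUC24."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from nof1cgm.metrics import (
    build_outcome_series,
    compute_auc24,
    compute_mage,
    compute_mpg,
    turning_points,
)
from nof1cgm.types import GlucoseTrace, MealEvent, ValidationError

from conftest import make_day_trace


def trace_of(day_df, pid="p"):
    return GlucoseTrace(participant_id=pid, samples=day_df)


def meal(slot="lunch", time=dt.time(12, 0), date=dt.date(2024, 1, 1), consumed=True, pid="p"):
    return MealEvent(participant_id=pid, date=date, slot=slot,
                     first_bite_time=time, consumed=consumed)


# ---------------------------------------------------------------------------
# MPG


class TestMpg:
    def test_flat_trace(self):
        t = trace_of(make_day_trace([5.0] * 96))
        m = compute_mpg(t, meal(slot="breakfast", time=dt.time(8, 0)))
        assert m.mpg == 5.0

    def test_window_truncated_at_next_meal(self):
        # max 7.0 occurs at 14:30, outside [12:00, 14:00); max inside is 6.1
        values = np.full(96, 5.0)
        times = [dt.time(h, m) for h in range(24) for m in (0, 15, 30, 45)]
        idx = {t: i for i, t in enumerate(times)}
        values[idx[dt.time(13, 45)]] = 6.1
        values[idx[dt.time(14, 30)]] = 7.0
        t = trace_of(make_day_trace(values))
        nxt = meal(slot="dinner", time=dt.time(14, 0))
        m = compute_mpg(t, meal(), nxt)
        # independent brute force over the enumerated window samples
        expected = max(
            v for tt, v in zip(times, values)
            if dt.time(12, 0) <= tt < dt.time(14, 0)
        )
        assert m.mpg == expected == 6.1
        assert m.window == (dt.datetime(2024, 1, 1, 12), dt.datetime(2024, 1, 1, 14))

    def test_window_is_half_open(self):
        # a sample exactly at the next meal's start belongs to the next meal
        values = np.full(96, 5.0)
        values[14 * 4] = 9.0  # 14:00 sharp
        t = trace_of(make_day_trace(values))
        m = compute_mpg(t, meal(), meal(slot="dinner", time=dt.time(14, 0)))
        assert m.mpg == 5.0

    def test_missed_meal_yields_no_metric(self):
        t = trace_of(make_day_trace([5.0] * 96))
        assert compute_mpg(t, meal(consumed=False)) is None

    def test_no_samples_in_window_is_missing(self):
        t = trace_of(make_day_trace([5.0] * 8))  # 00:00-01:45 only
        m = compute_mpg(t, meal())
        assert m.mpg is None

    def test_supersampling_never_raises_the_max(self):
        # interpolated points lie below the sampled max of the curve
        rng = np.random.default_rng(0)
        base = 5 + rng.random(96)
        coarse = trace_of(make_day_trace(base))
        fine_values = np.empty(191)
        fine_values[::2] = base
        fine_values[1::2] = (base[:-1] + base[1:]) / 2
        fine = trace_of(make_day_trace(fine_values, step_min=7.5))
        m_coarse = compute_mpg(coarse, meal(slot="breakfast", time=dt.time(8, 0)))
        m_fine = compute_mpg(fine, meal(slot="breakfast", time=dt.time(8, 0)))
        assert m_fine.mpg == pytest.approx(m_coarse.mpg)


# ---------------------------------------------------------------------------
# MAGE


def mage_oracle(values, ddof=1):
    """Independent brute-force MAGE: explicit plateau collapse and scan."""
    comp = []
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[j + 1] == values[i]:
            j += 1
        comp.append(values[i])
        i = j + 1
    tps = [
        comp[k]
        for k in range(1, len(comp) - 1)
        if (comp[k] - comp[k - 1]) * (comp[k + 1] - comp[k]) < 0
    ]
    sd = np.std(values, ddof=ddof)
    amps = [abs(tps[k + 1] - tps[k]) for k in range(len(tps) - 1)]
    qual = [a for a in amps if a > sd]
    return float(np.mean(qual)) if qual else None


class TestMage:
    def test_constant_trace_has_no_qualifying_excursion(self):
        assert compute_mage([5.0] * 96) is None

    def test_too_few_samples(self):
        assert compute_mage([5.0, 6.0]) is None

    def test_six_hour_sinusoid_gives_four(self):
        t = np.arange(96) * 0.25
        values = 5 + 2 * np.sin(2 * np.pi * t / 6.0)
        assert compute_mage(values) == pytest.approx(4.0, abs=1e-12)

    def test_only_large_bump_qualifies(self):
        # big bump of amplitude 3.0 and small bump of 0.5; day SD ~1.16
        values = np.array([5.0, 5.0, 8.0, 5.0, 5.5, 5.0])
        sd = np.std(values, ddof=1)
        assert 0.5 < sd < 3.0
        assert compute_mage(values) == pytest.approx(3.0)
        assert compute_mage(values) == pytest.approx(mage_oracle(values))

    def test_matches_brute_force_oracle_on_random_traces(self):
        # rounded random walks create plateaus and ties on purpose
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(3, 97))
            values = np.round(5 + np.cumsum(rng.normal(0, 0.4, size=n)), 1)
            got = compute_mage(values)
            want = mage_oracle(values)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=0)

    def test_first_direction_convention_subsets_both(self):
        rng = np.random.default_rng(5)
        values = 5 + np.cumsum(rng.normal(0, 0.5, size=96))
        both = compute_mage(values, direction="both")
        first = compute_mage(values, direction="first")
        assert first is not None and both is not None

    def test_plateau_collapses_to_single_turning_point(self):
        values = np.array([1.0, 2.0, 3.0, 3.0, 3.0, 2.0, 1.0])
        assert turning_points(values).tolist() == [3]  # midpoint of the plateau


# ---------------------------------------------------------------------------
# AUC24


class TestAuc24:
    def test_constant_day_is_120(self):
        day = make_day_trace([5.0] * 96)
        assert compute_auc24(day, dt.date(2024, 1, 1)) == pytest.approx(120.0, abs=1e-9)

    def test_linear_ramp_is_120(self):
        t = np.arange(97) * 0.25  # includes the closing midnight sample
        day = make_day_trace(4 + 2 * t / 24.0)
        assert compute_auc24(day, dt.date(2024, 1, 1)) == pytest.approx(120.0, abs=1e-9)

    def test_irregular_series_matches_hand_trapezoid(self):
        hours = np.array([0.0, 1.5, 4.0, 7.25, 9.0, 13.0, 15.5, 18.0, 21.0, 24.0])
        values = np.array([4.8, 5.2, 4.5, 6.9, 5.5, 7.2, 5.0, 6.1, 4.9, 4.7])
        start = dt.datetime(2024, 1, 1)
        day = pd.DataFrame(
            {"time": [start + dt.timedelta(hours=h) for h in hours], "glucose": values}
        )
        expected = sum(
            (values[i] + values[i + 1]) / 2 * (hours[i + 1] - hours[i])
            for i in range(len(hours) - 1)
        )
        got = compute_auc24(day, dt.date(2024, 1, 1), min_coverage=0.0)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_linearity_under_constant_shift(self):
        rng = np.random.default_rng(1)
        values = 5 + rng.random(96)
        day = make_day_trace(values)
        shifted = make_day_trace(values + 2.5)
        a = compute_auc24(day, dt.date(2024, 1, 1))
        b = compute_auc24(shifted, dt.date(2024, 1, 1))
        assert b - a == pytest.approx(24 * 2.5, abs=1e-9)

    def test_single_sample_is_missing(self):
        assert compute_auc24(make_day_trace([5.0]), dt.date(2024, 1, 1)) is None

    def test_low_coverage_is_missing(self):
        day = make_day_trace([5.0] * 30)  # 30/96 < 0.7
        assert compute_auc24(day, dt.date(2024, 1, 1)) is None


def test_day_shift_leaves_metrics_unchanged():
    rng = np.random.default_rng(3)
    values = 5 + np.cumsum(rng.normal(0, 0.2, 96))
    day1 = make_day_trace(values, date=dt.date(2024, 1, 1))
    day2 = make_day_trace(values, date=dt.date(2024, 1, 2))
    assert compute_auc24(day1, dt.date(2024, 1, 1)) == compute_auc24(day2, dt.date(2024, 1, 2))
    assert compute_mage(values) == compute_mage(values)


# ---------------------------------------------------------------------------
# Outcome-series assembly


class TestOutcomeSeries:
    def test_complete_participant_has_54_mpg_obs_per_arm(self, clean_participant):
        _, design, meals, trace = clean_participant
        series = build_outcome_series({"p1": trace}, {"p1": design}, meals)
        mpg = series[series["outcome"] == "MPG"]
        assert (mpg["x"] == 1).sum() == 54  # 3 sets x 6 days x 3 meals
        assert (mpg["x"] == 0).sum() == 54

    def test_washout_days_excluded(self, clean_participant):
        _, design, meals, trace = clean_participant
        series = build_outcome_series({"p1": trace}, {"p1": design}, meals)
        washout_dates = {d for p in design.periods if p.diet == "washout" for d in p.dates()}
        assert not set(series["date"]) & washout_dates

    def test_carb_labels_follow_period_halves(self, clean_participant):
        _, design, meals, trace = clean_participant
        series = build_outcome_series({"p1": trace}, {"p1": design}, meals)
        assert set(series["carb_pct"]) == {15.0, 25.0, 65.0, 75.0}
        mpg = series[series["outcome"] == "MPG"]
        assert mpg.groupby("carb_pct").size().tolist() == [27, 27, 27, 27]

    def test_fully_missed_day_dropped_only_for_daily_metrics(self, clean_participant):
        from dataclasses import replace

        _, design, meals, trace = clean_participant
        target = design.intervention_periods()[0].start_date
        edited = [
            replace(m, consumed=False) if m.date == target else m for m in meals
        ]
        series = build_outcome_series({"p1": trace}, {"p1": design}, edited)
        daily = series[series["outcome"].isin(["MAGE", "AUC24"])]
        assert target not in set(daily["date"])
        other = target + dt.timedelta(days=1)
        assert other in set(daily["date"])
        # MPG simply loses that day's three meals
        mpg = series[series["outcome"] == "MPG"]
        assert target not in set(mpg["date"])

    def test_observation_outside_any_period_errors(self, clean_participant):
        _, design, meals, trace = clean_participant
        stray = MealEvent(
            participant_id="p1",
            date=design.periods[-1].end_date + dt.timedelta(days=30),
            slot="lunch",
            first_bite_time=dt.time(12, 0),
            consumed=True,
        )
        with pytest.raises(ValidationError, match="outside any design period"):
            build_outcome_series({"p1": trace}, {"p1": design}, meals + [stray])

    def test_partially_missed_day_keeps_daily_metrics(self, clean_participant):
        from dataclasses import replace

        _, design, meals, trace = clean_participant
        target = design.intervention_periods()[0].start_date
        edited = [
            replace(m, consumed=False) if (m.date == target and m.slot == "lunch") else m
            for m in meals
        ]
        series = build_outcome_series({"p1": trace}, {"p1": design}, edited)
        daily = series[series["outcome"] == "AUC24"]
        assert target in set(daily["date"])
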
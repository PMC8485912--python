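"""Glycemic outcome metrics: per-meal MPG, per-day MAGE and AUC24.

Definitions
-----------
MPG
    Maximum postprandial glucose: the peak CGM value in the half-open
    window from a meal's first bite to 3 h later, truncated at the next
    meal's first bite when the gap is shorter. A sample exactly at the
    next meal's start belongs to the next meal.
MAGE
    Mean amplitude of glycemic excursions: the arithmetic mean of the
    absolute differences between consecutive peaks and nadirs of a day's
    trace, keeping only excursions whose amplitude exceeds 1 SD of that
    day's glucose values.
AUC24
    Area under the glucose–time curve from 00:00 to 24:00 (mmol/L·h),
    trapezoidal over the observed samples with boundary gaps closed by
    constant extrapolation of the first/last sample.

Missing-data rules: the MPG of a missed (not-consumed) meal is never used;
a day on which all three intervention meals were missed contributes no
MAGE or AUC24 observation; days with insufficient CGM coverage are
missing.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from nof1cgm.types import (
    INTERVENTION_DIETS,
    DIET_LFHC,
    GlucoseTrace,
    MealEvent,
    ValidationError,
)

logger = logging.getLogger("nof1cgm")

MPG_WINDOW = dt.timedelta(hours=3)

#: Expected number of 15-min samples in a full day.
SAMPLES_PER_DAY = 96

#: Minimum fraction of the day's expected samples for MAGE/AUC24.
DEFAULT_MIN_COVERAGE = 0.7


@dataclass(frozen=True)
class MealMetric:
    participant_id: str
    date: dt.date
    slot: str
    mpg: float | None
    window: tuple  # (start, end) datetimes, half-open


@dataclass(frozen=True)
class DailyMetric:
    participant_id: str
    date: dt.date
    mage: float | None
    auc24: float | None
    n_valid_meals: int
    coverage_fraction: float


# ---------------------------------------------------------------------------
# MPG


def compute_mpg(trace: GlucoseTrace, meal: MealEvent, next_meal: MealEvent | None = None) -> MealMetric | None:
    """MPG for one consumed meal; ``None`` for a missed meal.

    The window is ``[first_bite, first_bite + 3 h)`` truncated at the next
    meal's first bite. Ties in the maximum take the earliest timestamp.
    """
    if not meal.consumed:
        return None
    start = meal.first_bite
    end = start + MPG_WINDOW
    if next_meal is not None and next_meal.first_bite < end:
        end = next_meal.first_bite
    window = trace.between(start, end, closed="left")
    if window.empty:
        logger.warning(
            "compute_mpg: no CGM samples for participant %s, %s %s",
            meal.participant_id, meal.date, meal.slot,
        )
        mpg = None
    else:
        mpg = float(window["glucose"].max())
    return MealMetric(
        participant_id=meal.participant_id,
        date=meal.date,
        slot=meal.slot,
        mpg=mpg,
        window=(start, end),
    )


# ---------------------------------------------------------------------------
# MAGE


def _collapse_plateaus(values: np.ndarray):
    """Collapse runs of equal consecutive values to their midpoint index.

    Returns (indices, values) of the compressed series.
    """
    n = len(values)
    idx = []
    vals = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        idx.append((i + j) // 2)
        vals.append(values[i])
        i = j + 1
    return np.asarray(idx), np.asarray(vals, dtype=float)


def turning_points(values: np.ndarray):
    """Indices (into the original series) of local extrema.

    Plateaus are collapsed to a single representative at their midpoint;
    a turning point is a strict sign change of successive differences.
    Series endpoints are not turning points.
    """
    idx, vals = _collapse_plateaus(np.asarray(values, dtype=float))
    if len(vals) < 3:
        return np.asarray([], dtype=int)
    d = np.sign(np.diff(vals))
    turns = np.where(d[1:] != d[:-1])[0] + 1
    return idx[turns]


def compute_mage(
    day_values,
    *,
    sd_ddof: int = 1,
    direction: str = "both",
    median_filter: bool = False,
) -> float | None:
    """MAGE of one calendar day's glucose values (time-ordered, mmol/L).

    Consecutive peak/nadir amplitudes exceeding 1 SD of the day's values
    qualify; MAGE is the mean of the qualifying absolute amplitudes.
    ``direction="both"`` counts every consecutive peak↔nadir pair;
    ``direction="first"`` is the classic convention that counts only
    excursions in the direction of the first qualifying one. Returns
    ``None`` when fewer than 3 samples are present or no excursion
    qualifies (including a constant day, where SD = 0).
    """
    if direction not in ("both", "first"):
        raise ValidationError(f"direction must be 'both' or 'first', got {direction!r}")
    values = np.asarray(day_values, dtype=float)
    if len(values) < 3:
        return None
    if median_filter and len(values) >= 3:
        padded = np.concatenate([values[:1], values, values[-1:]])
        values = np.median(
            np.column_stack([padded[:-2], padded[1:-1], padded[2:]]), axis=1
        )
    sd = float(np.std(values, ddof=sd_ddof))
    tp = turning_points(values)
    if len(tp) < 2:
        return None
    amps = np.diff(values[tp])  # signed consecutive peak<->nadir differences
    qualifying = amps[np.abs(amps) > sd]
    if len(qualifying) == 0:
        return None
    if direction == "first":
        qualifying = qualifying[np.sign(qualifying) == np.sign(qualifying[0])]
    return float(np.mean(np.abs(qualifying)))


# ---------------------------------------------------------------------------
# AUC24


def compute_auc24(day_samples: pd.DataFrame, date: dt.date, *, min_coverage: float = DEFAULT_MIN_COVERAGE) -> float | None:
    """AUC 00:00–24:00 in mmol/L·h from a day slice of a trace.

    ``day_samples`` holds columns ``time``/``glucose`` within the closed
    interval [00:00, 24:00] of ``date`` (the closing midnight sample may be
    the next day's first reading). The integral is trapezoidal over the
    observed samples, with the first/last value carried to the day
    boundaries when the edge samples are missing. Returns ``None`` with a
    single sample or when coverage is below ``min_coverage``.
    """
    if len(day_samples) < 2:
        return None
    if day_coverage(day_samples, date) < min_coverage:
        return None
    start = dt.datetime.combine(date, dt.time(0, 0))
    hours = (day_samples["time"] - start).dt.total_seconds().to_numpy() / 3600.0
    values = day_samples["glucose"].to_numpy(dtype=float)
    if hours[0] < 0 or hours[-1] > 24:
        raise ValidationError(f"day slice extends outside {date}")
    if hours[0] > 0:
        hours = np.concatenate([[0.0], hours])
        values = np.concatenate([[values[0]], values])
    if hours[-1] < 24:
        hours = np.concatenate([hours, [24.0]])
        values = np.concatenate([values, [values[-1]]])
    return float(np.trapezoid(values, hours))


def day_coverage(day_samples: pd.DataFrame, date: dt.date) -> float:
    """Fraction of the expected 96 within-day samples that are present."""
    start = dt.datetime.combine(date, dt.time(0, 0))
    end = start + dt.timedelta(days=1)
    n = int(((day_samples["time"] >= start) & (day_samples["time"] < end)).sum())
    return n / SAMPLES_PER_DAY


# ---------------------------------------------------------------------------
# Per-participant assembly


def compute_meal_metrics(trace: GlucoseTrace, meals) -> list:
    """MealMetrics for one participant's consumed meals, in meal order."""
    meals = sorted(
        (m for m in meals if m.participant_id == trace.participant_id),
        key=lambda m: m.first_bite,
    )
    out = []
    for meal, nxt in zip(meals, list(meals[1:]) + [None]):
        metric = compute_mpg(trace, meal, nxt)
        if metric is not None:
            out.append(metric)
    return out


def compute_daily_metrics(
    trace: GlucoseTrace,
    meals,
    dates,
    *,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    mage_direction: str = "both",
    mage_sd_ddof: int = 1,
) -> list:
    """DailyMetrics (MAGE + AUC24) for the given dates of one participant.

    A fully-missed day (no consumed meals) yields missing MAGE/AUC24 per
    the missing-data rule; partially-missed days are retained.
    """
    by_date: dict = {}
    for m in meals:
        if m.participant_id == trace.participant_id:
            by_date.setdefault(m.date, []).append(m)
    out = []
    for date in dates:
        day = trace.day_slice(date)
        coverage = day_coverage(day, date)
        n_valid = sum(1 for m in by_date.get(date, []) if m.consumed)
        if n_valid == 0:
            mage = auc = None
        else:
            start = dt.datetime.combine(date, dt.time(0, 0))
            within = day.loc[day["time"] < start + dt.timedelta(days=1)]
            if coverage < min_coverage or len(within) < 3:
                mage = None
            else:
                mage = compute_mage(
                    within["glucose"].to_numpy(),
                    direction=mage_direction,
                    sd_ddof=mage_sd_ddof,
                )
            auc = compute_auc24(day, date, min_coverage=min_coverage)
        out.append(
            DailyMetric(
                participant_id=trace.participant_id,
                date=date,
                mage=mage,
                auc24=auc,
                n_valid_meals=n_valid,
                coverage_fraction=coverage,
            )
        )
    return out


def build_outcome_series(
    traces: dict,
    designs: dict,
    meals,
    *,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    mage_direction: str = "both",
    mage_sd_ddof: int = 1,
) -> pd.DataFrame:
    """Treatment-labelled outcome observations for every participant.

    Returns a tidy frame with columns ``participant_id, outcome, value, x,
    set_index, carb_pct, date, slot`` where ``x`` codes the diet (HF-LC = 0
    reference, LF-HC = 1) and ``carb_pct`` is the day's carbohydrate %E.
    Washout days are excluded; MPG has one row per consumed meal with
    usable CGM, MAGE/AUC24 one row per intervention day that is not
    fully-missed.
    """
    rows = []
    for pid in sorted(traces):
        trace = traces[pid]
        if pid not in designs:
            raise ValidationError(f"participant {pid} has CGM data but no design")
        design = designs[pid]
        pid_meals = [m for m in meals if m.participant_id == pid]
        for m in pid_meals:
            if design.period_for_date(m.date) is None:
                raise ValidationError(
                    f"participant {pid}: meal on {m.date} outside any design period"
                )

        meal_metrics = compute_meal_metrics(trace, pid_meals)
        for metric in meal_metrics:
            period = design.period_for_date(metric.date)
            if period.diet not in INTERVENTION_DIETS or metric.mpg is None:
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "outcome": "MPG",
                    "value": metric.mpg,
                    "x": int(period.diet == DIET_LFHC),
                    "set_index": period.set_index,
                    "carb_pct": period.carb_for_date(metric.date),
                    "date": metric.date,
                    "slot": metric.slot,
                }
            )

        intervention_dates = [
            d for p in design.intervention_periods() for d in p.dates()
        ]
        daily = compute_daily_metrics(
            trace,
            pid_meals,
            intervention_dates,
            min_coverage=min_coverage,
            mage_direction=mage_direction,
            mage_sd_ddof=mage_sd_ddof,
        )
        for metric in daily:
            period = design.period_for_date(metric.date)
            base = {
                "participant_id": pid,
                "x": int(period.diet == DIET_LFHC),
                "set_index": period.set_index,
                "carb_pct": period.carb_for_date(metric.date),
                "date": metric.date,
                "slot": "",
            }
            if metric.mage is not None:
                rows.append({**base, "outcome": "MAGE", "value": metric.mage})
            if metric.auc24 is not None:
                rows.append({**base, "outcome": "AUC24", "value": metric.auc24})

    columns = ["participant_id", "outcome", "value", "x", "set_index", "carb_pct", "date", "slot"]
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values(
        ["participant_id", "outcome", "date", "slot"], kind="mergesort"
    ).reset_index(drop=True)


def valid_data_fraction(trace: GlucoseTrace, design, meals) -> float:
    """Proportion of scheduled intervention meals with usable CGM data.

    A meal is usable when it was consumed and its MPG window contains at
    least one CGM sample.
    """
    scheduled = [
        m
        for m in meals
        if m.participant_id == trace.participant_id
        and (p := design.period_for_date(m.date)) is not None
        and p.diet in INTERVENTION_DIETS
    ]
    if not scheduled:
        return 0.0
    scheduled.sort(key=lambda m: m.first_bite)
    usable = 0
    for meal, nxt in zip(scheduled, list(scheduled[1:]) + [None]):
        metric = compute_mpg(trace, meal, nxt)
        if metric is not None and metric.mpg is not None:
            usable += 1
    return usable / len(scheduled)
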
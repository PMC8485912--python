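"""Core domain types shared across the package.

Glucose is always held internally in mmol/L; timestamps are timezone-naive
local time and a "day" is the calendar day 00:00–24:00 (the AUC24 window).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: mg/dL per mmol/L for glucose; fixed at exactly 18.0.
MGDL_PER_MMOL = 18.0

#: Physiologically plausible CGM bounds after unit normalisation (mmol/L).
GLUCOSE_MIN = 0.0
GLUCOSE_MAX = 30.0

DIET_LFHC = "LF-HC"
DIET_HFLC = "HF-LC"
DIET_WASHOUT = "washout"
INTERVENTION_DIETS = (DIET_HFLC, DIET_LFHC)

MEAL_SLOTS = ("breakfast", "lunch", "dinner")

#: Scheduled serving windows per slot (local time).
MEAL_WINDOWS = {
    "breakfast": (dt.time(7, 0), dt.time(9, 0)),
    "lunch": (dt.time(11, 0), dt.time(13, 0)),
    "dinner": (dt.time(17, 0), dt.time(19, 0)),
}

OUTCOMES = ("MPG", "MAGE", "AUC24")

#: Protein contribution is fixed by design; carbohydrate + fat fill the rest.
PROTEIN_PCT = 15.0


class ValidationError(ValueError):
    """An input violated a schema or a domain invariant."""


class InsufficientDataError(ValueError):
    """Too few observations to fit the requested model."""


def mgdl_to_mmol(value):
    """Convert glucose from mg/dL to mmol/L (divide by exactly 18.0)."""
    return np.asarray(value, dtype=float) / MGDL_PER_MMOL if np.ndim(value) else float(value) / MGDL_PER_MMOL


def mmol_to_mgdl(value):
    """Convert glucose from mmol/L to mg/dL (multiply by exactly 18.0)."""
    return np.asarray(value, dtype=float) * MGDL_PER_MMOL if np.ndim(value) else float(value) * MGDL_PER_MMOL


def mgdl_min_to_mmol_h(value):
    """Convert a glucose AUC from mg/dL·min to mmol/L·h."""
    return float(value) / MGDL_PER_MMOL / 60.0


@dataclass(frozen=True)
class Thresholds:
    """Clinically meaningful between-diet differences (delta) per outcome.

    Defaults: 0.167 mmol/L for the maximum postprandial glucose, 0.072
    mmol/L for the mean amplitude of glycemic excursions and 13.889
    mmol/L·h for the 24-h area under the glucose curve.
    """

    mpg: float = 0.167
    mage: float = 0.072
    auc24: float = 13.889

    def __post_init__(self):
        for name in ("mpg", "mage", "auc24"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"Thresholds.{name} must be > 0")

    def for_outcome(self, outcome: str) -> float:
        try:
            return {"MPG": self.mpg, "MAGE": self.mage, "AUC24": self.auc24}[outcome]
        except KeyError:
            raise ValidationError(f"unknown outcome {outcome!r}") from None

    @classmethod
    def from_mgdl(cls, mpg_mgdl: float, mage_mgdl: float, auc24_mgdl_min: float) -> "Thresholds":
        """Build thresholds from mg/dL (AUC in mg/dL·min), rounded to 3 decimals."""
        return cls(
            mpg=round(mgdl_to_mmol(mpg_mgdl), 3),
            mage=round(mgdl_to_mmol(mage_mgdl), 3),
            auc24=round(mgdl_min_to_mmol_h(auc24_mgdl_min), 3),
        )


@dataclass(frozen=True)
class MealEvent:
    """One scheduled meal for one participant-day."""

    participant_id: str
    date: dt.date
    slot: str
    first_bite_time: dt.time
    consumed: bool = True

    def __post_init__(self):
        if self.slot not in MEAL_SLOTS:
            raise ValidationError(
                f"MealEvent.slot must be one of {MEAL_SLOTS}, got {self.slot!r}"
            )

    @property
    def first_bite(self) -> dt.datetime:
        return dt.datetime.combine(self.date, self.first_bite_time)

    def in_scheduled_window(self) -> bool:
        lo, hi = MEAL_WINDOWS[self.slot]
        return lo <= self.first_bite_time <= hi


@dataclass(frozen=True)
class Period:
    """One 6-day (by default) diet period within a participant's design.

    ``carb_pct``/``fat_pct`` hold one value per day; protein is fixed at
    15 %E so carbohydrate + fat must equal 85 each day.
    """

    set_index: int  # 0 for the leading washout, 1..n_sets for pairs
    period_index: int  # position within its set (1-based)
    diet: str
    carb_pct: tuple
    fat_pct: tuple
    start_date: dt.date
    days: int

    def __post_init__(self):
        if self.diet not in (DIET_LFHC, DIET_HFLC, DIET_WASHOUT):
            raise ValidationError(f"unknown diet label {self.diet!r}")
        if len(self.carb_pct) != self.days or len(self.fat_pct) != self.days:
            raise ValidationError(
                f"Period.carb_pct/fat_pct must have one value per day "
                f"({self.days}), got {len(self.carb_pct)}/{len(self.fat_pct)}"
            )
        for c, f in zip(self.carb_pct, self.fat_pct):
            if abs(c + f + PROTEIN_PCT - 100.0) > 1e-9:
                raise ValidationError(
                    f"macronutrient percentages must sum to 100 with protein "
                    f"{PROTEIN_PCT}: carb={c}, fat={f}"
                )

    @property
    def end_date(self) -> dt.date:
        """First date after the period (exclusive end)."""
        return self.start_date + dt.timedelta(days=self.days)

    def dates(self):
        return [self.start_date + dt.timedelta(days=i) for i in range(self.days)]

    def contains(self, date: dt.date) -> bool:
        return self.start_date <= date < self.end_date

    def carb_for_date(self, date: dt.date) -> float:
        if not self.contains(date):
            raise ValidationError(f"{date} outside period starting {self.start_date}")
        return float(self.carb_pct[(date - self.start_date).days])


@dataclass(frozen=True)
class StudyDesign:
    """Ordered diet periods for one participant."""

    participant_id: str
    periods: tuple

    def __post_init__(self):
        object.__setattr__(self, "periods", tuple(self.periods))
        self.validate()

    def validate(self) -> None:
        prev_end = None
        by_set: dict = {}
        for p in self.periods:
            if prev_end is not None and p.start_date < prev_end:
                raise ValidationError(
                    f"participant {self.participant_id}: overlapping periods at "
                    f"{p.start_date}"
                )
            prev_end = p.end_date
            if p.diet in INTERVENTION_DIETS:
                by_set.setdefault(p.set_index, []).append(p)
        for set_index, periods in by_set.items():
            diets = sorted(p.diet for p in periods)
            if diets != sorted(INTERVENTION_DIETS):
                raise ValidationError(
                    f"participant {self.participant_id}, set {set_index}: each "
                    f"set must contain exactly one {DIET_LFHC} and one "
                    f"{DIET_HFLC} period, got {diets}"
                )
            for p in periods:
                if p.days != 6:
                    raise ValidationError(
                        f"participant {self.participant_id}, set {set_index}: "
                        f"intervention periods must be 6 days, got {p.days}"
                    )

    @property
    def n_sets(self) -> int:
        return len({p.set_index for p in self.periods if p.diet in INTERVENTION_DIETS})

    def period_for_date(self, date: dt.date):
        for p in self.periods:
            if p.contains(date):
                return p
        return None

    def intervention_periods(self):
        return [p for p in self.periods if p.diet in INTERVENTION_DIETS]

    def all_dates(self):
        out = []
        for p in self.periods:
            out.extend(p.dates())
        return out

    def truncated(self, n_sets: int) -> "StudyDesign":
        """Design keeping the leading washout and the first ``n_sets`` pairs."""
        keep = tuple(p for p in self.periods if p.set_index <= n_sets)
        return replace(self, periods=keep)


@dataclass(frozen=True)
class ParticipantMeta:
    """Analysis-relevant participant metadata and data-quality flags."""

    participant_id: str
    age: float
    sex: str  # "M" / "F"
    bmi: float
    completed_all_periods: bool = True
    valid_data_fraction: float = 1.0
    chronic_disease_or_medication: bool = False

    def __post_init__(self):
        if not 0.0 <= self.valid_data_fraction <= 1.0:
            raise ValidationError(
                f"ParticipantMeta.valid_data_fraction must be in [0, 1], got "
                f"{self.valid_data_fraction}"
            )
        if self.sex not in ("M", "F"):
            raise ValidationError(f"ParticipantMeta.sex must be 'M' or 'F', got {self.sex!r}")


@dataclass
class GlucoseTrace:
    """Timestamped interstitial glucose series for one participant.

    ``samples`` is a DataFrame with columns ``time`` (datetime64, strictly
    increasing) and ``glucose`` (mmol/L). Nominal spacing is 15 min; gaps
    are allowed.
    """

    participant_id: str
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        req = {"time", "glucose"}
        if not req.issubset(self.samples.columns):
            raise ValidationError(f"GlucoseTrace.samples needs columns {sorted(req)}")
        self.samples = self.samples[["time", "glucose"]].reset_index(drop=True)
        t = self.samples["time"].to_numpy()
        if len(t) > 1 and not (t[1:] > t[:-1]).all():
            raise ValidationError(
                f"participant {self.participant_id}: timestamps must be "
                f"strictly increasing (duplicates or disorder found)"
            )
        g = self.samples["glucose"].to_numpy(dtype=float)
        if len(g) and (g <= GLUCOSE_MIN).any():
            raise ValidationError(
                f"participant {self.participant_id}: non-positive glucose value"
            )
        if len(g) and (g >= GLUCOSE_MAX).any():
            raise ValidationError(
                f"participant {self.participant_id}: glucose >= {GLUCOSE_MAX} "
                f"mmol/L — check units"
            )

    def __len__(self) -> int:
        return len(self.samples)

    def between(self, start: dt.datetime, end: dt.datetime, closed: str = "left") -> pd.DataFrame:
        """Samples in [start, end) (``closed='left'``) or [start, end]."""
        t = self.samples["time"]
        if closed == "left":
            mask = (t >= start) & (t < end)
        elif closed == "both":
            mask = (t >= start) & (t <= end)
        else:
            raise ValueError("closed must be 'left' or 'both'")
        return self.samples.loc[mask]

    def day_slice(self, date: dt.date) -> pd.DataFrame:
        """Samples of the calendar day, including the closing midnight sample."""
        start = dt.datetime.combine(date, dt.time(0, 0))
        return self.between(start, start + dt.timedelta(days=1), closed="both")
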
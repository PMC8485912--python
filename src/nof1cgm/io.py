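"""Readers and writers for the canonical on-disk artifacts.

Canonical formats are plain CSV with a header:

* ``cgm.csv`` — participant_id, timestamp, glucose[, unit]
* ``meals.csv`` — participant_id, date, slot, time, consumed
* ``design.csv`` — participant_id, set, period, diet, carb_pct, fat_pct,
  start_date, days (carb/fat per-day values joined with ``/``)
* ``meta.csv`` — participant_id, age, sex, bmi, completed_all_periods,
  valid_data_fraction, chronic_disease_or_medication

All glucose is normalised to mmol/L on read (mg/dL divided by exactly
18.0). Reader output ordering is deterministic and independent of input
row order. A best-effort reader for FreeStyle-Libre-style exports maps the
device schema onto the canonical one.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from nof1cgm.types import (
    DIET_HFLC,
    DIET_LFHC,
    DIET_WASHOUT,
    MEAL_SLOTS,
    GlucoseTrace,
    MealEvent,
    ParticipantMeta,
    Period,
    StudyDesign,
    ValidationError,
    mgdl_to_mmol,
)

logger = logging.getLogger("nof1cgm")

_UNITS = {"mmol/L", "mg/dL"}


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str}, skipinitialspace=True)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def _parse_timestamps(values: pd.Series, path) -> pd.Series:
    parsed = pd.to_datetime(values, errors="coerce", format="mixed")
    if parsed.isna().any():
        row = int(parsed.index[parsed.isna()][0])
        raise ValidationError(
            f"{path}: unparseable timestamp {values.iloc[row]!r} at row {row + 2}"
        )
    return parsed


# ---------------------------------------------------------------------------
# CGM traces


def read_cgm(path, unit_hint: str = "auto") -> dict:
    """Read a canonical CGM CSV into ``{participant_id: GlucoseTrace}``.

    ``unit_hint`` is one of ``"mmol/L"``, ``"mg/dL"`` or ``"auto"``; under
    ``auto`` a per-row ``unit`` column is required — the unit is never
    silently guessed from magnitudes.
    """
    if unit_hint not in _UNITS | {"auto"}:
        raise ValidationError(f"unit_hint must be one of {_UNITS | {'auto'}}, got {unit_hint!r}")
    try:
        df = _read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("read_cgm: %s is empty, returning no traces", path)
        return {}
    if df.empty:
        logger.warning("read_cgm: %s is empty, returning no traces", path)
        return {}
    _require_columns(df, ["participant_id", "timestamp", "glucose"], path)
    df["timestamp"] = _parse_timestamps(df["timestamp"], path)
    glucose = pd.to_numeric(df["glucose"], errors="coerce")
    if glucose.isna().any():
        row = int(glucose.index[glucose.isna()][0])
        raise ValidationError(f"{path}: non-numeric glucose at row {row + 2}")
    if (glucose < 0).any():
        row = int(glucose.index[glucose < 0][0])
        raise ValidationError(f"{path}: negative glucose at row {row + 2}")

    if unit_hint == "auto":
        if "unit" not in df.columns:
            raise ValidationError(
                f"{path}: unit_hint='auto' requires a 'unit' column; refusing "
                f"to guess glucose units"
            )
        units = df["unit"].astype(str).str.strip()
        bad = ~units.isin(_UNITS)
        if bad.any():
            row = int(units.index[bad][0])
            raise ValidationError(
                f"{path}: unknown unit {units.iloc[row]!r} at row {row + 2} "
                f"(expected one of {sorted(_UNITS)})"
            )
        values = np.where(units == "mg/dL", mgdl_to_mmol(glucose.to_numpy()), glucose.to_numpy())
    elif unit_hint == "mg/dL":
        values = mgdl_to_mmol(glucose.to_numpy())
    else:
        values = glucose.to_numpy(dtype=float)
    df = df.assign(glucose=values)

    traces = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        if grp["timestamp"].duplicated().any():
            t = grp.loc[grp["timestamp"].duplicated(), "timestamp"].iloc[0]
            raise ValidationError(
                f"{path}: participant {pid}: duplicate timestamp {t}"
            )
        traces[str(pid)] = GlucoseTrace(
            participant_id=str(pid),
            samples=grp.rename(columns={"timestamp": "time"})[["time", "glucose"]],
        )
    return traces


def write_cgm(traces: dict, path) -> None:
    frames = []
    for pid in sorted(traces):
        t = traces[pid]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "timestamp": t.samples["time"].dt.strftime("%Y-%m-%d %H:%M:%S"),
                    "glucose": t.samples["glucose"].round(6),
                    "unit": "mmol/L",
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["participant_id", "timestamp", "glucose", "unit"]
    )
    out.to_csv(path, index=False)


_LIBRE_TIME_COLUMNS = ("Device Timestamp", "Meter Timestamp", "Time")
_LIBRE_GLUCOSE_COLUMNS = (
    ("Historic Glucose mmol/L", "mmol/L"),
    ("Historic Glucose mg/dL", "mg/dL"),
    ("Glucose (mmol/L)", "mmol/L"),
    ("Glucose (mg/dL)", "mg/dL"),
)


def read_libre_export(path, participant_id: str) -> dict:
    """Best-effort reader for a FreeStyle-Libre-style sensor export.

    Tolerates extra device columns; keeps only the historic-glucose rows
    and maps them onto the canonical schema. The exact export schema varies
    by device software version, so this is a convenience, not a contract.
    """
    raw = pd.read_csv(path)
    time_col = next((c for c in _LIBRE_TIME_COLUMNS if c in raw.columns), None)
    glu = next(((c, u) for c, u in _LIBRE_GLUCOSE_COLUMNS if c in raw.columns), None)
    if time_col is None or glu is None:
        raise ValidationError(
            f"{path}: unrecognised sensor-export layout (no timestamp/glucose "
            f"column found)"
        )
    col, unit = glu
    df = raw[[time_col, col]].dropna()
    df = pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": _parse_timestamps(df[time_col], path),
            "glucose": pd.to_numeric(df[col], errors="coerce"),
            "unit": unit,
        }
    ).dropna()
    values = df["glucose"].to_numpy(dtype=float)
    if unit == "mg/dL":
        values = mgdl_to_mmol(values)
    df = df.assign(glucose=values).sort_values("timestamp", kind="mergesort")
    df = df.drop_duplicates(subset="timestamp", keep="first")
    return {
        participant_id: GlucoseTrace(
            participant_id=participant_id,
            samples=df.rename(columns={"timestamp": "time"})[["time", "glucose"]],
        )
    }


# ---------------------------------------------------------------------------
# Meal logs


def _parse_bool(series: pd.Series, path, column: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    vals = series.astype(str).str.strip().str.lower().map(mapping)
    if vals.isna().any():
        row = int(vals.index[vals.isna()][0])
        raise ValidationError(
            f"{path}: unparseable boolean {series.iloc[row]!r} in column "
            f"{column!r} at row {row + 2}"
        )
    return vals


def read_meal_log(path, designs: dict | None = None) -> list:
    """Read ``meals.csv`` into a list of :class:`MealEvent`.

    With a design calendar (``designs``), meals absent from the file are
    interpreted as not consumed and filled in at the slot's scheduled time;
    without one, an incomplete participant-day is an error.
    """
    df = _read_csv(path)
    _require_columns(df, ["participant_id", "date", "slot", "time", "consumed"], path)
    slots = df["slot"].astype(str).str.strip()
    bad = ~slots.isin(MEAL_SLOTS)
    if bad.any():
        row = int(slots.index[bad][0])
        raise ValidationError(
            f"{path}: unknown meal slot {slots.iloc[row]!r} at row {row + 2} "
            f"(expected one of {MEAL_SLOTS})"
        )
    dup = df.duplicated(subset=["participant_id", "date", "slot"])
    if dup.any():
        r = df.loc[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate meal row for participant {r['participant_id']}, "
            f"{r['date']} {r['slot']}"
        )
    dates = _parse_timestamps(df["date"], path).dt.date
    times = _parse_timestamps(df["time"], path).dt.time
    consumed = _parse_bool(df["consumed"], path, "consumed")

    events = [
        MealEvent(
            participant_id=str(pid),
            date=date,
            slot=slot,
            first_bite_time=t,
            consumed=bool(c),
        )
        for pid, date, slot, t, c in zip(df["participant_id"], dates, slots, times, consumed)
    ]

    seen = {(e.participant_id, e.date, e.slot) for e in events}
    if designs is not None:
        from nof1cgm.simulate import DEFAULT_MEAL_TIMES  # scheduled slot times

        for pid in sorted(designs):
            for date in designs[pid].all_dates():
                for slot in MEAL_SLOTS:
                    if (pid, date, slot) not in seen:
                        events.append(
                            MealEvent(
                                participant_id=pid,
                                date=date,
                                slot=slot,
                                first_bite_time=DEFAULT_MEAL_TIMES[slot],
                                consumed=False,
                            )
                        )
    else:
        counts = {}
        for e in events:
            counts.setdefault((e.participant_id, e.date), set()).add(e.slot)
        for (pid, date), have in sorted(counts.items()):
            if len(have) < len(MEAL_SLOTS):
                raise ValidationError(
                    f"{path}: participant {pid}, {date}: only slots "
                    f"{sorted(have)} present and no design calendar supplied "
                    f"to infer missed meals"
                )
    events.sort(key=lambda e: (e.participant_id, e.date, MEAL_SLOTS.index(e.slot)))
    return events


def write_meal_log(events, path) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in events],
            "date": [e.date.isoformat() for e in events],
            "slot": [e.slot for e in events],
            "time": [e.first_bite_time.strftime("%H:%M") for e in events],
            "consumed": [e.consumed for e in events],
        }
    )
    df.to_csv(path, index=False)


def validate_meal_schedule(events) -> list:
    """Return the events whose first bite falls outside the slot's window."""
    return [e for e in events if not e.in_scheduled_window()]


# ---------------------------------------------------------------------------
# Study designs


def _split_pcts(value, days: int, path):
    parts = [float(v) for v in str(value).split("/")]
    if len(parts) == 1:
        parts = parts * days
    if len(parts) != days:
        raise ValidationError(
            f"{path}: carb/fat percentage list {value!r} does not match "
            f"period length {days}"
        )
    return tuple(parts)


def read_design(path) -> dict:
    """Read ``design.csv`` into ``{participant_id: StudyDesign}``."""
    df = _read_csv(path)
    _require_columns(
        df,
        ["participant_id", "set", "period", "diet", "carb_pct", "fat_pct", "start_date", "days"],
        path,
    )
    diets = df["diet"].astype(str).str.strip()
    bad = ~diets.isin({DIET_LFHC, DIET_HFLC, DIET_WASHOUT})
    if bad.any():
        row = int(diets.index[bad][0])
        raise ValidationError(f"{path}: unknown diet label {diets.iloc[row]!r} at row {row + 2}")
    dates = _parse_timestamps(df["start_date"], path).dt.date
    designs = {}
    for pid, grp in df.assign(diet=diets, start_date=dates).groupby("participant_id", sort=True):
        grp = grp.sort_values("start_date", kind="mergesort")
        periods = []
        for _, r in grp.iterrows():
            days = int(r["days"])
            periods.append(
                Period(
                    set_index=int(r["set"]),
                    period_index=int(r["period"]),
                    diet=r["diet"],
                    carb_pct=_split_pcts(r["carb_pct"], days, path),
                    fat_pct=_split_pcts(r["fat_pct"], days, path),
                    start_date=r["start_date"],
                    days=days,
                )
            )
        designs[str(pid)] = StudyDesign(participant_id=str(pid), periods=tuple(periods))
    return designs


def write_design(designs: dict, path) -> None:
    rows = []
    for pid in sorted(designs):
        for p in designs[pid].periods:
            rows.append(
                {
                    "participant_id": pid,
                    "set": p.set_index,
                    "period": p.period_index,
                    "diet": p.diet,
                    "carb_pct": "/".join(f"{v:g}" for v in p.carb_pct),
                    "fat_pct": "/".join(f"{v:g}" for v in p.fat_pct),
                    "start_date": p.start_date.isoformat(),
                    "days": p.days,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Participant metadata


def read_meta(path) -> dict:
    df = _read_csv(path)
    _require_columns(
        df,
        ["participant_id", "age", "sex", "bmi", "completed_all_periods",
         "valid_data_fraction", "chronic_disease_or_medication"],
        path,
    )
    completed = _parse_bool(df["completed_all_periods"], path, "completed_all_periods")
    chronic = _parse_bool(df["chronic_disease_or_medication"], path, "chronic_disease_or_medication")
    out = {}
    for i, r in df.iterrows():
        out[str(r["participant_id"])] = ParticipantMeta(
            participant_id=str(r["participant_id"]),
            age=float(r["age"]),
            sex=str(r["sex"]).strip(),
            bmi=float(r["bmi"]),
            completed_all_periods=bool(completed.iloc[i]),
            valid_data_fraction=float(r["valid_data_fraction"]),
            chronic_disease_or_medication=bool(chronic.iloc[i]),
        )
    return dict(sorted(out.items()))


def write_meta(meta: dict, path) -> None:
    rows = [
        {
            "participant_id": m.participant_id,
            "age": m.age,
            "sex": m.sex,
            "bmi": round(m.bmi, 3),
            "completed_all_periods": m.completed_all_periods,
            "valid_data_fraction": round(m.valid_data_fraction, 6),
            "chronic_disease_or_medication": m.chronic_disease_or_medication,
        }
        for m in (meta[k] for k in sorted(meta))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Results + run manifest


def config_hash(config: dict) -> str:
    """Stable sha256 of a JSON-serialisable config."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def write_results(results: dict, outdir, config: dict | None = None, seeds=None) -> Path:
    """Write result tables plus a JSON run manifest; returns the manifest path.

    ``results`` maps a table name to a DataFrame; floats are written with 6
    decimals so that write→read round-trips are stable to 1e-6.
    """
    from nof1cgm import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "nof1cgm",
        "version": __version__,
        "config_hash": config_hash(config or {}),
        "seeds": seeds,
        "tables": {},
    }
    for name, df in results.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6f")
        manifest["tables"][name] = {
            "rows": int(len(df)),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


class JsonlLogger:
    """Minimal structured (JSON-lines) run log."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def log(self, event: str, **fields) -> None:
        rec = {"ts": dt.datetime.now().isoformat(timespec="seconds"), "event": event}
        rec.update(fields)
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")
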
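"""Synthetic cohort generator for n-of-1 diet-crossover CGM studies.

Emulates the data-generating structure the analysis assumes: a cohort of
participants each completing a leading washout and three randomized
LF-HC/HF-LC pairs of 6-day diet periods (block-of-2 randomisation), three
scheduled meals per day, a 15-min CGM grid with circadian baseline, meal
excursions and AR(1) sensor noise, a responder mixture of
participant-specific diet effects, and realistic missingness (skipped
meals, early withdrawals, sensor failure).

The generative diet effect shifts the *excursion peak height* on LF-HC
days, not the basal level, so MPG and MAGE respond to it while AUC24
responds only weakly.

Everything is deterministic given one integer seed; all draws flow from a
single :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from nof1cgm import io as cgm_io
from nof1cgm.types import (
    DIET_HFLC,
    DIET_LFHC,
    DIET_WASHOUT,
    MEAL_SLOTS,
    PROTEIN_PCT,
    GlucoseTrace,
    MealEvent,
    ParticipantMeta,
    Period,
    StudyDesign,
    ValidationError,
)

#: Scheduled first-bite times; on the 15-min CGM grid so that the meal
#: kernel's peak (45 min post bite) falls exactly on a sample.
DEFAULT_MEAL_TIMES = {
    "breakfast": dt.time(8, 0),
    "lunch": dt.time(12, 0),
    "dinner": dt.time(18, 0),
}

#: Per-day carbohydrate %E for the two 3-day halves of each period type.
CARB_SCHEDULE = {
    DIET_LFHC: (65.0, 75.0),
    DIET_HFLC: (25.0, 15.0),
    DIET_WASHOUT: (55.0, 55.0),
}

SAMPLE_MINUTES = 15
KERNEL_PEAK_MIN = 45.0  # meal excursion peaks 45 min after first bite
KERNEL_SUPPORT_MIN = 240.0  # ~0 beyond 3-4 h


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters for one participant's glucose physiology."""

    participant_id: str
    baseline_glucose: float = 4.5  # mmol/L fasting level
    circadian_amplitude: float = 0.3  # mmol/L
    meal_response_base: float = 2.0  # excursion peak height on HF-LC, mmol/L
    diet_effect_mpg: float = 0.0  # true LF-HC minus HF-LC peak shift, mmol/L
    carb_dose_slope: float = 0.0  # mmol/L per carbohydrate %E above 15
    noise_sd: float = 0.3  # stationary AR(1) sd, mmol/L
    ar1_rho: float = 0.7
    missing_meal_prob: float = 0.02
    responder_label: str = "nonresponder"

    def __post_init__(self):
        if not 3.5 <= self.baseline_glucose <= 6.0:
            raise ValidationError(
                f"baseline_glucose {self.baseline_glucose} outside the "
                f"normoglycemic default range [3.5, 6.0]"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not 0 <= self.ar1_rho < 1:
            raise ValidationError("ar1_rho must be in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the canonical design: 30 enrolled participants (2
    simulated early withdrawals leaving 28 complete), 3 sets of 2
    six-day periods, 3 meals/day = 18 outcome observations per period, a
    (9, 6, 13)/28 HC-responder/HF-responder/nonresponder mixture with
    effect magnitudes ±0.3 mmol/L, and 2% skipped meals (98% adherence).
    """

    n_participants: int = 30
    n_sets: int = 3
    days_per_period: int = 6
    meals_per_day: int = 3
    mixture: tuple = (9 / 28, 6 / 28, 13 / 28)  # (HC, HF, non)
    hc_effect: float = 0.3  # mmol/L, diet_effect_mpg for HC-responders
    hf_effect: float = -0.3
    carb_dose_slope: float = 0.0  # nonzero switches dose-response mode on
    baseline_glucose: float = 4.5
    baseline_sd: float = 0.25  # between-participant spread, truncated to [3.5, 6]
    circadian_amplitude: float = 0.3
    meal_response_base: float = 2.0
    noise_sd: float = 0.3
    ar1_rho: float = 0.7
    missing_meal_prob: float = 0.02
    n_withdrawals: int = 2
    n_low_valid: int = 1  # participants with simulated sensor failure
    n_chronic: int = 1  # participants flagged chronic disease / medication
    start_date: dt.date = dt.date(2024, 1, 1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValidationError(f"mixture proportions must sum to 1, got {self.mixture}")
        if self.n_sets < 1:
            raise ValidationError("n_sets must be >= 1")
        if self.n_participants <= self.n_withdrawals:
            raise ValidationError("need more participants than withdrawals")


@dataclass
class CohortData:
    """In-memory bundle of everything :func:`generate_cohort` produces."""

    spec: CohortSpec
    designs: dict
    meals: list
    traces: dict
    meta: dict
    profiles: dict
    truth: pd.DataFrame = field(repr=False, default=None)


def _participant_ids(n: int):
    return [str(i + 1) for i in range(n)]


# ---------------------------------------------------------------------------
# Design


def generate_design(
    spec: CohortSpec,
    rng: np.random.Generator,
    participant_id: str,
) -> StudyDesign:
    """Randomized design for one participant: washout then block-of-2 pairs.

    The leading washout standardises the baseline; within each set the
    LF-HC/HF-LC order is a fair coin (block size 2), and each period's
    days 1–3 / 4–6 carry the two sub-compositions (LF-HC 65/75 %E
    carbohydrate, HF-LC 25/15, washout 55).
    """
    d = spec.days_per_period
    half = d // 2
    date = spec.start_date
    periods = []

    def make(diet, set_index, period_index, start):
        c1, c2 = CARB_SCHEDULE[diet]
        carb = (c1,) * half + (c2,) * (d - half)
        fat = tuple(100.0 - PROTEIN_PCT - c for c in carb)
        return Period(
            set_index=set_index,
            period_index=period_index,
            diet=diet,
            carb_pct=carb,
            fat_pct=fat,
            start_date=start,
            days=d,
        )

    periods.append(make(DIET_WASHOUT, 0, 1, date))
    date += dt.timedelta(days=d)
    for s in range(1, spec.n_sets + 1):
        order = (DIET_LFHC, DIET_HFLC) if rng.random() < 0.5 else (DIET_HFLC, DIET_LFHC)
        for k, diet in enumerate(order, start=1):
            periods.append(make(diet, s, k, date))
            date += dt.timedelta(days=d)
    return StudyDesign(participant_id=participant_id, periods=tuple(periods))


def generate_meal_log(design: StudyDesign) -> list:
    """All-consumed meal events at the scheduled times for every design day."""
    return [
        MealEvent(
            participant_id=design.participant_id,
            date=date,
            slot=slot,
            first_bite_time=DEFAULT_MEAL_TIMES[slot],
            consumed=True,
        )
        for date in design.all_dates()
        for slot in MEAL_SLOTS
    ]


# ---------------------------------------------------------------------------
# Trace simulation


def meal_kernel(minutes: np.ndarray) -> np.ndarray:
    """Unimodal excursion shape: 0 at the bite, 1 at 45 min, ~0 by 3-4 h.

    A gamma-like pulse g(t) = (t/45)^2 exp(2 - 2 t/45) (t in minutes).
    """
    t = np.asarray(minutes, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    r = t[pos] / KERNEL_PEAK_MIN
    out[pos] = r**2 * np.exp(2.0 - 2.0 * r)
    return out


def simulate_trace(
    profile: ParticipantProfile,
    design: StudyDesign,
    meals,
    rng: np.random.Generator,
) -> GlucoseTrace:
    """15-min CGM trace over the whole design.

    glucose(t) = baseline + circadian sinusoid + sum of meal excursions +
    stationary AR(1) noise. A consumed meal adds A·g(t − t_meal) with
    A = meal_response_base + diet_effect_mpg·1[LF-HC]
      (+ carb_dose_slope·(carb%E − 15) in dose-response mode);
    missed meals add nothing. The grid closes with the midnight sample
    after the last day so AUC24 of the final day is well defined.
    """
    dates = design.all_dates()
    if not dates:
        raise ValidationError(f"participant {design.participant_id}: empty design")
    meal_dates = {m.date for m in meals if m.participant_id == design.participant_id}
    missing_days = [d for d in dates if d not in meal_dates]
    if missing_days:
        raise ValidationError(
            f"participant {design.participant_id}: meal log does not cover "
            f"design day {missing_days[0]}"
        )
    t0 = dt.datetime.combine(dates[0], dt.time(0, 0))
    n = len(dates) * (24 * 60 // SAMPLE_MINUTES) + 1  # closing midnight sample
    minutes = np.arange(n) * float(SAMPLE_MINUTES)
    times = pd.to_datetime(t0) + pd.to_timedelta(minutes, unit="m")

    hours_of_day = (minutes / 60.0) % 24.0
    glucose = profile.baseline_glucose + profile.circadian_amplitude * np.sin(
        2.0 * np.pi * (hours_of_day - 10.0) / 24.0
    )

    for meal in meals:
        if meal.participant_id != design.participant_id or not meal.consumed:
            continue
        period = design.period_for_date(meal.date)
        if period is None:
            continue
        amplitude = profile.meal_response_base
        if period.diet == DIET_LFHC:
            amplitude += profile.diet_effect_mpg
        if profile.carb_dose_slope != 0.0:
            amplitude += profile.carb_dose_slope * (period.carb_for_date(meal.date) - 15.0)
        offset = (meal.first_bite - t0).total_seconds() / 60.0
        rel = minutes - offset
        lo = int(np.searchsorted(rel, 0.0, side="right"))
        hi = int(np.searchsorted(rel, KERNEL_SUPPORT_MIN, side="right"))
        glucose[lo:hi] += amplitude * meal_kernel(rel[lo:hi])

    # stationary AR(1): e_t = rho e_{t-1} + sd sqrt(1-rho^2) z_t
    z = rng.standard_normal(n)
    noise = np.empty(n)
    noise[0] = profile.noise_sd * z[0]
    scale = profile.noise_sd * np.sqrt(1.0 - profile.ar1_rho**2)
    for i in range(1, n):
        noise[i] = profile.ar1_rho * noise[i - 1] + scale * z[i]
    glucose = glucose + noise

    return GlucoseTrace(
        participant_id=design.participant_id,
        samples=pd.DataFrame({"time": times, "glucose": glucose}),
    )


# ---------------------------------------------------------------------------
# Missingness


def inject_meal_missingness(meals, missing_meal_prob: float, rng: np.random.Generator) -> list:
    """Independently flip consumed meals to missed with the given probability."""
    if not 0.0 <= missing_meal_prob <= 1.0:
        raise ValidationError("missing_meal_prob must be in [0, 1]")
    out = []
    for m in meals:
        if m.consumed and rng.random() < missing_meal_prob:
            m = replace(m, consumed=False)
        out.append(m)
    return out


def drop_sensor_windows(trace: GlucoseTrace, windows) -> GlucoseTrace:
    """Delete CGM samples inside the given (start, end) datetime windows."""
    keep = np.ones(len(trace), dtype=bool)
    t = trace.samples["time"]
    for start, end in windows:
        keep &= ~((t >= start) & (t < end)).to_numpy()
    return GlucoseTrace(
        participant_id=trace.participant_id,
        samples=trace.samples.loc[keep].reset_index(drop=True),
    )


def inject_missingness(
    trace: GlucoseTrace,
    meals,
    missing_meal_prob: float,
    sensor_dropout_windows=None,
    seed: int = 0,
):
    """Convenience wrapper: meal skips plus optional sensor dropout."""
    rng = np.random.default_rng(seed)
    meals = inject_meal_missingness(meals, missing_meal_prob, rng)
    if sensor_dropout_windows:
        trace = drop_sensor_windows(trace, sensor_dropout_windows)
    return trace, meals


# ---------------------------------------------------------------------------
# Cohort assembly


def _allocate_labels(n: int, mixture, rng: np.random.Generator):
    """Largest-remainder allocation of responder labels, then shuffled.

    Exact: when n * proportion is integral the counts are hit exactly.
    """
    labels = ("HC-responder", "HF-responder", "nonresponder")
    raw = np.array(mixture, dtype=float) * n
    counts = np.floor(raw + 1e-9).astype(int)
    remainder = raw - counts
    while counts.sum() < n:
        i = int(np.argmax(remainder))
        counts[i] += 1
        remainder[i] = -1
    assigned = [lab for lab, c in zip(labels, counts) for _ in range(c)]
    rng.shuffle(assigned)
    return assigned


def _profile_for(spec: CohortSpec, pid: str, label: str, rng: np.random.Generator) -> ParticipantProfile:
    effect = {"HC-responder": spec.hc_effect, "HF-responder": spec.hf_effect}.get(label, 0.0)
    baseline = float(
        np.clip(rng.normal(spec.baseline_glucose, spec.baseline_sd), 3.5, 6.0)
    )
    return ParticipantProfile(
        participant_id=pid,
        baseline_glucose=baseline,
        circadian_amplitude=spec.circadian_amplitude,
        meal_response_base=spec.meal_response_base,
        diet_effect_mpg=effect,
        carb_dose_slope=spec.carb_dose_slope * (1 if label == "HC-responder" else -1 if label == "HF-responder" else 0),
        noise_sd=spec.noise_sd,
        ar1_rho=spec.ar1_rho,
        missing_meal_prob=spec.missing_meal_prob,
        responder_label=label,
    )


def generate_cohort(spec: CohortSpec, outdir=None) -> CohortData:
    """Generate a full synthetic cohort; optionally write it to ``outdir``.

    Produces designs, meal logs, CGM traces, participant metadata and a
    ground-truth table of every generative profile (for parameter-recovery
    tests). Early withdrawals keep only their first completed set;
    low-valid participants lose most intervention CGM to simulated sensor
    failure. Deterministic given ``spec.seed``; responder labels are
    allocated exactly over the analysis set (non-withdrawn participants).
    """
    root = np.random.SeedSequence(spec.seed)
    (seq_design, seq_labels, seq_profiles, seq_meals,
     seq_traces, seq_meta, seq_select) = root.spawn(7)
    rng_design = np.random.default_rng(seq_design)
    rng_labels = np.random.default_rng(seq_labels)
    rng_profiles = np.random.default_rng(seq_profiles)
    rng_meals = np.random.default_rng(seq_meals)
    rng_meta = np.random.default_rng(seq_meta)
    rng_select = np.random.default_rng(seq_select)
    trace_seqs = seq_traces.spawn(spec.n_participants)

    ids = _participant_ids(spec.n_participants)
    withdrawn = set(
        rng_select.choice(ids, size=spec.n_withdrawals, replace=False).tolist()
    ) if spec.n_withdrawals else set()
    analysis_ids = [p for p in ids if p not in withdrawn]
    labels = dict(zip(analysis_ids, _allocate_labels(len(analysis_ids), spec.mixture, rng_labels)))
    for pid in withdrawn:
        labels[pid] = _allocate_labels(1, spec.mixture, rng_labels)[0]

    pool = [p for p in analysis_ids]
    low_valid = set(rng_select.choice(pool, size=min(spec.n_low_valid, len(pool)), replace=False).tolist()) if spec.n_low_valid else set()
    pool = [p for p in pool if p not in low_valid]
    chronic = set(rng_select.choice(pool, size=min(spec.n_chronic, len(pool)), replace=False).tolist()) if spec.n_chronic else set()

    designs, meals, traces, meta, profiles = {}, [], {}, {}, {}
    truth_rows = []
    for i, pid in enumerate(ids):
        design = generate_design(spec, rng_design, pid)
        if pid in withdrawn:
            design = design.truncated(1)  # completed one cycle, then quit
        profile = _profile_for(spec, pid, labels[pid], rng_profiles)
        log = generate_meal_log(design)
        log = inject_meal_missingness(log, profile.missing_meal_prob, rng_meals)
        trace = simulate_trace(profile, design, log, np.random.default_rng(trace_seqs[i]))
        if pid in low_valid:
            # sensor failure across most intervention periods -> <50% valid
            drop = [
                (dt.datetime.combine(p.start_date, dt.time(0, 0)),
                 dt.datetime.combine(p.end_date, dt.time(0, 0)))
                for p in design.intervention_periods()[: 2 * spec.n_sets - 1]
            ]
            trace = drop_sensor_windows(trace, drop)

        from nof1cgm.metrics import valid_data_fraction

        vdf = valid_data_fraction(trace, design, log)
        designs[pid] = design
        meals.extend(log)
        traces[pid] = trace
        profiles[pid] = profile
        meta[pid] = ParticipantMeta(
            participant_id=pid,
            age=float(rng_meta.integers(22, 35)),
            sex="M" if rng_meta.random() < 9 / 28 else "F",
            bmi=float(np.clip(rng_meta.normal(22.0, 3.0), 17.2, 31.9)),
            completed_all_periods=pid not in withdrawn,
            valid_data_fraction=vdf,
            chronic_disease_or_medication=pid in chronic,
        )
        truth_rows.append(
            {
                "participant_id": pid,
                "responder_label": profile.responder_label,
                "diet_effect_mpg": profile.diet_effect_mpg,
                "carb_dose_slope": profile.carb_dose_slope,
                "baseline_glucose": profile.baseline_glucose,
                "meal_response_base": profile.meal_response_base,
                "noise_sd": profile.noise_sd,
                "ar1_rho": profile.ar1_rho,
                "withdrew_early": pid in withdrawn,
                "low_valid_data": pid in low_valid,
            }
        )
    truth = pd.DataFrame(truth_rows)
    data = CohortData(
        spec=spec, designs=designs, meals=meals, traces=traces,
        meta=meta, profiles=profiles, truth=truth,
    )
    if outdir is not None:
        write_cohort(data, outdir)
    return data


def write_cohort(data: CohortData, outdir) -> Path:
    """Write the cohort bundle in the canonical CSV schemas plus truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cgm_io.write_cgm(data.traces, outdir / "cgm.csv")
    cgm_io.write_meal_log(data.meals, outdir / "meals.csv")
    cgm_io.write_design(data.designs, outdir / "design.csv")
    cgm_io.write_meta(data.meta, outdir / "meta.csv")
    data.truth.to_csv(outdir / "truth.csv", index=False, float_format="%.6f")
    return outdir


def read_cohort(outdir) -> CohortData:
    """Round-trip reader for a written cohort bundle (truth included)."""
    outdir = Path(outdir)
    designs = cgm_io.read_design(outdir / "design.csv")
    return CohortData(
        spec=None,
        designs=designs,
        meals=cgm_io.read_meal_log(outdir / "meals.csv", designs=designs),
        traces=cgm_io.read_cgm(outdir / "cgm.csv"),
        meta=cgm_io.read_meta(outdir / "meta.csv"),
        profiles={},
        truth=pd.read_csv(outdir / "truth.csv", dtype={"participant_id": str}),
    )
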
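"""Shared fixtures: small deterministic cohorts and helper constructors."""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd
import pytest

from nof1cgm.metrics import build_outcome_series
from nof1cgm.simulate import (
    CohortSpec,
    ParticipantProfile,
    generate_cohort,
    generate_design,
    generate_meal_log,
    simulate_trace,
)

# the repeated per-meal "no CGM samples" warnings from the simulated
# sensor-failure participant are expected; keep test output readable
logging.getLogger("nof1cgm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """Full default synthetic cohort (30 enrolled, 28 complete), seed 1."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def default_series(default_cohort):
    data = default_cohort
    return build_outcome_series(data.traces, data.designs, data.meals)


@pytest.fixture(scope="session")
def clean_participant():
    """One near-noiseless participant with a known +0.5 mmol/L diet effect."""
    spec = CohortSpec(n_participants=1, n_withdrawals=0, n_low_valid=0, n_chronic=0)
    rng = np.random.default_rng(42)
    design = generate_design(spec, rng, "p1")
    meals = generate_meal_log(design)
    profile = ParticipantProfile(
        participant_id="p1",
        diet_effect_mpg=0.5,
        noise_sd=1e-9,
        ar1_rho=0.0,
        missing_meal_prob=0.0,
    )
    trace = simulate_trace(profile, design, meals, np.random.default_rng(7))
    return profile, design, meals, trace


def make_day_trace(values, date=dt.date(2024, 1, 1), step_min=15):
    """DataFrame day slice (time, glucose) starting at 00:00."""
    start = dt.datetime.combine(date, dt.time(0, 0))
    times = pd.to_datetime(start) + pd.to_timedelta(
        np.arange(len(values)) * step_min, unit="m"
    )
    return pd.DataFrame({"time": times, "glucose": np.asarray(values, dtype=float)})
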
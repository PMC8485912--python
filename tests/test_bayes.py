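"""Individual Bayesian model: Gibbs vs closed-form oracle, responder rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nof1cgm.bayes import (
    CALL_HC,
    CALL_HF,
    CALL_NON,
    IndividualModelSpec,
    PosteriorSummary,
    classify_responder,
    dose_response_fit,
    fit_individual,
    summarize_cohort_calls,
)
from nof1cgm.types import InsufficientDataError, ValidationError

SPEC = IndividualModelSpec(chains=4, iterations=3000, burn_in=500, seed=0)


def t_tail_oracle(y, x, delta):
    """Flat-prior closed form: beta | data ~ t_{n-2}(mean diff, pooled se)."""
    y0, y1 = y[x == 0], y[x == 1]
    n0, n1 = len(y0), len(y1)
    bhat = y1.mean() - y0.mean()
    s2 = (((y0 - y0.mean()) ** 2).sum() + ((y1 - y1.mean()) ** 2).sum()) / (n0 + n1 - 2)
    se = np.sqrt(s2 * (1 / n0 + 1 / n1))
    df = n0 + n1 - 2
    return (
        float(sps.t.sf((delta - bhat) / se, df)),
        float(sps.t.cdf((-delta - bhat) / se, df)),
        bhat,
        se,
    )


def synth(rng, effect, sd, n_per_arm=27):
    x = np.repeat([0, 1], n_per_arm)
    y = 5.0 + effect * x + rng.normal(0, sd, size=2 * n_per_arm)
    return y, x


class TestFitIndividual:
    def test_identical_constant_arms_give_null_effect(self):
        y = np.full(20, 5.0)
        x = np.repeat([0, 1], 10)
        s = fit_individual(y, x, SPEC, 0.167)
        assert s.beta_mean == pytest.approx(0.0, abs=0.01)
        assert s.p_above < 0.05 and s.p_below < 0.05

    def test_large_effect_detected_with_certainty(self):
        rng = np.random.default_rng(1)
        y, x = synth(rng, effect=0.5, sd=0.2)
        s = fit_individual(y, x, SPEC, 0.167)
        _, _, bhat, se = t_tail_oracle(y, x, 0.167)
        assert abs(s.beta_mean - 0.5) < 3 * se
        assert s.p_above > 0.99
        assert s.converged and s.rhat < 1.05

    def test_tail_probabilities_match_t_oracle(self):
        rng = np.random.default_rng(7)
        y, x = synth(rng, effect=0.2, sd=0.4)
        s = fit_individual(y, x, SPEC, 0.167)
        p_above, p_below, _, _ = t_tail_oracle(y, x, 0.167)
        assert s.p_above == pytest.approx(p_above, abs=0.02)
        assert s.p_below == pytest.approx(p_below, abs=0.02)

    def test_tails_partition_at_delta_zero(self):
        rng = np.random.default_rng(3)
        y, x = synth(rng, effect=0.1, sd=0.3)
        s = fit_individual(y, x, SPEC, 0.0)
        assert s.p_above + s.p_below == pytest.approx(1.0, abs=1e-12)

    def test_tails_plus_middle_sum_to_one(self):
        rng = np.random.default_rng(4)
        y, x = synth(rng, effect=0.15, sd=0.3)
        s = fit_individual(y, x, SPEC, 0.167)
        assert 0.0 <= s.p_above + s.p_below <= 1.0

    def test_label_flip_swaps_tails(self):
        rng = np.random.default_rng(9)
        y, x = synth(rng, effect=0.3, sd=0.3)
        s = fit_individual(y, x, SPEC, 0.167)
        s_flip = fit_individual(y, 1 - x, SPEC, 0.167)
        assert s_flip.beta_mean == pytest.approx(-s.beta_mean, abs=0.02)
        assert s_flip.p_above == pytest.approx(s.p_below, abs=0.02)
        assert s_flip.p_below == pytest.approx(s.p_above, abs=0.02)

    def test_classification_is_scale_consistent(self):
        rng = np.random.default_rng(11)
        y, x = synth(rng, effect=0.3, sd=0.25)
        for c in (0.5, 10.0):
            s1 = fit_individual(y, x, SPEC, 0.167)
            s2 = fit_individual(c * y, x, SPEC, c * 0.167)
            assert classify_responder(s1).call == classify_responder(s2).call

    def test_insufficient_arm_raises(self):
        y = np.array([5.0, 5.1, 5.2])
        x = np.array([0, 0, 1])
        with pytest.raises(InsufficientDataError, match="LF-HC"):
            fit_individual(y, x, SPEC, 0.167)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(13)
        y, x = synth(rng, effect=0.2, sd=0.3)
        a = fit_individual(y, x, SPEC, 0.167)
        b = fit_individual(y, x, SPEC, 0.167)
        assert a.beta_mean == b.beta_mean and a.p_above == b.p_above

    def test_paired_mode_agrees_with_observation_level(self):
        rng = np.random.default_rng(21)
        sets = np.repeat([1, 2, 3], 18)
        x = np.tile(np.repeat([0, 1], 9), 3)
        y = 5.0 + 0.4 * x + rng.normal(0, 0.3, size=54)
        obs = fit_individual(y, x, SPEC, 0.167, set_index=sets)
        paired = fit_individual(
            y, x,
            IndividualModelSpec(chains=4, iterations=3000, burn_in=500, seed=0, paired=True),
            0.167, set_index=sets,
        )
        assert paired.beta_mean == pytest.approx(obs.beta_mean, abs=0.1)

    def test_oracle_equivalence_across_simulated_grid(self):
        # Gibbs tail mass vs flat-prior t tail within +/-0.02 (a denser
        # 50-dataset sweep runs in the acceptance suite)
        rng = np.random.default_rng(2024)
        for i in range(10):
            effect = rng.uniform(-0.3, 0.5)
            sd = rng.uniform(0.2, 0.8)
            y, x = synth(rng, effect, sd)
            spec = IndividualModelSpec(chains=4, iterations=3000, burn_in=500, seed=i)
            s = fit_individual(y, x, spec, 0.167)
            p_above, p_below, _, _ = t_tail_oracle(y, x, 0.167)
            assert s.p_above == pytest.approx(p_above, abs=0.02)
            assert s.p_below == pytest.approx(p_below, abs=0.02)


def summary_of(p_below_pct, p_above_pct, pid="x", outcome="MPG"):
    return PosteriorSummary(
        participant_id=pid, outcome=outcome, beta_mean=0.0, ci95=(0, 0),
        p_above=p_above_pct / 100, p_below=p_below_pct / 100,
        n_obs=(0, 0), rhat=1.0, converged=True,
    )


class TestClassify:
    @pytest.mark.parametrize(
        "p_below,p_above,expected",
        [
            (0.0, 100.0, CALL_HC),  # certain high-carb responder
            (81.0, 1.60, CALL_HF),
            (17.3, 28.6, CALL_NON),
            (80.0, 0.0, CALL_NON),  # rule is strictly greater than 80%
        ],
    )
    def test_rule(self, p_below, p_above, expected):
        assert classify_responder(summary_of(p_below, p_above)).call == expected

    def test_threshold_monotone(self):
        s = summary_of(0.0, 85.0)
        assert classify_responder(s, 0.8).call == CALL_HC
        assert classify_responder(s, 0.9).call == CALL_NON

    def test_bad_threshold(self):
        with pytest.raises(ValidationError):
            classify_responder(summary_of(0, 0), 1.5)


class TestCohortSummary:
    def test_all_zero_probabilities_are_all_nonresponders(self):
        calls = [
            classify_responder(summary_of(0, 0, pid=str(i), outcome=o))
            for i in range(1, 29)
            for o in ("MPG", "MAGE", "AUC24")
        ]
        summary = summarize_cohort_calls(calls)
        assert summary.overall_counts[CALL_NON] == 28

    def test_double_responder_counted_once_overall(self):
        calls = [
            classify_responder(summary_of(0, 95, pid="1", outcome="MPG")),
            classify_responder(summary_of(0, 95, pid="1", outcome="MAGE")),
        ]
        summary = summarize_cohort_calls(calls)
        assert summary.overall_counts[CALL_HC] == 1
        assert summary.both_hc == ["1"]

    def test_conflicting_directions_flagged(self):
        calls = [
            classify_responder(summary_of(0, 95, pid="1", outcome="MPG")),
            classify_responder(summary_of(95, 0, pid="1", outcome="MAGE")),
        ]
        summary = summarize_cohort_calls(calls)
        assert summary.conflicts == ["1"]
        assert summary.overall["1"] == "conflict"


class TestDoseResponse:
    def _series(self, slope, rng, n=27):
        rows = []
        for carb in (15.0, 25.0, 65.0, 75.0):
            y = 5.0 + slope * (carb - 15.0) + rng.normal(0, 0.15, size=n)
            for v in y:
                rows.append(
                    {"participant_id": "p", "outcome": "MPG", "value": v,
                     "x": int(carb > 40), "set_index": 1, "carb_pct": carb,
                     "date": None, "slot": ""}
                )
        return pd.DataFrame(rows)

    def test_positive_slope_gives_increasing_contrasts(self):
        df = self._series(0.01, np.random.default_rng(0))
        out = dose_response_fit(df, SPEC, 0.167)
        means = out.set_index("carb_pct")["beta_mean"]
        assert means[25.0] < means[65.0] < means[75.0]
        assert out["monotone_increasing"].all()

    def test_zero_effect_never_clears_the_threshold(self):
        df = self._series(0.0, np.random.default_rng(1))
        out = dose_response_fit(df, SPEC, 0.167)
        assert (out["p_above"] < 0.8).all()

    def test_negative_slope_gives_decreasing_contrasts(self):
        df = self._series(-0.01, np.random.default_rng(2))
        out = dose_response_fit(df, SPEC, 0.167)
        means = out.set_index("carb_pct")["beta_mean"]
        assert means[25.0] > means[65.0] > means[75.0]
        assert out["monotone_decreasing"].all()

    def test_missing_level_skipped_with_remaining_contrasts(self):
        df = self._series(0.01, np.random.default_rng(3))
        df = df[df["carb_pct"] != 65.0]
        out = dose_response_fit(df, SPEC, 0.167)
        assert set(out["carb_pct"]) == {25.0, 75.0}
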
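"""Per-participant Bayesian treatment-effect model and responder calls.

Each participant's outcome observations follow

    y = alpha + beta * x + eps,    eps ~ Normal(0, sigma^2)

with x = 0 for the high-fat/low-carbohydrate (HF-LC) diet and x = 1 for
the low-fat/high-carbohydrate (LF-HC) diet, so beta > 0 means higher
glycemia on the high-carbohydrate diet. Priors are noninformative:
Normal(0, 1e6) on alpha and beta and InverseGamma(0.001, 0.001) on the
residual variance, making every full conditional conjugate; the sampler
is a plain Gibbs scheme vectorised across chains.

The posterior tail masses P(beta > +delta) and P(beta < -delta) against a
clinically meaningful threshold delta drive the responder rule: a
participant is an HC-responder when P(beta > +delta) exceeds the
probability threshold (default 0.80), an HF-responder when
P(beta < -delta) does, and a nonresponder otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nof1cgm.types import InsufficientDataError, Thresholds, ValidationError

logger = logging.getLogger("nof1cgm")

RHAT_LIMIT = 1.05

CALL_HC = "HC-responder"
CALL_HF = "HF-responder"
CALL_NON = "nonresponder"


@dataclass(frozen=True)
class IndividualModelSpec:
    """Priors and MCMC settings for the within-participant model."""

    prior_mean: float = 0.0
    prior_var: float = 1e6  # "large variance" noninformative prior, mmol/L scale
    sigma2_shape: float = 0.001
    sigma2_scale: float = 0.001
    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int = 0
    paired: bool = False  # fit set-wise paired mean differences instead

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValidationError("IndividualModelSpec: iterations must exceed burn_in")
        if self.prior_var <= 0:
            raise ValidationError("IndividualModelSpec: prior_var must be > 0")
        if self.chains < 2:
            raise ValidationError("IndividualModelSpec: need >= 2 chains for split-Rhat")


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior of the LF-HC minus HF-LC effect for one participant-outcome."""

    participant_id: str
    outcome: str
    beta_mean: float
    ci95: tuple
    p_above: float  # P(beta > +delta)
    p_below: float  # P(beta < -delta)
    n_obs: tuple  # (n HF-LC, n LF-HC)
    rhat: float
    converged: bool
    alpha_mean: float = float("nan")
    sigma_mean: float = float("nan")
    delta: float = float("nan")


@dataclass(frozen=True)
class ResponderCall:
    participant_id: str
    outcome: str
    call: str
    prob_threshold: float = 0.80


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (chains, draws_per_chain); each chain is split in
    half before the classic between/within variance ratio is formed.
    """
    c, n = draws.shape
    half = n // 2
    chains = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _gibbs_two_param(stats, spec: IndividualModelSpec, rng) -> np.ndarray:
    """Gibbs draws of beta for y = alpha + beta x + eps, chains vectorised.

    ``stats`` = (n, Sx, Sxx, Sy, Sxy, Syy) sufficient statistics.
    Returns draws with shape (chains, kept).
    """
    n, sx, sxx, sy, sxy, syy = stats
    c = spec.chains
    a0, b0 = spec.sigma2_shape, spec.sigma2_scale
    prior_prec = 1.0 / spec.prior_var
    prior_rhs = spec.prior_mean / spec.prior_var

    # overdispersed starts around the least-squares solution
    denom = n * sxx - sx * sx
    if denom > 0:
        beta_hat = (n * sxy - sx * sy) / denom
        alpha_hat = (sy - beta_hat * sx) / n
    else:  # single-arm degenerate; guarded earlier
        beta_hat, alpha_hat = 0.0, sy / n
    ssr0 = max(syy + n * alpha_hat**2 + beta_hat**2 * sxx + 2 * alpha_hat * beta_hat * sx
               - 2 * alpha_hat * sy - 2 * beta_hat * sxy, 1e-12)
    sigma2 = (ssr0 / max(n - 2, 1)) * rng.uniform(0.5, 2.0, size=c)

    kept = (spec.iterations - spec.burn_in) // spec.thin
    out = np.empty((c, kept))
    k = 0
    for it in range(spec.iterations):
        inv_s2 = 1.0 / sigma2
        a11 = n * inv_s2 + prior_prec
        a12 = sx * inv_s2
        a22 = sxx * inv_s2 + prior_prec
        r1 = sy * inv_s2 + prior_rhs
        r2 = sxy * inv_s2 + prior_rhs
        det = a11 * a22 - a12 * a12
        v11, v12, v22 = a22 / det, -a12 / det, a11 / det
        m_alpha = v11 * r1 + v12 * r2
        m_beta = v12 * r1 + v22 * r2
        l11 = np.sqrt(v11)
        l21 = v12 / l11
        l22 = np.sqrt(np.maximum(v22 - l21 * l21, 1e-300))
        z1 = rng.standard_normal(c)
        z2 = rng.standard_normal(c)
        alpha = m_alpha + l11 * z1
        beta = m_beta + l21 * z1 + l22 * z2
        ssr = (syy + n * alpha**2 + beta**2 * sxx + 2 * alpha * beta * sx
               - 2 * alpha * sy - 2 * beta * sxy)
        sigma2 = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * np.maximum(ssr, 1e-12)))
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            out[:, k] = beta
            k += 1
    return out[:, :k], sigma2


def _gibbs_mean_only(y: np.ndarray, spec: IndividualModelSpec, rng) -> np.ndarray:
    """Gibbs draws of the mean for y = beta + eps (paired-difference mode)."""
    n = len(y)
    sy, syy = y.sum(), (y**2).sum()
    c = spec.chains
    a0, b0 = spec.sigma2_shape, spec.sigma2_scale
    prior_prec = 1.0 / spec.prior_var
    prior_rhs = spec.prior_mean / spec.prior_var
    var0 = max(float(np.var(y, ddof=1)) if n > 1 else 1.0, 1e-12)
    sigma2 = var0 * rng.uniform(0.5, 2.0, size=c)
    kept = (spec.iterations - spec.burn_in) // spec.thin
    out = np.empty((c, kept))
    k = 0
    for it in range(spec.iterations):
        prec = n / sigma2 + prior_prec
        mean = (sy / sigma2 + prior_rhs) / prec
        beta = mean + rng.standard_normal(c) / np.sqrt(prec)
        ssr = syy - 2 * beta * sy + n * beta**2
        sigma2 = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * np.maximum(ssr, 1e-12)))
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            out[:, k] = beta
            k += 1
    return out[:, :k], sigma2


def fit_individual(
    y,
    x,
    spec: IndividualModelSpec,
    delta: float,
    *,
    participant_id: str = "",
    outcome: str = "",
    set_index=None,
) -> PosteriorSummary:
    """Fit the within-participant treatment-effect model.

    ``y`` are outcome values and ``x`` their 0/1 diet codes. In paired
    mode (``spec.paired``) the observations are first collapsed into
    set-wise LF-HC minus HF-LC mean differences (``set_index`` required)
    and the posterior of their mean is returned instead.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n0 = int((x == 0).sum())
    n1 = int((x == 1).sum())
    if n0 < 2 or n1 < 2:
        raise InsufficientDataError(
            f"participant {participant_id} {outcome}: need >= 2 observations "
            f"per arm, got {n0} (HF-LC) and {n1} (LF-HC)"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.paired:
        if set_index is None:
            raise ValidationError("paired mode requires set_index per observation")
        s = np.asarray(set_index)
        diffs = []
        for si in np.unique(s):
            m1 = (s == si) & (x == 1)
            m0 = (s == si) & (x == 0)
            if m1.any() and m0.any():
                diffs.append(y[m1].mean() - y[m0].mean())
        if len(diffs) < 2:
            raise InsufficientDataError(
                f"participant {participant_id} {outcome}: paired mode needs "
                f">= 2 complete sets"
            )
        draws, sigma2 = _gibbs_mean_only(np.asarray(diffs), spec, rng)
        alpha_mean = float("nan")
    else:
        stats = (
            float(len(y)),
            float(x.sum()),
            float((x**2).sum()),
            float(y.sum()),
            float((x * y).sum()),
            float((y**2).sum()),
        )
        draws, sigma2 = _gibbs_two_param(stats, spec, rng)
        alpha_mean = float("nan")

    flat = draws.ravel()
    rhat = split_rhat(draws)
    converged = rhat < RHAT_LIMIT
    if not converged:
        logger.warning(
            "fit_individual: participant %s %s split-Rhat %.3f > %.2f",
            participant_id, outcome, rhat, RHAT_LIMIT,
        )
    lo, hi = np.percentile(flat, [2.5, 97.5])
    return PosteriorSummary(
        participant_id=participant_id,
        outcome=outcome,
        beta_mean=float(flat.mean()),
        ci95=(float(lo), float(hi)),
        p_above=float(np.mean(flat > delta)),
        p_below=float(np.mean(flat < -delta)),
        n_obs=(n0, n1),
        rhat=rhat,
        converged=converged,
        alpha_mean=alpha_mean,
        sigma_mean=float(np.sqrt(sigma2).mean()),
        delta=float(delta),
    )


def fit_all_individuals(
    series: pd.DataFrame,
    spec: IndividualModelSpec,
    thresholds: Thresholds = Thresholds(),
    outcomes=("MPG", "MAGE", "AUC24"),
) -> list:
    """Fit every participant × outcome present in a tidy outcome series.

    Seeds are derived deterministically per participant-outcome from
    ``spec.seed`` so results do not depend on iteration order.
    """
    from dataclasses import replace

    out = []
    for (pid, outcome), grp in series.groupby(["participant_id", "outcome"], sort=True):
        if outcome not in outcomes:
            continue
        sub_seed = int(
            np.random.SeedSequence([spec.seed, _stable_id(pid), _stable_id(outcome)])
            .generate_state(1)[0] % (2**31)
        )
        try:
            summary = fit_individual(
                grp["value"].to_numpy(),
                grp["x"].to_numpy(),
                replace(spec, seed=sub_seed),
                thresholds.for_outcome(outcome),
                participant_id=pid,
                outcome=outcome,
                set_index=grp["set_index"].to_numpy(),
            )
        except InsufficientDataError as err:
            logger.warning("fit_all_individuals: skipped — %s", err)
            continue
        out.append(summary)
    return out


def _stable_id(text: str) -> int:
    import hashlib

    return int.from_bytes(hashlib.sha256(str(text).encode()).digest()[:4], "big")


# ---------------------------------------------------------------------------
# Responder classification


def classify_responder(
    summary: PosteriorSummary,
    prob_threshold: float = 0.80,
) -> ResponderCall:
    """Deterministic responder rule on the posterior tail probabilities.

    HC-responder iff P(beta > +delta) > threshold (glycemia higher on the
    high-carbohydrate diet); HF-responder iff P(beta < -delta) > threshold;
    otherwise nonresponder. At threshold >= 0.5 the two conditions are
    mutually exclusive.
    """
    if not 0 < prob_threshold < 1:
        raise ValidationError(f"prob_threshold must be in (0, 1), got {prob_threshold}")
    if summary.p_above > prob_threshold:
        call = CALL_HC
    elif summary.p_below > prob_threshold:
        call = CALL_HF
    else:
        call = CALL_NON
    return ResponderCall(
        participant_id=summary.participant_id,
        outcome=summary.outcome,
        call=call,
        prob_threshold=prob_threshold,
    )


@dataclass
class CohortCallSummary:
    """Responder counts per outcome plus overall union labels.

    A participant is an HC-responder overall when classified HC for MPG or
    MAGE (analogously HF); a participant HC on one of those outcomes and
    HF on the other is a conflict, flagged for manual review and counted
    in neither group.
    """

    per_outcome: dict = field(default_factory=dict)  # outcome -> {call: count}
    overall: dict = field(default_factory=dict)  # participant -> label
    overall_counts: dict = field(default_factory=dict)
    conflicts: list = field(default_factory=list)
    both_hc: list = field(default_factory=list)  # HC for both MPG and MAGE
    both_hf: list = field(default_factory=list)


def summarize_cohort_calls(calls, union_outcomes=("MPG", "MAGE")) -> CohortCallSummary:
    """Aggregate responder calls into per-outcome and overall counts."""
    summary = CohortCallSummary()
    by_participant: dict = {}
    for call in calls:
        counts = summary.per_outcome.setdefault(
            call.outcome, {CALL_HC: 0, CALL_HF: 0, CALL_NON: 0}
        )
        counts[call.call] += 1
        by_participant.setdefault(call.participant_id, {})[call.outcome] = call.call

    for pid in sorted(by_participant, key=_natural_key):
        calls_for = by_participant[pid]
        relevant = [calls_for.get(o, CALL_NON) for o in union_outcomes]
        is_hc = CALL_HC in relevant
        is_hf = CALL_HF in relevant
        if is_hc and is_hf:
            label = "conflict"
            summary.conflicts.append(pid)
            logger.warning(
                "summarize_cohort_calls: participant %s is HC on one outcome "
                "and HF on another — flagged for manual review", pid,
            )
        elif is_hc:
            label = CALL_HC
        elif is_hf:
            label = CALL_HF
        else:
            label = CALL_NON
        summary.overall[pid] = label
        summary.overall_counts[label] = summary.overall_counts.get(label, 0) + 1
        if all(calls_for.get(o) == CALL_HC for o in union_outcomes):
            summary.both_hc.append(pid)
        if all(calls_for.get(o) == CALL_HF for o in union_outcomes):
            summary.both_hf.append(pid)
    for label in (CALL_HC, CALL_HF, CALL_NON):
        summary.overall_counts.setdefault(label, 0)
    return summary


def _natural_key(pid: str):
    return (0, int(pid)) if str(pid).isdigit() else (1, str(pid))


# ---------------------------------------------------------------------------
# Carbohydrate dose-response contrasts


def dose_response_fit(
    series: pd.DataFrame,
    spec: IndividualModelSpec,
    delta: float,
    *,
    reference_carb: float = 15.0,
    contrast_carbs=(25.0, 65.0, 75.0),
) -> pd.DataFrame:
    """Per-participant contrasts of each carbohydrate level against 15 %E.

    For each participant and carbohydrate level c in ``contrast_carbs``,
    fits the treatment model on the observations at levels {15, c} with
    x = 1 at level c, giving the posterior mean difference and meaningful-
    difference tail probabilities. Also reports whether the posterior
    means increase monotonically with carbohydrate level.
    """
    from dataclasses import replace

    rows = []
    for pid, grp in series.groupby("participant_id", sort=True):
        means = {}
        for carb in contrast_carbs:
            sub = grp[grp["carb_pct"].isin([reference_carb, carb])]
            x = (sub["carb_pct"] == carb).astype(int).to_numpy()
            if (x == 1).sum() == 0 or (x == 0).sum() == 0:
                logger.warning(
                    "dose_response_fit: participant %s has no data at carb "
                    "level %g — contrast skipped", pid, carb,
                )
                continue
            sub_seed = int(
                np.random.SeedSequence([spec.seed, _stable_id(pid), int(carb)])
                .generate_state(1)[0] % (2**31)
            )
            try:
                summary = fit_individual(
                    sub["value"].to_numpy(),
                    x,
                    replace(spec, seed=sub_seed, paired=False),
                    delta,
                    participant_id=pid,
                    outcome=f"carb{carb:g}_vs_{reference_carb:g}",
                )
            except InsufficientDataError as err:
                logger.warning("dose_response_fit: %s", err)
                continue
            means[carb] = summary.beta_mean
            rows.append(
                {
                    "participant_id": pid,
                    "carb_pct": carb,
                    "reference_carb": reference_carb,
                    "beta_mean": summary.beta_mean,
                    "ci_low": summary.ci95[0],
                    "ci_high": summary.ci95[1],
                    "p_above": summary.p_above,
                    "p_below": summary.p_below,
                }
            )
        ordered = [means[c] for c in contrast_carbs if c in means]
        monotone_up = all(a < b for a, b in zip(ordered, ordered[1:])) and len(ordered) > 1
        monotone_down = all(a > b for a, b in zip(ordered, ordered[1:])) and len(ordered) > 1
        for r in rows:
            if r["participant_id"] == pid:
                r["monotone_increasing"] = monotone_up
                r["monotone_decreasing"] = monotone_down
    return pd.DataFrame(rows)


def summaries_to_frame(summaries) -> pd.DataFrame:
    """PosteriorSummary list → tidy frame (probabilities as percentages)."""
    return pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "outcome": s.outcome,
                "beta_mean": s.beta_mean,
                "ci_low": s.ci95[0],
                "ci_high": s.ci95[1],
                "p_below_delta": 100.0 * s.p_below,
                "p_above_delta": 100.0 * s.p_above,
                "n_hflc": s.n_obs[0],
                "n_lfhc": s.n_obs[1],
                "rhat": s.rhat,
                "converged": s.converged,
            }
            for s in summaries
        ]
    )
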
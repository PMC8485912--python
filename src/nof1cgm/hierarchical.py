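"""Bayesian hierarchical meta-analysis of the individual n-of-1 series.

Two-level normal model over all participants' observations:

    y_ij = alpha_i + beta_i x_ij + eps_ij,   eps_ij ~ Normal(0, sigma^2)
    alpha_i ~ Normal(mu_alpha, omega^2)
    beta_i  ~ Normal(z_i' b, tau^2)

where z_i = (1, age_i, sex_i, BMI_i) holds centred/standardised
covariates, so the intercept of b is the population-level treatment
effect at the covariate mean and tau^2 is the between-participant
variance. Priors are Normal(0, 1e6) on all location parameters and
InverseGamma(0.001, 0.001) on each variance ("noninformative inverse
gamma"), keeping every full conditional conjugate for Gibbs sampling.

The population-level evidence for a clinically meaningful effect is the
two-tailed posterior mass P(effect > +delta) + P(effect < -delta),
compared against a 90% threshold (stricter than the 80% individual-level
rule, to hold the group-level type-I error down).

An optional AR(1) residual switch prewhitens each participant-period's
observation run at a fixed correlation before the conjugate updates
(generalised least-squares transform); it is OFF by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nof1cgm.bayes import split_rhat
from nof1cgm.types import (
    InsufficientDataError,
    ValidationError,
)

logger = logging.getLogger("nof1cgm")


@dataclass(frozen=True)
class HierarchicalSpec:
    prior_var: float = 1e6
    tau2_shape: float = 0.001  # between-participant variance prior
    tau2_scale: float = 0.001
    omega2_shape: float = 0.001
    omega2_scale: float = 0.001
    sigma2_shape: float = 0.001
    sigma2_scale: float = 0.001
    ar1: bool = False
    ar1_rho: float = 0.0
    chains: int = 4
    iterations: int = 5_000
    burn_in: int = 1_000
    seed: int = 0
    prob_threshold: float = 0.90

    def __post_init__(self):
        if not 0.5 < self.prob_threshold < 1:
            raise ValidationError("prob_threshold must be in (0.5, 1)")
        for name in ("tau2_shape", "tau2_scale", "omega2_shape", "omega2_scale",
                     "sigma2_shape", "sigma2_scale", "prior_var"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"HierarchicalSpec.{name} must be > 0")
        if self.iterations <= self.burn_in:
            raise ValidationError("iterations must exceed burn_in")
        if self.ar1 and not 0 <= self.ar1_rho < 1:
            raise ValidationError("ar1_rho must be in [0, 1)")


@dataclass
class HierarchicalResult:
    outcome: str
    effect_mean: float
    effect_sd: float
    ci95: tuple
    p_above: float
    p_below: float
    p_meaningful: float  # two-tailed mass beyond +/- delta
    p_dominant_tail: float  # larger single tail, also reported
    tau_mean: float  # between-participant effect sd
    tau_ci95: tuple
    covariates: dict  # name -> (mean, ci_low, ci_high)
    shrunken_effects: dict  # participant -> posterior mean beta_i
    individual_estimates: dict  # participant -> raw arm-mean difference
    n_participants: int
    n_observations: int
    rhat: float
    converged: bool
    delta: float
    meaningful: bool = field(init=False)

    def __post_init__(self):
        self.meaningful = False  # set by caller against its threshold


def _prewhiten(y: np.ndarray, x: np.ndarray, rho: float):
    """GLS transform of an AR(1)-correlated observation run.

    Returns transformed (c0, c1, y) columns for the design [1, x].
    """
    n = len(y)
    c0 = np.ones(n)
    c1 = x.astype(float).copy()
    yt = y.astype(float).copy()
    if n == 0 or rho == 0.0:
        return c0, c1, yt
    s = np.sqrt(1.0 - rho**2)
    c0t = np.empty(n)
    c1t = np.empty(n)
    out = np.empty(n)
    c0t[0], c1t[0], out[0] = s * c0[0], s * c1[0], s * yt[0]
    c0t[1:] = c0[1:] - rho * c0[:-1]
    c1t[1:] = c1[1:] - rho * c1[:-1]
    out[1:] = yt[1:] - rho * yt[:-1]
    return c0t, c1t, out


def _participant_stats(grp: pd.DataFrame, spec: HierarchicalSpec):
    """Sufficient statistics (S00, S01, S11, S0y, S1y, Syy, n, raw diff)."""
    y = grp["value"].to_numpy(dtype=float)
    x = grp["x"].to_numpy(dtype=float)
    d_raw = y[x == 1].mean() - y[x == 0].mean() if (x == 1).any() and (x == 0).any() else np.nan
    if spec.ar1 and spec.ar1_rho > 0:
        c0s, c1s, ys = [], [], []
        for (_, _), run in grp.groupby(["set_index", "x"], sort=True):
            c0, c1, yt = _prewhiten(
                run["value"].to_numpy(dtype=float),
                run["x"].to_numpy(dtype=float),
                spec.ar1_rho,
            )
            c0s.append(c0)
            c1s.append(c1)
            ys.append(yt)
        c0 = np.concatenate(c0s)
        c1 = np.concatenate(c1s)
        yt = np.concatenate(ys)
    else:
        c0, c1, yt = np.ones_like(y), x, y
    return (
        float(c0 @ c0), float(c0 @ c1), float(c1 @ c1),
        float(c0 @ yt), float(c1 @ yt), float(yt @ yt),
        len(y), float(d_raw),
    )


def _covariate_matrix(pids, meta: dict):
    """Centred/standardised covariate design (with intercept) and names."""
    names = ["intercept"]
    cols = [np.ones(len(pids))]
    if meta:
        age = np.array([meta[p].age for p in pids], dtype=float)
        sex = np.array([1.0 if meta[p].sex == "M" else 0.0 for p in pids])
        bmi = np.array([meta[p].bmi for p in pids], dtype=float)
        for name, col, standardise in (("age", age, True), ("sex", sex, False), ("bmi", bmi, True)):
            centred = col - col.mean()
            sd = col.std(ddof=0)
            if sd <= 1e-12:
                logger.warning(
                    "fit_hierarchical: covariate %r is constant — dropped", name
                )
                continue
            cols.append(centred / sd if standardise else centred)
            names.append(name)
    return np.column_stack(cols), names


def fit_hierarchical(
    series: pd.DataFrame,
    meta: dict | None,
    spec: HierarchicalSpec,
    delta: float,
    *,
    outcome: str = "",
) -> HierarchicalResult:
    """Gibbs fit of the two-level model for one outcome's tidy series.

    ``series`` holds one outcome's observations (columns ``participant_id,
    value, x, set_index``); ``meta`` supplies the age/sex/BMI covariates
    and may be ``None`` for an unadjusted fit. Participants are
    canonicalised to sorted order so row order never changes the result.
    """
    if outcome and "outcome" in series.columns:
        series = series[series["outcome"] == outcome]
    pids = sorted(series["participant_id"].unique())
    if len(pids) < 1:
        raise InsufficientDataError("hierarchical fit needs >= 1 participant")
    stats = np.array(
        [_participant_stats(series[series["participant_id"] == p], spec) for p in pids]
    )
    s00, s01, s11, s0y, s1y, syy, n_i, d_raw = stats.T
    n_total = int(n_i.sum())
    P = len(pids)
    Z, cov_names = _covariate_matrix(pids, meta or {})
    q = Z.shape[1]
    ZtZ = Z.T @ Z

    C = spec.chains
    rng = np.random.default_rng(spec.seed)
    prior_prec = 1.0 / spec.prior_var

    # initial values from per-participant least squares
    d0 = np.where(np.isfinite(d_raw), d_raw, 0.0)
    alpha = np.tile((s0y / np.maximum(s00, 1e-12)), (C, 1)) + 0.1 * rng.standard_normal((C, P))
    beta = np.tile(d0, (C, 1)) + 0.1 * rng.standard_normal((C, P))
    mu_alpha = alpha.mean(axis=1)
    bcoef = np.zeros((C, q))
    bcoef[:, 0] = beta.mean(axis=1)
    sigma2 = np.full(C, 0.25) * rng.uniform(0.5, 2.0, size=C)
    tau2 = np.full(C, max(d0.var() + 1e-4, 1e-4)) * rng.uniform(0.5, 2.0, size=C)
    omega2 = np.full(C, 0.25) * rng.uniform(0.5, 2.0, size=C)

    kept = spec.iterations - spec.burn_in
    draw_effect = np.empty((C, kept))
    draw_tau = np.empty((C, kept))
    draw_b = np.empty((C, kept, q))
    beta_running = np.zeros((C, P))

    eye_q = np.eye(q)
    k = 0
    for it in range(spec.iterations):
        inv_s2 = (1.0 / sigma2)[:, None]  # (C,1)
        # alpha_i
        prec_a = s00[None, :] * inv_s2 + (1.0 / omega2)[:, None]
        num_a = (s0y[None, :] - beta * s01[None, :]) * inv_s2 + (mu_alpha / omega2)[:, None]
        alpha = num_a / prec_a + rng.standard_normal((C, P)) / np.sqrt(prec_a)
        # beta_i
        m_prior = bcoef @ Z.T  # (C,P)
        prec_b = s11[None, :] * inv_s2 + (1.0 / tau2)[:, None]
        num_b = (s1y[None, :] - alpha * s01[None, :]) * inv_s2 + m_prior / tau2[:, None]
        beta = num_b / prec_b + rng.standard_normal((C, P)) / np.sqrt(prec_b)
        # hyper-regression coefficients b | beta
        for c in range(C):
            A = ZtZ / tau2[c] + prior_prec * eye_q
            rhs = Z.T @ beta[c] / tau2[c]
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, rhs)
            bcoef[c] = mean + np.linalg.solve(L.T, rng.standard_normal(q))
        # mu_alpha
        prec_m = P / omega2 + prior_prec
        mean_m = alpha.sum(axis=1) / omega2 / prec_m
        mu_alpha = mean_m + rng.standard_normal(C) / np.sqrt(prec_m)
        # variances
        res_a = ((alpha - mu_alpha[:, None]) ** 2).sum(axis=1)
        omega2 = 1.0 / rng.gamma(
            spec.omega2_shape + 0.5 * P, 1.0 / (spec.omega2_scale + 0.5 * res_a)
        )
        res_b = ((beta - bcoef @ Z.T) ** 2).sum(axis=1)
        tau2 = 1.0 / rng.gamma(
            spec.tau2_shape + 0.5 * P, 1.0 / (spec.tau2_scale + 0.5 * res_b)
        )
        ssr = (
            syy[None, :] + alpha**2 * s00[None, :] + beta**2 * s11[None, :]
            + 2 * alpha * beta * s01[None, :]
            - 2 * alpha * s0y[None, :] - 2 * beta * s1y[None, :]
        ).sum(axis=1)
        sigma2 = 1.0 / rng.gamma(
            spec.sigma2_shape + 0.5 * n_total,
            1.0 / (spec.sigma2_scale + 0.5 * np.maximum(ssr, 1e-12)),
        )
        if it >= spec.burn_in:
            draw_effect[:, k] = bcoef[:, 0]
            draw_tau[:, k] = np.sqrt(tau2)
            draw_b[:, k, :] = bcoef
            beta_running += beta
            k += 1

    flat = draw_effect.ravel()
    rhat = split_rhat(draw_effect)
    converged = rhat < 1.05
    if not converged:
        logger.warning("fit_hierarchical: %s split-Rhat %.3f > 1.05", outcome, rhat)
    lo, hi = np.percentile(flat, [2.5, 97.5])
    p_above = float(np.mean(flat > delta))
    p_below = float(np.mean(flat < -delta))
    tau_flat = draw_tau.ravel()
    tlo, thi = np.percentile(tau_flat, [2.5, 97.5])
    covariates = {
        name: (
            float(draw_b[:, :, j].mean()),
            float(np.percentile(draw_b[:, :, j], 2.5)),
            float(np.percentile(draw_b[:, :, j], 97.5)),
        )
        for j, name in enumerate(cov_names)
    }
    shrunken = dict(zip(pids, beta_running.mean(axis=0) / kept))
    result = HierarchicalResult(
        outcome=outcome,
        effect_mean=float(flat.mean()),
        effect_sd=float(flat.std(ddof=1)),
        ci95=(float(lo), float(hi)),
        p_above=p_above,
        p_below=p_below,
        p_meaningful=p_above + p_below,
        p_dominant_tail=max(p_above, p_below),
        tau_mean=float(tau_flat.mean()),
        tau_ci95=(float(tlo), float(thi)),
        covariates=covariates,
        shrunken_effects=shrunken,
        individual_estimates=dict(zip(pids, d_raw)),
        n_participants=P,
        n_observations=n_total,
        rhat=rhat,
        converged=converged,
        delta=float(delta),
    )
    result.meaningful = result.p_meaningful > spec.prob_threshold
    return result


# ---------------------------------------------------------------------------
# Sensitivity subsets


SUBSET_NAMES = (
    "all_available",
    "exclude_withdrawn",
    "complete_protocol",
    "complete_no_chronic",
)


def sensitivity_subsets(meta: dict, valid_fraction_min: float = 0.5) -> dict:
    """The four nested sensitivity-analysis participant subsets.

    1. all available participants;
    2. excluding early withdrawals;
    3. completers only (excluding withdrawals and those with valid data
       below ``valid_fraction_min``);
    4. completers with neither chronic disease nor prescription medication.
    """
    pids = sorted(meta, key=lambda p: (0, int(p)) if str(p).isdigit() else (1, p))
    completed = [p for p in pids if meta[p].completed_all_periods]
    complete_valid = [
        p for p in completed if meta[p].valid_data_fraction >= valid_fraction_min
    ]
    healthy = [
        p for p in complete_valid if not meta[p].chronic_disease_or_medication
    ]
    return {
        "all_available": list(pids),
        "exclude_withdrawn": completed,
        "complete_protocol": complete_valid,
        "complete_no_chronic": healthy,
    }


def run_sensitivity(
    series: pd.DataFrame,
    meta: dict,
    spec: HierarchicalSpec,
    delta: float,
    *,
    outcome: str = "",
) -> dict:
    """Hierarchical fit per sensitivity subset; empty subsets are skipped."""
    results = {}
    for name, pids in sensitivity_subsets(meta).items():
        sub = series[series["participant_id"].isin(pids)]
        if sub.empty or sub["participant_id"].nunique() < 2:
            logger.warning("run_sensitivity: subset %s empty or too small — skipped", name)
            results[name] = None
            continue
        results[name] = fit_hierarchical(
            sub, {p: meta[p] for p in pids if p in meta}, spec, delta, outcome=outcome
        )
    return results
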
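"""End-to-end orchestration: simulate → metrics → fits → power → report.

Every stage reads and writes the canonical CSV schemas, so any stage can
also be run standalone from files via the CLI. A JSON run manifest
(config hash, seeds, package version, table row counts and checksums)
makes a run reproducible and self-describing; re-running with the same
config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from nof1cgm import __version__, io as cgm_io
from nof1cgm.bayes import (
    classify_responder,
    fit_all_individuals,
    summaries_to_frame,
    summarize_cohort_calls,
)
from nof1cgm.config import RunConfig
from nof1cgm.hierarchical import run_sensitivity
from nof1cgm.metrics import build_outcome_series
from nof1cgm.power import residual_sd_band, run_power
from nof1cgm.simulate import generate_cohort
from nof1cgm.types import OUTCOMES

logger = logging.getLogger("nof1cgm")


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage in order; stops at the first error.

    Writes the synthetic cohort under ``outdir/data``, stage outputs under
    ``outdir``, a ``manifest.json`` and a human-readable ``report.md``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = cgm_io.JsonlLogger(outdir / "run.jsonl")
    marker = outdir / "INCOMPLETE"
    marker.write_text("pipeline in progress or failed\n")

    try:
        log.log("simulate", seed=config.cohort.seed)
        data = generate_cohort(config.cohort, outdir / "data")

        log.log("metrics")
        series = build_outcome_series(
            data.traces,
            data.designs,
            data.meals,
            min_coverage=config.metrics.min_coverage,
            mage_direction=config.metrics.mage_direction,
            mage_sd_ddof=config.metrics.mage_sd_ddof,
        )

        log.log("fit_individual", n_series=int(series.groupby(["participant_id", "outcome"]).ngroups))
        summaries = fit_all_individuals(series, config.individual_model, config.thresholds)
        posterior = summaries_to_frame(summaries)

        log.log("classify", threshold=config.classification.prob_threshold)
        calls = [
            classify_responder(s, config.classification.prob_threshold)
            for s in summaries
        ]
        cohort_summary = summarize_cohort_calls(calls)
        calls_df = pd.DataFrame(
            [
                {
                    "participant_id": c.participant_id,
                    "outcome": c.outcome,
                    "call": c.call,
                    "prob_threshold": c.prob_threshold,
                }
                for c in calls
            ]
        )

        log.log("fit_group")
        group = {}
        for outcome in OUTCOMES:
            results = run_sensitivity(
                series[series["outcome"] == outcome],
                data.meta,
                config.hierarchical,
                config.thresholds.for_outcome(outcome),
                outcome=outcome,
            )
            group[outcome] = results
            payload = {
                name: _group_payload(res) for name, res in results.items()
            }
            (outdir / f"group_{outcome.lower()}.json").write_text(
                json.dumps(payload, indent=2)
            )

        log.log("power", n_simulations=config.power.n_simulations)
        power = run_power(config.power)
        band = residual_sd_band(config.power)
        (outdir / "power_report.json").write_text(
            json.dumps(
                {
                    "power": power.power,
                    "mc_ci": power.mc_ci,
                    "type1_error": power.type1_error,
                    "type1_mc_ci": power.type1_mc_ci,
                    "config": dataclasses.asdict(power.config),
                    "residual_sd_band": band.to_dict(orient="records"),
                },
                indent=2,
            )
        )

        tables = {
            "outcome_series": series,
            "posterior": posterior,
            "calls": calls_df,
        }
        cgm_io.write_results(
            tables, outdir, config=config.to_dict(), seeds={"seed": config.seed}
        )
        _write_report(outdir, config, cohort_summary, posterior, group, power, band)
        marker.unlink()
    except Exception:
        log.log("failed")
        raise
    return outdir


def _group_payload(res) -> dict | None:
    if res is None:
        return None
    return {
        "effect_mean": res.effect_mean,
        "ci95": list(res.ci95),
        "p_meaningful": res.p_meaningful,
        "p_dominant_tail": res.p_dominant_tail,
        "tau_mean": res.tau_mean,
        "n_participants": res.n_participants,
        "covariates": {k: list(v) for k, v in res.covariates.items()},
        "rhat": res.rhat,
    }


def _write_report(outdir, config, cohort_summary, posterior, group, power, band) -> None:
    """Markdown report mirroring the per-participant and count table layouts."""
    lines = [
        "# n-of-1 diet-crossover analysis report",
        "",
        f"nof1cgm {__version__}; seed {config.seed}",
        "",
        "## Per-participant posterior probabilities (%) of a meaningful difference",
        "",
        "| Participant | MPG < -δ | MPG > +δ | MAGE < -δ | MAGE > +δ | AUC24 < -δ | AUC24 > +δ |",
        "|---|---|---|---|---|---|---|",
    ]
    wide = posterior.pivot(
        index="participant_id", columns="outcome",
        values=["p_below_delta", "p_above_delta"],
    )
    for pid in sorted(wide.index, key=lambda p: (0, int(p)) if str(p).isdigit() else (1, p)):
        cells = []
        for outcome in OUTCOMES:
            for side in ("p_below_delta", "p_above_delta"):
                try:
                    cells.append(f"{wide.loc[pid, (side, outcome)]:.1f}")
                except KeyError:
                    cells.append("—")
        lines.append(f"| {pid} | " + " | ".join(cells) + " |")
    lines += [
        "",
        "## Responder counts",
        "",
        "| Outcome | HC-responders | HF-responders | Nonresponders |",
        "|---|---|---|---|",
    ]
    for outcome in OUTCOMES:
        counts = cohort_summary.per_outcome.get(outcome, {})
        lines.append(
            f"| {outcome} | {counts.get('HC-responder', 0)} | "
            f"{counts.get('HF-responder', 0)} | {counts.get('nonresponder', 0)} |"
        )
    oc = cohort_summary.overall_counts
    lines += [
        "",
        f"Overall (MPG or MAGE): {oc.get('HC-responder', 0)} HC-responders, "
        f"{oc.get('HF-responder', 0)} HF-responders, "
        f"{oc.get('nonresponder', 0)} nonresponders"
        + (f", {len(cohort_summary.conflicts)} conflicts" if cohort_summary.conflicts else ""),
        "",
        "## Group-level (hierarchical) results",
        "",
        "| Outcome | Subset | Effect (95% CrI) | P(meaningful) two-tail | Dominant tail | τ |",
        "|---|---|---|---|---|---|",
    ]
    for outcome in OUTCOMES:
        for name, res in group[outcome].items():
            if res is None:
                lines.append(f"| {outcome} | {name} | — | — | — | — |")
                continue
            lines.append(
                f"| {outcome} | {name} | {res.effect_mean:.3f} "
                f"({res.ci95[0]:.3f}, {res.ci95[1]:.3f}) | {res.p_meaningful:.3f} | "
                f"{res.p_dominant_tail:.3f} | {res.tau_mean:.3f} |"
            )
    lines += [
        "",
        "## Power",
        "",
        f"Estimated power: {100 * power.power:.1f}% "
        f"(MC 95% CI {100 * power.mc_ci[0]:.1f}–{100 * power.mc_ci[1]:.1f}%), "
        f"type-I error {100 * power.type1_error:.1f}% at two-sided α = "
        f"{power.config.alpha}",
        "",
        "| Residual sd (mmol/L) | Power | Type-I error |",
        "|---|---|---|",
    ]
    for _, r in band.iterrows():
        lines.append(f"| {r['residual_sd']:.1f} | {r['power']:.3f} | {r['type1_error']:.3f} |")
    lines.append("")
    (Path(outdir) / "report.md").write_text("\n".join(lines))
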
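"""Bundled example datasets.

Currently one table: per-participant posterior tail probabilities for a
28-participant diet-crossover reference cohort, used as a worked example
for responder classification and as a regression fixture for the cohort
summary logic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from nof1cgm.bayes import PosteriorSummary


def load_reference_posteriors() -> pd.DataFrame:
    """Posterior tail probabilities (percent) for the reference cohort.

    Columns ``p_<outcome>_below`` / ``p_<outcome>_above`` give, per
    participant, the posterior probability that the LF-HC minus HF-LC
    difference lies below −δ / above +δ for each of the three glycemic
    outcomes (δ = 0.167 mmol/L MPG, 0.072 mmol/L MAGE, 13.889 mmol/L·h
    AUC24). Values are percentages as reported, so 100 means certainty.
    """
    with resources.files("nof1cgm.data").joinpath("reference_posteriors.csv").open() as fh:
        return pd.read_csv(fh, dtype={"participant_id": str})


def reference_posterior_summaries() -> list:
    """The reference table as :class:`~nof1cgm.bayes.PosteriorSummary` objects.

    Only the tail probabilities are carried by the table; effect means and
    credible intervals are unknown and set to NaN.
    """
    df = load_reference_posteriors()
    out = []
    for _, row in df.iterrows():
        for outcome, col in (("MPG", "mpg"), ("MAGE", "mage"), ("AUC24", "auc24")):
            out.append(
                PosteriorSummary(
                    participant_id=row["participant_id"],
                    outcome=outcome,
                    beta_mean=float("nan"),
                    ci95=(float("nan"), float("nan")),
                    p_above=float(row[f"p_{col}_above"]) / 100.0,
                    p_below=float(row[f"p_{col}_below"]) / 100.0,
                    n_obs=(0, 0),
                    rhat=1.0,
                    converged=True,
                )
            )
    return out
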
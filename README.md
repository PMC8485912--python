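# nof1cgm

Bayesian analysis of aggregated **n-of-1 diet-crossover trials** with
continuous glucose monitoring (CGM) outcomes.

## The problem

In an n-of-1 crossover trial each participant alternates repeatedly
between two interventions and serves as their own control. Applied to
nutrition, this design asks a precision-nutrition question the ordinary
parallel-group RCT cannot: *which* diet is better **for this person**?
Here the two interventions are isocaloric diet periods — low-fat /
high-carbohydrate (LF-HC, 65–75 %E carbohydrate) versus high-fat /
low-carbohydrate (HF-LC, 15–25 %E carbohydrate), protein fixed at 15 %E —
worn with a CGM sampling interstitial glucose every 15 min. Each
participant completes a leading washout then three randomized LF-HC/HF-LC
pairs of 6-day periods (block-of-2 randomisation), eating three scheduled
meals a day, giving 18 outcome observations per period.

Three glycemic outcomes are extracted per participant:

* **MPG** — maximum postprandial glucose: the peak CGM value within 3 h of
  a meal's first bite, truncated at the next meal when it comes sooner;
* **MAGE** — mean amplitude of glycemic excursions: the mean of
  consecutive peak↔nadir amplitudes exceeding 1 SD of the day's glucose;
* **AUC24** — area under the glucose–time curve from 00:00 to 24:00
  (mmol/L·h).

## The model

Within participant *i*, observations follow a normal linear model

    y = α + β·x + ε,   x ∈ {0 = HF-LC, 1 = LF-HC},  ε ~ N(0, σ²)

with noninformative priors (Normal(0, 10⁶) on α, β; InverseGamma(0.001,
0.001) on σ²) sampled by a conjugate Gibbs scheme. The posterior of the
diet effect β is compared with a prespecified clinically meaningful
difference δ (0.167 mmol/L for MPG, 0.072 for MAGE, 13.889 mmol/L·h for
AUC24): a participant is an **HC-responder** when P(β > +δ) > 80 %, an
**HF-responder** when P(β < −δ) > 80 %, otherwise a nonresponder.

Across participants, a hierarchical model

    y_ij = α_i + β_i·x_ij + ε_ij,   β_i ~ N(z_i'b, τ²)

with age/sex/BMI covariates z_i pools the individual series into a
population-level effect (the intercept of b), judged against a stricter
90 % posterior-probability threshold, with four sensitivity subsets
(all data / excluding withdrawals / completers / completers without
chronic disease or medication). A simulation-based power module checks
the aggregated design's operating characteristics, and a synthetic-cohort
generator (circadian baseline, meal excursion kernels, AR(1) sensor
noise, responder mixtures, realistic missingness) makes every stage
testable without any participant data.

## Worked example

```bash
nof1cgm run-all --out run/ --seed 0
```

runs the full pipeline — synthetic cohort → metrics → individual fits →
responder calls → hierarchical meta-analysis → power — and writes
`run/report.md`. The default cohort enrolls 30 participants (28
completers plus one partial completer with a full cycle, so 29 analysable
trials) with a 9 / 6 / 13 HC-responder / HF-responder / nonresponder
ground-truth mixture at ±0.3 mmol/L meal-peak effects. At seed 0 the
responder section reads

```
| Outcome | HC-responders | HF-responders | Nonresponders |
|---|---|---|---|
| MPG | 8 | 5 | 16 |
| MAGE | 8 | 8 | 13 |
| AUC24 | 0 | 0 | 29 |

Overall (MPG or MAGE): 8 HC-responders, 8 HF-responders, 13 nonresponders
```

MPG calls track the planted mixture closely (the ±0.3 mmol/L effects sit
less than 2δ above the 0.167 mmol/L threshold, so a borderline
participant can fall either way); MAGE, judged against its much tighter
δ = 0.072 mmol/L, additionally flags borderline participants; and AUC24
yields no responders at all because the generative diet effect shifts
meal-excursion *peaks*, not the basal level — the area under a full day's
curve barely moves. The group-level table shows a small pooled effect
with low posterior probability of exceeding δ: a cohort of opposing
responders cancels at the population level, which is exactly why the
individual-level analysis matters. The power section prints, for the
printed design and default noise,

```
Estimated power: 100.0% (MC 95% CI 98.2–100.0%), type-I error 5.0% at two-sided α = 0.05
```

A library-level example of the responder rule on the bundled reference
table of 28 participants' posterior tail probabilities:

```python
from nof1cgm.bayes import classify_responder, summarize_cohort_calls
from nof1cgm.datasets import reference_posterior_summaries

calls = [classify_responder(s, 0.80) for s in reference_posterior_summaries()]
print(summarize_cohort_calls(calls).per_outcome["MPG"])
# {'HC-responder': 7, 'HF-responder': 3, 'nonresponder': 18}
```

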
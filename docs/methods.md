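# Methods

This note documents the models, algorithms, default parameters and design
choices behind `nof1cgm`, and what the synthetic cohort does and does not
emulate.

## Study design assumed

Each participant's schedule is a leading 6-day washout followed by
`n_sets` (default 3) pairs of 6-day intervention periods; within each
pair the LF-HC / HF-LC order is randomized with block size 2 (a fair coin
per set). Within every period, days 1–3 and 4–6 carry two
sub-compositions: LF-HC 65 then 75 %E carbohydrate, HF-LC 25 then 15 %E,
washout 55 %E throughout; protein is fixed at 15 %E and fat fills the
remainder. Three meals per day are scheduled (breakfast 07:00–09:00,
lunch 11:00–13:00, dinner 17:00–19:00), so a 6-day period contributes 18
meal-level observations. Washout days are simulated and parsed — so
period-boundary logic is exercised — but excluded from all outcome
series.

## Glycemic metrics

**Units.** Glucose is held in mmol/L; mg/dL inputs are divided by exactly
18.0. That factor reproduces the three clinically meaningful thresholds
to their printed precision (3 mg/dL → 0.167 mmol/L, 1.3 mg/dL → 0.072
mmol/L, 1.5×10⁴ mg/dL·min → 13.889 mmol/L·h), which is why it is fixed
rather than the physically exact molar-mass ratio (≈18.016). The AUC24
threshold is stored as 13.889 mmol/L·h.

**MPG.** Maximum over the half-open window [first bite, first bite + 3 h),
truncated at the next meal's first bite when the gap is shorter; a sample
exactly at the next meal's start belongs to the next meal. Ties take the
earliest timestamp. Missed meals yield no MPG observation.

**MAGE.** Computed per calendar day: (1) the day's sample SD (n−1
denominator); (2) turning points as strict sign changes of successive
differences, with plateaus collapsed to their midpoint; (3) consecutive
peak↔nadir amplitudes qualify when strictly greater than 1 SD; (4) MAGE
is the mean of qualifying absolute amplitudes, missing when none qualify
(a constant day has SD 0 and no turning points, hence missing). Both
directions are counted by default, matching the "differences between
consecutive peaks and nadirs" reading; the classic first-direction-only
convention is available (`mage_direction="first"`). No smoothing is
applied by default; an optional 3-point median filter exists. Per-day
(rather than per-6-day-period) computation was chosen because the day is
the unit at which the outcome enters the treatment model; the SD
denominator and the per-day unit are both conventions the source
definitions leave open.

**AUC24.** Trapezoidal integral of glucose versus time over 00:00–24:00
in mmol/L·h. A day slice includes the closing midnight sample; when edge
samples are missing the first/last values are carried to the boundaries
(constant extrapolation), so a constant 5 mmol/L day integrates to
exactly 120 mmol/L·h on the standard 96-sample grid. No gap
interpolation beyond that.

**Missing-data rules.** A meal not consumed contributes no MPG; a day
with all three meals missed contributes no MAGE/AUC24 (partially missed
days are retained); days with CGM coverage below 70 % of the expected 96
samples are missing for MAGE/AUC24. The 70 % floor is a package choice
(the defining sources are silent); it is configurable and logged.

## Individual treatment-effect model

Observation-level normal regression `y = α + β·x + ε` with x = 0 (HF-LC)
/ 1 (LF-HC), so β > 0 means higher glycemia on high carbohydrate. Priors:
Normal(0, 10⁶) on α and β on the outcome's mmol/L scale ("large
variance"), InverseGamma(0.001, 0.001) on σ². All full conditionals are
conjugate; the Gibbs sampler draws (α, β) jointly from the exact
bivariate-normal conditional and σ² from its inverse-gamma conditional,
vectorised across chains. Defaults: 4 chains × 10,000 iterations, 2,000
burn-in, no thinning; convergence is flagged by split-chain R̂ ≥ 1.05.
The fit is at observation level (meal-level MPG; day-level MAGE/AUC24),
which uses all data and matches the 18-observations-per-period design; a
set-wise paired-mean-difference variant is available (`paired=True`).
With these priors the β posterior is numerically indistinguishable from
the flat-prior Student-t form, which the test suite uses as an
independent closed-form oracle (agreement within ±0.02 in tail mass).

Responder rule: HC-responder iff P(β > +δ) > 0.80, HF-responder iff
P(β < −δ) > 0.80, else nonresponder; the two one-sided tails are assessed
separately. Overall labels take the union over MPG and MAGE; a
participant HC on one and HF on the other would be flagged for manual
review rather than counted.

Dose–response contrasts compare each carbohydrate level {25, 65, 75} %E
against the 15 %E reference with the same model on the relevant subset,
and report whether posterior mean differences are ordered in carbohydrate
level.

## Hierarchical meta-analysis

Two-level normal model: within-participant regression as above with a
common residual variance; participant intercepts α_i ~ N(μ_α, ω²);
participant effects β_i ~ N(z_i'b, τ²) with z_i = (1, age, sex, BMI).
Age and BMI are z-scored and sex (0/1) is centred, so the intercept of b
is the population effect at the covariate mean and the flat priors are
comparably diffuse across coefficients; a constant covariate (e.g. a
single-sex cohort) is dropped with a warning. Priors: Normal(0, 10⁶) on
all locations, InverseGamma(0.001, 0.001) on ω², τ², σ² — the
inverse-gamma family is the conventional noninformative choice for
variance components and its hyperparameters are stated in the output
rather than hidden. Group-level evidence uses the two-tailed mass
P(effect > +δ) + P(effect < −δ) against a 0.90 threshold (stricter than
the individual 0.80 rule, to control group-level type-I error); the
dominant single tail is also reported since either convention is
defensible. Serial correlation is available as an AR(1) residual switch
(generalised-least-squares prewhitening within each participant-period
run at a fixed ρ) and is OFF by default: no structure or estimate exists
to calibrate it against.

Four sensitivity subsets are built from participant metadata: all
available participants; excluding early withdrawals; completers with ≥50 %
valid meal-level CGM; completers additionally free of chronic disease and
prescription medication.

## Power simulation

Each simulated trial draws β_i ~ N(effect, between_sd²), generates every
observation (n_sets × 2 periods × obs_per_period per participant at the
residual sd), and pools per-participant arm-mean differences with a
random-effects meta-analysis: DerSimonian–Laird moment estimate of τ²
and a Knapp–Hartung t interval. This closed-form path stands in for the
hierarchical Gibbs fit inside the simulation loop purely for speed; their
agreement on the pooled effect is itself a test. Detection means the
two-sided 95 % interval excludes zero (default) or, under the
`posterior_prob` rule, that the posterior mass beyond ±δ exceeds the
group threshold. Power carries an exact Clopper–Pearson Monte-Carlo
interval, and a second pass at effect 0 reports the empirical type-I
error (the Knapp–Hartung form keeps it at the nominal 5 %).

The within/between noise magnitudes have no published values; the
defaults — residual sd 0.8 mmol/L, between-participant effect sd 0.1
mmol/L — are deliberately conservative for meal-level MPG in a
normoglycemic cohort, and the headline power figure is always reported
together with its sensitivity across a residual-sd band of 0.5–1.0
mmol/L.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

* 15-min CGM grid, 96 samples/day plus the closing midnight sample;
* glucose(t) = baseline + circadian sinusoid + Σ meal excursions + AR(1)
  noise; the excursion kernel (t/45)²·exp(2 − 2t/45) rises to 1 at
  45 min and decays to ~0 by 3–4 h;
* the diet effect shifts the **excursion peak height** on LF-HC days
  (A = meal_response_base + diet_effect·1[LF-HC], optionally +
  carb_dose_slope·(carb%E − 15)), not the basal level — so MPG and MAGE
  respond while AUC24 responds only weakly, reproducing the qualitative
  pattern that area-under-curve outcomes yield no responders;
* responder mixture (default 9/28, 6/28, 13/28 at ±0.3 mmol/L) allocated
  exactly over the analysis set by largest-remainder counts;
* missingness: meals skipped independently at 2 % (≈98 % adherence), two
  early withdrawals who keep one completed set, and one participant with
  simulated sensor failure (<50 % valid data);
* everything flows from one `SeedSequence`: same seed, byte-identical
  CSVs.

Defaults (baseline 4.5 mmol/L with 0.25 between-participant sd, circadian
amplitude 0.3, meal response 2.0, noise sd 0.3, AR(1) ρ 0.7) put fasting
glucose near a healthy young-adult median (~4.2–4.5 mmol/L) and peak
postprandial values in the normoglycemic range. Because no within-person
outcome variances are published for this design, these are plausible
placeholders — parameter-recovery tests show the pipeline recovers what
the generator planted, not that real CGM data behave identically. The
generator deliberately omits: glucose–insulin physiology (no ODE model),
meal-composition effects beyond the single amplitude shift, sensor drift
and calibration artefacts, day-to-day adherence correlation, and any
microbiome/metabolomic covariates.

## Numerical choices and edge cases

* Tie-breaks: MPG maxima take the earliest sample; MAGE plateaus collapse
  to their midpoint.
* Degenerate inputs: <3 samples → MAGE missing; single sample → AUC24
  missing; an arm with <2 observations → explicit insufficient-data
  error; constant traces classify as nonresponders (no qualifying
  excursion, near-zero effect posterior).
* Gibbs initialisation: least-squares point estimates with overdispersed
  multiplicative jitter on the variance; residual SSR floored at 1e-12 to
  keep inverse-gamma draws finite on exactly-constant data.
* Problem sizes: tests and the bundled pipeline run the samplers at 4
  chains × 2,000–3,000 iterations and the power simulator at 100–500
  trials — sizes at which every Monte-Carlo tolerance in the suite is
  several times the corresponding standard error; the 10,000-iteration
  defaults remain available for production runs.
* A single-participant hierarchical fit is allowed, but its
  population-level location is heavy-tailed (the noninformative
  inverse-gamma τ² posterior has no finite moments with one effect
  observation); the participant-level (shrunken) posterior is the stable
  quantity there.

## Known limitations

* The FreeStyle-Libre-style export reader is a best-effort convenience:
  no authoritative device export schema exists to validate against.
* The AR(1) residual option uses a fixed, user-supplied ρ; it is not
  estimated.
* No incremental AUC, time-in-range, CONGA or other variability indices;
  no gap interpolation; no informative priors; no multiplicity correction
  across participants (none is applied in this analysis tradition).
* Group-level conclusions inherit whatever covariate imbalance the cohort
  carries; only age, sex and BMI are adjusted.
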
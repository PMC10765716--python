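# Methods

## Frailty index

The FI follows the standard deficit-accumulation procedure: each of 41
items maps raw survey responses to a score in [0, 1], and the index is
the mean score over items with valid data. Design choices:

* **Missingness rule.** "More than 80% valid" is implemented strictly:
  `n_valid / n_items > 0.80`, so with 41 items at least 34 must be valid
  (32/41 ≈ 78% is undefined). No imputation is performed beyond this
  denominator rule; an all-missing record yields an undefined FI with an
  explanatory reason rather than an exception.
* **Category boundaries.** Robust is FI < 0.10; frail is strictly
  FI > 0.21; pre-frail is the closed interval [0.10, 0.21]. The strict
  upper inequality is forced by the equivalence "frail ⇔ 9+ deficits of
  41" (9/41 ≈ 0.2195 > 0.21, while 0.21 itself is pre-frail); symmetry
  places 0.10 in pre-frail.
* **BMI.** The body-mass item accepts either a numeric BMI (bands:
  [18.5, 25) → 0, [25, 30] → 0.5, otherwise 1, edges inclusive as
  written) or a precomputed band code; numeric input takes precedence.
* **Unknown codes are errors.** A response that is neither missing nor a
  declared level raises a scoring error naming the item and value.
  Treating it as missing would silently erode the >80% rule. Level codes
  take precedence over missing-value sentinels, since `none` is a valid
  level of several graded items.
* **Precision.** FI values are kept at full float precision; rounding
  (2 d.p. for FIs, 1 d.p. for percentages — half-up, matching common
  table formatting) happens only in report rendering.
* The default codebook stores target prevalences per level for the
  generator. Three published cells are obvious decimal-shift misprints
  (rows summing far from 100%); they are stored corrected and flagged in
  the codebook comments. Each item's level fractions are renormalized to
  sum to 1 before use.

The sensitivity index drops the four flagged cardiovascular items
(myocardial infarction, coronary heart disease, hypertension, stroke),
leaving 37 items; the validity rule re-evaluates against 37.

## Synthetic cohort generator

The generator emulates a community-dwelling 65+ health-interview cohort
with linked mortality follow-up. It is a modelling device with known
truth, not a re-creation of any particular survey's joint distribution.

**Demographics.** Age is 65 + Gamma with mean 7.1 y and SD 5.8 y — right
skewed, support exactly ≥ 65, matching the target mean (72.1) and SD
(5.8) of the emulated population. Sex is Bernoulli(0.547 female),
education multinomial (28.3 / 51.3 / 20.4% low/medium/high). The
living-alone fraction is not published for the emulated cohort; the
default 0.31 is a typical value for European 65+ survey populations.

**Deficits.** A single-factor Gaussian liability
`z = 0.35·age_std + 0.25·female + 0.35·low_education + ε` (standardized)
drives all items: each item's latent is `λ·z + √(1−λ²)·noise` with a
common loading λ = 0.5, cut into levels at the *empirical quantiles* of
the simulated latent corresponding to the item's cumulative target
fractions. Empirical-quantile calibration keeps every item's marginal
level frequencies on target under any loading (a normal-theory threshold
would drift, because z is not exactly Gaussian). Only marginals are
published for such instruments; the dependence strength λ is therefore a
free knob, chosen once as the simplest value producing a right-skewed FI
(sample skewness ≈ 1.1) with the expected age/sex/education gradients
and category fractions (≈ 43 / 40 / 17% robust/pre-frail/frail at
defaults). Item-level missingness (default 1% per item) is injected
after scoring; the *true* FI used for hazard generation comes from the
complete pre-missingness responses, keeping the ground truth
unambiguous.

**Survival.** Three competing causes (CVD, cancer, other) have
independent latent Gompertz times with hazard
`scale_k · exp(shape_k · t) · exp(lp_k)`, where
`lp_k = log(HR_k)·FI/0.1 + β_age·(age−72.1) + β_female + β_alone`.
Default per-0.1-FI hazard ratios are 1.25 (CVD), 1.19 (cancer), 1.52
(other); the implied all-cause association is ≈ 1.33 per 0.1 FI.
Gompertz (not exponential) baselines make mortality age-accelerating,
and cause-specific age effects (CVD strongest, cancer weakest) reproduce
the qualitative ordering of mean age at death (cancer < other < CVD).
Baseline scales were calibrated once so a default n = 20,000 cohort dies
of the three causes at ≈ 5.8 / 5.0 / 5.1% over the 8-year window; the
calibrated values are frozen as defaults. Censoring is purely
administrative: entry is staggered uniformly over `entry_spread` years
before a fixed end of follow-up at 8 years. With uniform entry on
[0, w], censored follow-up is uniform on [8−w, 8], so median follow-up
is 8 − w/2 and IQR w/2; the default w = 1.6 y gives median 7.2 y.
`calibrate_followup` inverts this closed form (with a simulation check)
for other targets. Everything is driven by one seed via split
`SeedSequence` streams, so identical configs give byte-identical
exports.

**What the generator does not model** — and hence what passing tests do
not establish about real data: inter-item dependence beyond one factor,
item-specific missingness patterns, loss to follow-up or informative
censoring, time-varying frailty over follow-up, survey weighting, and
measurement error in self-reports. Parameter-recovery results show the
estimators are correct under the generating model, not that any real
cohort satisfies it.

## Estimation layer

* **Kaplan–Meier / Aalen–Johansen.** Both estimators are computed from a
  shared per-death-time risk-set table (persons censored at a death time
  count as at risk there, i.e. deaths precede censorings at ties). This
  guarantees the accounting identity `1 − KM(t) = Σ_k CIF_k(t)` at every
  death time to machine precision — a property we assert in tests. The
  implementations are cross-checked against lifelines' fitters; we do
  not use lifelines' Aalen–Johansen directly because it jitters tied
  event times, which breaks the identity on discretized data.
* **Cause-specific Cox.** Deaths from competing causes are censored at
  their death time; all-cause treats every death as an event. This is
  the cause-specific hazard formulation — no subdistribution (Fine–Gray)
  models are provided. Fitting is delegated to lifelines'
  `CoxPHFitter` (Efron tie handling, the de-facto standard). The FI
  enters either as FI/0.1 (hazard ratio per 0.1 increment) or as
  pre-frail/frail indicators against a robust reference; education as
  medium/high dummies against low. The default adjustment set is sex,
  living alone and education — age is exposed as an explicit
  `adjust_age` switch rather than silently included, since adjustment
  conventions for socio-demographics differ and the choice materially
  changes the FI coefficient whenever age both drives mortality and
  correlates with the FI (as in the generator). Parameter-recovery
  tests fit with age adjusted, because age is in the generating hazards;
  the default report omits it.
* **Harrell's C.** A pair is comparable when the strictly shorter time
  ends in an event; tied times are not compared; tied risk scores count
  0.5. The confidence interval uses the influence-function (asymptotic
  U-statistic) variance of the concordant/comparable ratio — lifelines
  and scikit-survival return only the point estimate, so the CI is
  implemented here and the point value is verified against both an
  O(n²) double-loop oracle and lifelines' `concordance_index`. The
  computation is chunked O(n²) in vectorized blocks; adequate to
  n ≈ 20,000.
* **PH diagnostics.** Scaled-Schoenfeld score tests via lifelines with
  the Kaplan–Meier time transform by default (identity available); the
  global statistic sums per-covariate chi-squares. The test requires
  more events than covariates.
* **Interaction LRT.** FI-by-sex (1 df) or FI-by-education (2 df for a
  continuous FI) product terms; the reduced model is fit on the
  identical row set, and twice the log-likelihood difference is referred
  to chi-square. The statistic is floored at 0.

## Numerical and degenerate-input conventions

Zero events raise a dedicated `NoEventsError` (a cohort censored at
entry errors at fitting, not at scoring). An all-censored Kaplan–Meier
returns the constant-1 curve with a warning. Empty categories are
omitted from grouped incidence curves with a warning, and their
percentage cells render as an em dash. Non-finite hazards in the
generator raise immediately. Report rounding is decimal half-up (HRs
2 d.p., concordance 3 d.p., percentages 1 d.p.).

## Problem sizes used in the checks

Desk-scale defaults keep everything single-CPU friendly: estimator
oracles run on ≤ 500-row fixtures; distributional checks of the
generator use one n = 20,000 cohort; hazard-ratio CI coverage uses 150
replicates at n = 5,000 (enough that the binomial noise of a ~95%-
coverage estimate stays well clear of the 90% requirement); null
calibration of the PH test and interaction LRT uses 50 replicates each.

## Known limitations

Cause labels are a fixed three-way partition; finer cause groupings,
survey weights, multiple imputation, time-varying covariates or frailty
(random-effect) terms, and Fine–Gray subdistribution hazards are out of
scope. The concordance CI is asymptotic (no bootstrap). The generator's
dependence model is deliberately minimal — one latent factor — and its
hazard parameters, while calibrated to plausible 65+ mortality margins,
are not estimates from any real cohort.
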
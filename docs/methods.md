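# Methods

This note documents the statistical models implemented in `jdmsm`, the
conventions and numerical choices behind them, what the synthetic cohort
generator does and does not emulate, and the package's known limitations.

## Data model and conventions

Time is measured in months since diagnosis (diagnosis = 0); calendar dates
never enter the package. Scores follow the standard juvenile
dermatomyositis instruments: modified skin DAS in [0, 5] and physician's
global assessment (PGA) in [0, 10], higher = worse; muscle CMAS in
[0, 52], lower = worse. Scores are stored as continuous values.

Treatment recency ("split time") partitions every patient-visit into
never/not-yet, ≤6 months since CYC start, 6–12 months, and >12 months.
Boundaries are half-open with the boundary month assigned to the earlier
category (exactly 6 months after initiation codes as ≤6 months): the
published category labels do not fix a convention, and half-open intervals
guarantee a partition with categories that are non-decreasing along any
trajectory.

A single treatment course is assumed throughout: `cyc_start`/`cyc_stop`
are per-patient scalars, `on_cyc` must equal `cyc_start ≤ t < cyc_stop`
at every visit, and a visit pattern implying a second course is rejected
at validation time (split-time coding is undefined for re-treatment).

Eligibility filtering retains incident cases: first recorded visit at most
3 months after diagnosis (strictly greater excludes — the criterion's
wording does not resolve the boundary, so "exceeding" is read strictly)
and a known CYC start date for anyone with recorded CYC exposure.

Visits are aligned to nominal 0/6/12/24-month time points (for the
descriptive analysis, relative to CYC start) by choosing the visit
minimising |t − nominal| within a ±2-month window; equidistant ties go to
the earlier visit, deterministically.

## Synthetic cohort generator

No patient-level data are shipped; every experiment runs on cohorts from
`simulate_cohort`, which emulates the structure that makes this analysis
hard — treatment assignment driven by observed severity.

**Latent severity.** Each patient carries a scalar severity s on the 0–10
global scale. Baseline severity is Normal(6.5, 1.5²), shifted −0.08 per
year of age at diagnosis above 8 (younger children present sicker) and
clipped to [4.0, 9.5]. Severity declines linearly at 0.015 units/month
(natural improvement under first-line therapy) plus mean-reverting
deviations: an Ornstein–Uhlenbeck process with stationary sd 0.9 and
reversion rate 0.06/month (deviation half-life ≈ 11.5 months). The linear
trend is deliberate: the analytical model adjusts for time linearly, so
the generator's time effect is inside the model class and recovery
experiments isolate the weighting machinery rather than trend
misspecification. The severity floor and deviation spread keep planted
effects acting in the interior of the clipped score ranges (a shift that
pushes scores against a bound would be attenuated mechanically).

**Observed scores.** DAS = 0.5·s, PGA = s, CMAS = 52 − 4.2·s, each plus
Gaussian noise (sd 0.45, 0.8, 3.5 respectively) and clipped to range; a
glucocorticoid dose decays exponentially with time. One latent factor
driving all three scores is the simplest structure reproducing their
mutual correlation.

**Visits.** A renewal process: gamma-distributed gaps with mean 1.2
months during year 1 and 4.0 months thereafter (shape 2, minimum gap 0.25
months), per-patient follow-up uniform on 0.55–1.45 × 7.5 years (so every
patient has ≥ 2 years). Visit frequency is a modelling choice — the
published analysis does not characterise it.

**Treatment initiation.** At each visit an untreated patient starts CYC
with probability expit(c + 2·β·DAS + γ·t), with β = 0.4 (the
`confounding_strength`, log-odds per severity unit — the recorded skin
score rescaled to the 0–10 scale), γ = −0.25/month (starts concentrate
shortly after diagnosis) and an extra −1.5 offset at the first visit
(baseline receipt is rarer than early initiation). The intercept c is
calibrated by bisection so the expected treated fraction, given the
realised visit schedules, equals the 28% target; assignment then consumes
pre-drawn uniforms, keeping a fixed seed bit-reproducible. Making the
hazard depend on the *recorded* (noisy, never-missing) skin score rather
than latent severity means the probability-of-treatment model below is
correctly specified, so recovery experiments have a well-defined truth.
Median time to initiation is ≈ 1.5–2.5 months, with baseline-severity
imbalance between eventually-treated and never-treated patients of
roughly 1.3 PGA units — the confounding-by-indication signature.

**Course and effects.** Course length is log-normal (median 5.2 months,
log-sd 0.2565, matching a ≈ 4.6–6.5-month interquartile range) truncated
to [3, 9] months; everyone completes (no discontinuers). Treatment
effects are additive shifts per split-time category, applied to visits
strictly after the initiation visit (scores at that visit are
pre-infusion assessments) and re-clipped to range. Defaults plant the
published point estimates — DAS −1.19 and PGA −0.66 for the >12-month
category, nothing elsewhere.

**Missingness.** Items are deleted completely at random per visit: PGA
25%, CMAS 26%, glucocorticoid dose 55% (long-run averages of the
published per-window percentages), DAS never (its rate must be 0). An
`informative_missingness` switch ties the missingness odds to the visit's
PGA for sensitivity experiments.

**Concomitant medications and clinical features** are static per-patient
flags with severity-dependent prevalence (e.g. intravenous
glucocorticoids ≈ 48%, IVIG ≈ 17%, biologics ≈ 14% at mean severity),
reproducing the direction of the treated-vs-untreated imbalance.

**What it does not emulate** — and hence what passing tests do *not*
establish about real registries: visit schedules independent of disease
state (real sick patients are seen more often), missingness unrelated to
severity by default, integer-valued instruments, autoantibody subgroups,
unmeasured confounders (the generator's assignment depends only on
recorded scores), loss to follow-up correlated with outcome, and any
second treatment course.

## Descriptive battery

* 2×2 comparisons use Pearson's chi-square **with** the Yates continuity
  correction (the published p-values reproduce only with it) or Fisher's
  exact test with the two-sided p defined by the probability-mass method
  (sum of table probabilities not exceeding the observed one — the
  convention of R's `fisher.test`).
* Group comparisons of numeric variables use the two-sample rank-sum
  test: exact enumeration of group assignments (ties handled via
  mid-ranks) when the combined n ≤ 10, otherwise the tie-corrected normal
  approximation. (The published table labels these comparisons "signed
  rank", but the groups are independent, so rank-sum is what is meant.)
* Friedman's repeated-measures test uses within-block mid-ranks with the
  tie-corrected statistic; the default p is the chi-square approximation
  with k−1 df (the convention of the original analysis), with
  `method="exact"` enumerating all (k!)^n within-block orderings for
  small problems (guarded at 200 000 orderings). Blocks with any missing
  time point are dropped (complete-case analysis).
* Signed-rank post hocs drop zero differences before mid-ranking
  (classical convention), enumerate all 2^n sign assignments exactly for
  n ≤ 15 nonzero differences, and use the tie-corrected normal
  approximation (variance Σr²/4, no continuity correction) beyond;
  all pairwise time-point comparisons are flagged against the Bonferroni
  threshold α/m.

## Multiple imputation

Missing PGA and CMAS values are completed m = 5 times by chained
equations with normal linear conditional models and proper Bayesian
draws: per variable, σ² is drawn from the scaled inverse-χ² posterior,
coefficients from their Normal posterior, and missing cells from the
predictive distribution, clipped to the score's range; 5 Gibbs sweeps per
set. Predictors are the (complete) skin score, the other incomplete
score's current completion, time since diagnosis, current treatment
state, the split-time category, age at diagnosis, the patient's
first-visit skin score, and the nearest *observed* earlier and later
values of the score being imputed (patient-mean fallback at the edges).
The last three points matter: the imputation model must include the
analysis model's treatment-recency covariate (congeniality — omitting it
measurably distorts treatment effects in imputed cells), the baseline
score carries persistent-severity information that current-visit values
alone do not, and the neighbouring observed values give the model the
longitudinal structure of the scores — they are strongly autocorrelated
between adjacent visits, and without them imputed cells are noticeably
flatter than real trajectories, which attenuates treatment effects
estimated from them. Glucocorticoid dose
is excluded from imputation and from all models by default: over half of
its values are missing, plausibly informatively. Observed cells are never
altered, and each set draws from an independently spawned generator so a
fixed seed yields bit-identical sets with genuine between-set
variability.

## Probability-of-treatment model

Treatment states change on the visit grid (registries record treatment at
clinic visits), giving a discrete-time hazard factorisation with three
sub-models:

1. **baseline receipt** — logistic in baseline DAS, PGA, CMAS and age,
   over patients. Baseline events are few, so a constant target falls
   back to an add-half smoothed empirical fraction, and separation
   triggers a light ridge refit inside the orchestrator (calling
   `fit_baseline_model` directly with `penalty=0` raises a
   `SeparationError` naming the covariate and advising the penalty
   switch);
2. **initiation** — pooled logistic over visits of not-yet-treated
   patients (the visit where CYC starts counts as an event, with
   covariates measured at that visit — the clinical decision uses the
   current assessment), with current DAS/PGA/CMAS, time since diagnosis,
   age and flags for intravenous glucocorticoids, IVIG and biologics;
   cluster-by-patient robust variance;
3. **discontinuation** — logistic in time-on-treatment over visits
   following an on-treatment visit. Because stopping is protocolized
   (course completed at ~5–6 months, no discontinuers), this model is
   expected to quasi-separate; separation — detected by non-convergence,
   coefficient magnitude, or fitted probabilities collapsing to 0/1 —
   routes to a banded empirical hazard (bands [0,3), [3,4.5), [4.5,6),
   [6,9), [9,∞) months on treatment, add-half smoothing), which keeps
   every probability strictly inside (0, 1).

Once a course is complete, treatment history is fixed and a visit's
probability factor is exactly 1. Any sub-model probability reaching 0 or
1 in floating point raises a `PositivityError` — weights must not be
built on a positivity violation. Zero-variance covariates are dropped
automatically (logged in the fit object), which also yields the
intercept-only reduction: with constant covariates each sub-model's
prediction equals the empirical event fraction.

## Weights

The raw weight at visit k is the running product over u ≤ k of
numerator/denominator state probabilities. Denominators condition on the
covariate history above. **Numerators condition on time only** (intercept
at baseline, time since diagnosis for initiation, time-on-treatment for
stopping): a stabilization numerator may only contain covariates the
final analytical model also adjusts for, and that model adjusts for time
and treatment recency alone — putting age or sex in the numerator leaves
the pseudo-population balanced only conditionally on them and leaks
residual confounding into the marginal estimate. Time-on-treatment is a
function of treatment history, not a confounder, and using the same
structure in both numerator and denominator makes the (unconfounded,
near-deterministic) stop factors cancel instead of inflating weight
variance. An unstabilized mode (numerator ≡ 1) is available for
comparison.

Weights are truncated at 20 by default — the conventional cap, kept
configurable precisely because it is conventional. On well-specified
synthetic cohorts the mean raw stabilized weight is ≈ 1.0 and truncation
is rarely active.

Balance diagnostics compare never/not-yet patient-visits with treated
patients at their course-start visit, per 3-month bin of time since
diagnosis over the first two years: unweighted and weighted means with
normal-approximation 95% intervals, plus an average absolute
standardized-difference summary. Empty bins are flagged, not fabricated.

## Outcome model and pooling

Each outcome is regressed on an intercept, time since diagnosis (linear
by default) and the three non-reference split-time dummies
(reference: never/not yet treated), using the truncated weights. With an
identity link and independence working correlation the estimating-equation
solution *is* weighted least squares, so the fit is computed by WLS with
a cluster-by-patient robust sandwich variance evaluated at the weights;
independence working correlation is required for valid point estimation
with inverse-probability weights. A split-time category with no observed
visits is reported as inestimable, never silently dropped. Per-category
Wald inference uses a t reference with (patients − parameters) degrees of
freedom.

Across the m imputed sets, Rubin's rules combine each coefficient: pooled
estimate = mean; total variance T = W + (1 + 1/m)B with W the mean
squared SE and B the between-set variance; confidence intervals and
p-values use Barnard–Rubin small-sample degrees of freedom (with B = 0
collapsing to the complete-data df). The identity T = W + (1 + 1/m)B is
exact by construction and asserted in tests.

`run_msm` orchestrates eligibility → imputation → per-set PoTM
(denominator and numerator) → per-set truncated weights → per-set
outcome fits → pooling, recomputing weights for every imputed set, and
logs per-stage record counts and weight summaries. A cohort with no
treated patients short-circuits to unit weights and reports every
treatment category as inestimable.

## Validation experiments and problem sizes

The test suite validates the pipeline at the scale of the study it
mirrors: 100 replicate cohorts of n = 200 patients (~28% treated, m = 5
imputations) for effect recovery, confidence-interval coverage,
confounding-bias reduction and weight behaviour, and another 100
replicates with all effects zero for type-I error; exact-test
implementations are checked against brute-force enumeration (all 2×2
tables with total ≤ 40 for Fisher; full permutation enumeration for small
Friedman and signed-rank problems). Sub-model coefficient recovery uses
cohorts of 1 000–2 000 patients where asymptotics are sharp.

## Known limitations

* **Finite-sample IPTW attenuation.** At n = 200 with material
  confounding, the weighted estimator retains a small bias toward the
  unadjusted estimate (~1–2% of the effect). It shrinks with n and is
  present even with the generating-model weights, i.e. it is a property
  of ratio-weighted estimators at this scale, not of the implementation.
* **Conservative confidence intervals.** The sandwich variance treats the
  weights as known. Estimating them from the same data — with confounders
  that are essentially the outcome scores themselves — reduces the true
  sampling variance well below the sandwich estimate (reported SEs run
  ~40–45% above the empirical sampling sd in replicate experiments), so
  nominal 95% intervals cover planted effects ~99–100% of the time. This
  is the standard behaviour of IPTW analyses that do not stack the
  treatment-model and outcome-model estimating equations; the p-values
  err on the cautious side.
* No censoring weights: loss to follow-up simply contributes fewer
  visits, as in the original design; informative dropout is not modelled.
* Missingness is handled as missing-at-random; the generator's default is
  in fact MCAR, so the imputation machinery is exercised under milder
  conditions than a real registry may present.
* The discontinuation fallback's band edges are fixed; with course
  lengths far outside 3–9 months the bands would need revisiting.
* No dynamic-regime or doubly-robust estimators; the forest output is
  tabular (no plotting).
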
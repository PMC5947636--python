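# jdmsm

Marginal structural models for the effect of a time-varying treatment in
juvenile dermatomyositis (JDM) cohort data.

## The problem

JDM is a rare autoimmune disease of childhood. When first-line therapy
(glucocorticoids, methotrexate) is not enough, a short course of
cyclophosphamide (CYC) may be given — but its efficacy is hard to
establish: randomized trials are infeasible at such low incidence, and in
registry data the sicker children are both more likely to receive CYC and
more likely to do badly. A naive comparison is therefore biased *against*
the drug (confounding by indication), and the confounder — disease severity
— changes over time and is itself affected by treatment.

`jdmsm` implements the full analysis chain for this setting, aimed at
biostatisticians working with longitudinal registry data:

* **cohort I/O and eligibility** — long-format patient/visit tables as
  delimited text, range and consistency validation, incident-case
  filtering (first visit within 3 months of diagnosis, known CYC start);
* **descriptive battery** — chi-square (continuity-corrected) and Fisher
  group comparisons, rank-sum tests, Friedman repeated-measures analysis
  over visits aligned to nominal 0/6/12/24-month time points (±2 months),
  signed-rank post hocs with Bonferroni correction;
* **multiple imputation** — chained equations with proper posterior draws
  for missing PGA/CMAS scores, m = 5 completed data sets;
* **probability-of-treatment model (PoTM)** — three discrete-time logistic
  sub-models: CYC receipt at baseline, initiation while untreated,
  discontinuation while on treatment;
* **stabilized, truncated inverse-probability-of-treatment weights** with
  covariate-balance diagnostics;
* **weighted outcome models and Rubin pooling** — estimating-equation fits
  with cluster-robust variance, combined across imputations;
* **synthetic cohort generator** — severity-driven treatment initiation,
  planted lagged treatment effects, irregular visits and item missingness,
  so the whole pipeline is testable end to end with known ground truth.

## The model

Disease-activity scores (skin DAS 0–5 and physician's global assessment
PGA 0–10, higher = worse; muscle CMAS 0–52, lower = worse) are recorded at
irregular clinic visits. Treatment recency is coded by the "split time"
category

s(t) ∈ {never/not yet, ≤6 months since CYC start, 6–12 months, >12 months}.

For patient *i* at visit *k*, the stabilized weight is

    sw_ik = Π_{u ≤ k}  P(A_iu | A-history, t_iu)  /  P(A_iu | A-history, L_iu)

where A is the observed treatment state (receive / start / stop /
continue), L the covariate history (current DAS, PGA, CMAS, time since
diagnosis, age, concomitant medications) and the numerator conditions on
time only. Weights are truncated at 20. The final analytical model for
each outcome Y is the marginal structural model

    E[Y_ik] = β₀ + β₁ · t_ik + Σ_c β_c · 1[s(t_ik) = c]

fitted by weighted estimating equations (identity link, independence
working correlation, cluster-robust sandwich variance), once per imputed
data set, with Rubin's rules (T = W + (1 + 1/m)B, Barnard–Rubin degrees of
freedom) combining the m fits. β_c is the average difference in Y between
patients in recency category c and never/not-yet-treated patients at the
same time since diagnosis, free of measured time-varying confounding.

## Worked example

`python examples/run_msm.py` simulates a 200-patient cohort in which a
completed CYC course truly lowers DAS by 1.19 units and PGA by 0.66 units
after 12 months, then runs the full pipeline:

```
eligibility: retained 200, excluded 0
imputation: 5 sets, variables ['pga', 'cmas']
set 1: mean raw weight 0.994, 0 truncated at 20
...
pooled treatment-recency effects (reference: never/not yet treated):
outcome  category           coef               95% CI         p
das      cyc_le_6mo         0.04    [  -0.21,   0.29]    0.7319
das      cyc_6_12mo         0.09    [  -0.22,   0.40]    0.5573
das      cyc_gt_12mo       -1.08    [  -1.37,  -0.79]    0.0000 *
pga      cyc_le_6mo         0.19    [  -0.29,   0.67]    0.4303
pga      cyc_6_12mo         0.23    [  -0.50,   0.96]    0.5335
pga      cyc_gt_12mo       -0.51    [  -1.12,   0.10]    0.1019
...
planted >12-month effects: DAS -1.19, PGA -0.66
```

The >12-month DAS row recovers the planted −1.19 within its confidence
interval on this single cohort; `examples/parameter_recovery.py` repeats
the experiment across replicates and also shows the unweighted comparator
stalling near −0.76 — the confounding bias the weights remove. Mean raw
weights near 1 are the expected behaviour of stabilized weights. The other
examples cover the descriptive battery (`simulate_and_describe.py`,
`group_comparisons.py`) and weighted covariate balance
(`balance_diagnostics.py`).

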
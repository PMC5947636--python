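"""Generate a synthetic cohort and run the unadjusted descriptive analysis.

Simulates a 200-patient juvenile dermatomyositis cohort with severity-driven
cyclophosphamide (CYC) initiation, aligns treated patients' visits to nominal
0/6/12/24-month time points after CYC start, and tests whether skin disease
activity (DAS, 0-5, higher = worse) changes across those time points.
"""

from jdmsm import (
    SimulationConfig,
    change_summary,
    friedman_test,
    signed_rank_posthoc,
    simulate_cohort,
)

cohort, truth = simulate_cohort(SimulationConfig(seed=7))
treated = cohort.patients["cyc_start"].notna().sum()
print(f"cohort: {cohort.n_patients} patients, {treated} treated with CYC, "
      f"{len(cohort.visits)} visits\n")

summary = change_summary(cohort, "das")
print("skin DAS by nominal month after CYC start (treated patients):")
print(summary.table.round(2).to_string(index=False))

res = friedman_test(summary.complete_blocks)
print(f"\nFriedman test on {res.n_used} complete cases: "
      f"chi2[{res.df}] = {res.statistic:.1f}, p = {res.p_value:.2e}")

print("\nsigned-rank post hocs (Bonferroni-corrected):")
print(signed_rank_posthoc(summary.wide).round(4).to_string(index=False))

# The medians fall from ~4 at the start of treatment to ~2.5 at 24 months:
# part natural improvement, part the planted late treatment effect.  The
# Friedman p confirms the repeated-measures change; the post hocs show which
# time-point pairs differ after correcting for the 6 comparisons.
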
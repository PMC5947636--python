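"""Run the full marginal-structural-model pipeline on one synthetic cohort.

The cohort plants a true effect of a completed CYC course: after more than
12 months, skin DAS is 1.19 units lower and PGA 0.66 units lower than under
no treatment.  The pipeline multiply-imputes missing scores, fits the
three-part probability-of-treatment model per imputed set, builds
stabilized truncated inverse-probability weights, fits the weighted outcome
models and pools with Rubin's rules.
"""

from jdmsm import MsmConfig, SimulationConfig, forest_table, format_forest, run_msm, simulate_cohort

cohort, truth = simulate_cohort(SimulationConfig(seed=42))
result = run_msm(cohort, MsmConfig(m=5, seed=1, cap=20.0))

for line in result.logs:
    print(line)

print("\npooled treatment-recency effects (reference: never/not yet treated):")
print(format_forest(forest_table(result.pooled)))

planted = truth.effects["das"]["cyc_gt_12mo"], truth.effects["pga"]["cyc_gt_12mo"]
print(f"\nplanted >12-month effects: DAS {planted[0]:+.2f}, PGA {planted[1]:+.2f}")

# The >12-month rows should recover the planted negative effects within
# sampling error, while the <=6-month rows hover near zero (no early effect
# was planted).  Mean raw weights near 1 indicate well-behaved stabilized
# weights; the truncation count shows how many visit-weights hit the cap.
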
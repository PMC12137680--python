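"""Full pipeline on a synthetic meal-test cohort.

Simulates plasma (F, T) readings for a 6-pig cohort over the standard
sampling schedule, baseline-adjusts, splits every time point's total
signal into free / dipeptide-derived / tripeptide-derived equivalents,
and integrates to the AUC decomposition AUC_T = AUC_F + AUC_DD + AUC_TD.
"""

from aminogram import SimScenario, decompose_table, simulate_readings, summarize_groups

scenario = SimScenario(seed=42, noise_cv=0.1, n_subjects=6)
records = simulate_readings(scenario)
print(records.head(8).to_string(index=False))

decomp = decompose_table(records)
print("\nper-subject AUC decomposition (µg/mL·min):")
print(decomp[["subject_id", "auc_T", "auc_F", "auc_DD", "auc_TD"]]
      .round(0).to_string(index=False))

summary = summarize_groups(decomp)
print("\ngroup summary (mean ± SD):")
print(summary.round(1).to_string(index=False))

# Each subject's three components sum exactly to AUC_T; the summary rows
# are the heights of a stacked postprandial bar with error bars.
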
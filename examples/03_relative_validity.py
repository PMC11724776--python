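"""Relative validity of the screener against the FFQ-derived reference.

Simulates a cohort where caregivers over-claim points on the
questionnaire (social-desirability bias, strongest for items capping
less healthy foods), then computes per-item 2x2 agreement, Cohen's kappa
with 95% CI and interpretation band, the dichotomised total-score
agreement, and the Bland-Altman summary of the two totals.
"""

from med4child import (
    bland_altman,
    derive_table,
    generate_cohort,
    preset_biased,
    score_table,
    validate_items,
    validation_report,
)

cohort = generate_cohort(preset_biased(n=1500, seed=42))
results = validate_items(cohort.questionnaire, cohort.ffq)
report = validation_report(results)
print(report.round(3).to_string(index=False))

scored_q = score_table(cohort.questionnaire)
scored_f = derive_table(cohort.ffq)
paired = scored_q.merge(scored_f, on="child_id", suffixes=("_q", "_f"))
ba = bland_altman(paired["total_q"], paired["total_f"])
print()
print(f"Bland-Altman: mean difference {ba.mean_difference:+.2f} points "
      f"(administered - FFQ-derived), LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}]")
print()
print("Items capping unhealthy foods (12-18) show lower kappas than the")
print("Mediterranean-staple items — the signature of one-directional")
print("over-reporting — and the positive mean difference shows the")
print("administered score overstates adherence relative to the FFQ.")
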
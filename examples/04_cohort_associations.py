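"""Cohort analyses: intake gradients by quartile and adjusted associations.

On a calibrated synthetic cohort, computes (1) mean food-group and
nutrient intakes by score quartile with ANOVA and p-for-trend, (2) age-
and sex-adjusted linear associations between the score and
cardiometabolic outcomes, and (3) the sensitivity analysis that rebuilds
the score without the consumption-capping items.
"""

from med4child import (
    association_table,
    generate_cohort,
    preset_calibrated,
    quartile_summary,
    score_table,
    sensitivity_exclude,
)

cohort = generate_cohort(preset_calibrated(n=3000, seed=7))
scored = score_table(cohort.questionnaire)

gradient = quartile_summary(
    cohort.ffq, scored, ["vegetables", "fruits", "nuts", "fibre_g", "vitamin_c_mg"]
)
cols = ["variable", "Q1_mean", "Q4_mean", "anova_p", "trend_p"]
print(gradient[cols].round(4).to_string(index=False))
print()

assoc = association_table(
    scored, cohort.outcomes, ["wc", "hdl", "tg", "homa", "bmi"]
)
print(assoc.round(3).to_string(index=False))
print()

sens = sensitivity_exclude(
    (12, 13, 14, 15, 16, 17, 18),
    cohort.questionnaire,
    cohort.outcomes,
    ["wc", "hdl"],
)
print(sens[["outcome", "beta_full", "beta_reduced"]].round(3).to_string(index=False))
print()
print("Intakes of Mediterranean staples rise monotonically across the")
print("quartiles (tiny trend p-values); the fitted waist-circumference")
print("and HDL slopes recover the generator's effects (-0.15 and +0.30")
print("per score point).  Dropping the seven consumption-capping items")
print("keeps the signs and inference; the per-point slopes grow because")
print("an 11-item total spans a narrower range than the 18-item one.")
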
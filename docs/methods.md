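# Methods

This note records the scientific and numerical choices behind med4child:
what is modelled, which parameters matter, what the synthetic cohorts do
and do not emulate, and where the design was genuinely open.

## Scoring model

The screener awards one point per satisfied item; the total ranges 0–18.
Items are encoded as machine-readable criteria (direction, threshold,
unit, optional serving-gram range, optional sub-condition) in
`src/med4child/data/items.yaml`, so thresholds are applied by the engine
rather than baked into collection forms.  Conventions:

- **`at_least` vs `less_than`.** `at_least t` is satisfied at the
  boundary (answer ≥ t); `less_than t` is strict (answer < t), so zero
  consumption always satisfies a consumption cap.
- **Item 7 (legumes).** The instrument phrases the criterion as "2–3 or
  more servings a week"; the registry uses the lower bound (≥ 2),
  editable in the YAML.
- **Item 11 (sofrito).** No quantitative criterion is stated on the
  instrument; the default (≥ 2 servings/week) follows the adult
  14-item screener analogue and is editable.  The item is excluded from
  validation by default because the reference FFQ cannot estimate it.
- **Item 3 sub-condition.** The raw/salad requirement (≥ 1 serving/week)
  is checked only when a sub-answer (`q03_raw`) is supplied; otherwise
  the main threshold decides, matching the FFQ side where the
  sub-condition is not separable from group-level intakes.
- **Missing data.** The default `complete_case` policy signals exclusion
  (records are counted, never silently scored); `score_zero` is
  available for sensitivity work.
- **Quartiles and dichotomy.** Fixed cut points (8, 11, 13) give the
  bands 0–8 / 9–11 / 12–13 / 14–18; an empirical mode uses sample
  quartiles instead.  The low/high cutoff defaults to 10 and is a
  parameter.
- **Total-score comparison across instruments.** The administered total
  spans 18 items and the FFQ-derived total 17; the dichotomy cutoff (10)
  is applied to each instrument's own total.  A 17-item administered
  total can be requested via `items_used` if a like-for-like comparison
  is preferred; neither convention is asserted as canonical.

## FFQ mapping

FFQ intakes arrive as g/day per canonical food group with optional
`freq_<group>` occasions/week.  Gram intakes are converted to servings
(`servings = g/day ÷ g/serving`, ×7 for weekly criteria).  Serving sizes
live in `src/med4child/data/ffq_mapping.yaml`:

- stated ranges (vegetables 50–80 g, fish 40–70 g, nuts 15–20 g) default
  to midpoints;
- one tablespoon of olive oil is 10 mL × 0.92 g/mL = 9.2 g;
- one beverage glass is 200 mL ≡ 200 g;
- one fermented-dairy serving is 125 g (a commercial yogurt portion);
- groups the screener quantifies only as "times a week" (whole grains,
  red meat, sweets, dairy desserts, pastries, pre-cooked) carry package
  default serving sizes used only when the frequency columns are absent.

Frequency-phrased items prefer the FFQ frequency columns and fall back
to gram-based servings.  Two preference items have no stated crosswalk
(the published item-level mapping is in a non-public supplement) and are
reconstructed: olive oil as main culinary fat ⇔ olive-oil intake > 0 and
greater than butter+cream intake; white-over-red-meat preference ⇔
white-meat frequency strictly greater than red-meat frequency.

## Agreement statistics

Kappa is computed from the 2×2 cell proportions; its CI uses the
Fleiss–Cohen–Everitt large-sample variance (the source analysis does not
state its CI method).  A table where both methods are constant and equal
(Pₑ = 1) yields an *undefined-kappa* signal: validation rows are flagged
and retained rather than reported as 0.  Percent agreement is defined as
(a+d)/n; the corresponding column in the published item table contains
values (e.g. 2.42) that are not interpretable as proportions under any
reconstruction we attempted, so no attempt is made to reproduce that
column's scale.  Bland–Altman differences are fixed as administered −
FFQ-derived (the source text describes the direction inconsistently);
limits of agreement are mean ± 1.96 SD (SD with ddof = 1).

## Cohort analyses

- **HOMA-IR** = insulin (µU/mL) × glucose (mg/dL) / 405.
- **Quartile gradients**: group means with t-based 95% CIs, one-way
  ANOVA, and p-for-trend from a regression of the variable on the
  integer quartile rank 1–4 (the trend method is not stated in the
  source; OLS-on-rank is the common choice and is documented as ours).
- **Associations**: OLS of each outcome on the total score plus age and
  a single sex indicator (girl = 1).  Unstandardized betas (per score
  point) and standardized betas (SD per SD) are reported in separate,
  labelled columns because the published association table pairs betas
  and CIs on inconsistent scales; no attempt is made to reproduce that
  pairing.  No multiple-testing correction is applied, matching the
  single-model-per-outcome design.
- **Descriptives**: variables configured as skewed (serum lipids by
  default) are summarised as median (P25–P75) with Mann–Whitney;
  everything else as mean ± SD with Welch's t-test.  Skewness routing is
  by configuration, not auto-detection, to keep output deterministic.
- **Sensitivity analysis**: totals are rebuilt over the retained items
  and all associations re-fitted; both coefficient sets are reported
  side by side.  Per-point betas on a reduced item set are expected to
  grow in magnitude because the score range shrinks.

## Synthetic cohorts

The generator emulates the statistical structure a validation assumes,
not any real cohort's joint distribution:

- a one-dimensional Gaussian latent adherence trait (the construct a
  single adherence score presumes) drives all items through a logistic
  link; base logits are calibrated by Gauss–Hermite quadrature + Brent
  root-finding so simulated prevalences match target marginals (the
  published per-item percentages by default; sofrito, unpublished, is
  set to 0.5);
- reported quantities are drawn uniformly from the satisfying or
  violating region of each criterion (`at_least t`: U[t, 2t+1) vs
  U[0, t); `less_than t`: U[0, t) vs U[t, 2t)) — the bounded violating
  region keeps intakes in child-plausible ranges and keeps the fat
  intakes mutually coherent;
- misreporting is an independent flip per item and instrument with a
  desirability direction; the `biased` preset flips toward scoring the
  point, hardest for the consumption-capping items (0.30 questionnaire /
  0.05 FFQ, vs 0.10 / 0.05 for the staples), which reproduces the
  published qualitative pattern of markedly lower kappas on unhealthy
  items;
- logical coherence: ≥ 3 tbsp olive oil/day entails olive oil as
  culinary fat, so item 1 is the union with item 2 (its base rate is
  calibrated on the union so the marginal still hits the target);
- outcomes are linear in the true score with age/sex effects and
  Gaussian noise; default effect sizes are small, with the sign pattern
  negative for waist circumference, triglycerides and insulin and
  positive for HDL.  Magnitudes (e.g. −0.15 cm waist per point) are
  package defaults chosen to be realistic for preschool cohorts, not
  published estimates.  Intercepts and residual SDs approximate typical
  3–6-year-old distributions.
- ages are uniform on 3–6 years with a 50% girl fraction.

Not emulated: within-child correlation across food groups beyond the
shared trait (intakes are conditionally independent given the trait),
seasonal or day-to-day variance, energy coupling between groups, and any
real cohort's covariance of outcomes.  Passing tests therefore establish
correctness of the *methodology* under its own assumptions, not field
performance of the screener.

## Problem sizes and numerics

Simulation-based tests use cohorts of 400–10,000 children and the
parameter-recovery suite uses n = 5,000 across 5 seeds — large enough
that 3-standard-error recovery bounds are tight, small enough for an
ordinary laptop.  All randomness flows through `numpy.random.default_rng`
seeds carried in the configs; identical config ⇒ bit-identical tables,
and the pipeline stamps every report with a config hash and package
version.  Kappa's CI is truncated to [−1, 1]; its variance is floored at
0 against floating-point cancellation.  Degenerate inputs (empty tables,
zero-variance variables, collinear designs, all-items-dropped scores)
raise typed errors rather than returning numbers.

## Known limitations

- The FFQ crosswalk for the two preference items is a documented
  reconstruction, not the instrument's own (non-public) mapping.
- The item-3 raw/salad sub-condition cannot be derived from group-level
  FFQ data; FFQ-side points for item 3 use the main threshold only.
- The sofrito criterion is an editable default, not a published rule.
- Published numeric results from the restricted cohort (quartile means,
  item kappas, association betas, the 5-point Bland–Altman offset) are
  not reproducible from public data and are not targets of this package;
  the in-paper arithmetic identities that are checkable (flow counts,
  kappa–marginal consistency) are covered by the test suite.
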
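# Mapping from FFQ food-group intakes to MED4CHILD items (version 1).
#
# `servings` defines grams per serving for each canonical food group.
# Where the screener states a gram range (vegetables 50-80 g, fish 40-70 g,
# nuts 15-20 g), the default is the midpoint and `source_interval` records
# the range.  One tablespoon of olive oil is 10 mL, converted to grams with
# density 0.92 g/mL.  One beverage glass is taken as 200 mL (200 g).
# Serving sizes for groups the screener quantifies only as "times per week"
# (whole grains, red meat, sweets, dairy desserts, pastries, pre-cooked)
# are package defaults used only for the gram-based fallback when the FFQ
# frequency columns are absent.
#
# `items` maps each item to its food group(s) and derivation rule:
#   servings      - convert g/day to servings and compare with the criterion
#   frequency     - use freq_<group> (occasions/week) when present, else
#                   fall back to gram-based servings per week
#   main_fat      - olive oil used as main culinary fat: intake > 0 and
#                   greater than butter+cream intake (reconstruction; the
#                   published item-level crosswalk is not public)
#   white_vs_red  - white-meat frequency strictly greater than red-meat
#                   frequency scores the point
#   not_derivable - item cannot be estimated from the FFQ (item 11, sofrito)
version: 1
servings:
  vegetables: {grams: 65.0, source_interval: [50, 80]}
  fruits: {grams: 100.0}
  olive_oil: {grams: 9.2}
  butter_cream: {grams: 12.0}
  refined_cereals: {grams: 60.0}
  whole_grains: {grams: 60.0}
  fish_seafood: {grams: 55.0, source_interval: [40, 70]}
  red_processed_meat: {grams: 50.0}
  white_meat: {grams: 50.0}
  nuts: {grams: 17.5, source_interval: [15, 20]}
  legumes: {grams: 40.0}
  fermented_dairy: {grams: 125.0}
  dairy_desserts: {grams: 100.0}
  sugared_beverages: {grams: 200.0}
  sweets_snacks: {grams: 30.0}
  pastries: {grams: 50.0}
  precooked: {grams: 100.0}
items:
  1: {rule: main_fat, groups: [olive_oil, butter_cream]}
  2: {rule: servings, groups: [olive_oil]}
  3: {rule: servings, groups: [vegetables]}
  4: {rule: servings, groups: [fruits]}
  5: {rule: frequency, groups: [whole_grains]}
  6: {rule: servings, groups: [fermented_dairy]}
  7: {rule: servings, groups: [legumes]}
  8: {rule: servings, groups: [fish_seafood]}
  9: {rule: servings, groups: [nuts]}
  10: {rule: white_vs_red, groups: [white_meat, red_processed_meat]}
  11: {rule: not_derivable, groups: []}
  12: {rule: frequency, groups: [red_processed_meat]}
  13: {rule: servings, groups: [butter_cream]}
  14: {rule: frequency, groups: [sugared_beverages]}
  15: {rule: frequency, groups: [sweets_snacks]}
  16: {rule: frequency, groups: [dairy_desserts]}
  17: {rule: frequency, groups: [pastries]}
  18: {rule: frequency, groups: [precooked]}
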
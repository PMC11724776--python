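"""Derive the reference score from FFQ food-group intakes.

An FFQ reports grams per day per food group (plus optional weekly eating
occasions).  Serving sizes convert grams to servings so the screener
criteria can be applied; the sofrito item has no FFQ counterpart, so the
reference score spans 17 of the 18 items.
"""

from med4child import FFQRecord, derive_score_from_ffq, load_mapping
from med4child.ffq import CANONICAL_GROUPS

mapping = load_mapping()

record = FFQRecord(
    child_id="example",
    group_intakes={g: 0.0 for g in CANONICAL_GROUPS}
    | {
        "olive_oil": 30.0,        # ~3.3 tablespoons/day at 9.2 g each
        "vegetables": 150.0,      # ~2.3 servings/day at 65 g
        "fruits": 180.0,          # 1.8 small fruits/day
        "fermented_dairy": 250.0, # 2 yogurt portions/day
        "legumes": 12.0,          # 2.1 servings/week at 40 g
        "fish_seafood": 25.0,     # 3.2 servings/week at 55 g
        "nuts": 5.0,              # 2 servings/week at 17.5 g
        "butter_cream": 4.0,      # a third of a 12 g serving/day
    },
    frequencies={
        "whole_grains": 4.0,
        "red_processed_meat": 1.5,
        "white_meat": 3.0,
        "sugared_beverages": 1.0,
        "sweets_snacks": 2.0,
        "dairy_desserts": 0.5,
        "pastries": 1.0,
        "precooked": 0.5,
    },
)

result = derive_score_from_ffq(record)
print("per-item points:", dict(sorted(result.item_points.items())))
print(f"reference total: {result.total} / {len(result.items_used)} items")
print()
print("Nuts miss the point (2 < 3 servings/week) and so do fruits")
print("(1.8 < 3/day) and sweets (2 >= 1 time/week caps the point); the")
print("other Mediterranean staples and the consumption caps all score.")
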
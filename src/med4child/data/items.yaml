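# Default MED4CHILD item registry (version 1).
#
# One entry per item of the 18-item Mediterranean-diet adherence screener
# for children aged 3-6 years.  Each satisfied criterion contributes one
# point to a 0-18 total.  `direction` is how the reported quantity is
# compared with `threshold` in the item's `unit`; `serving_grams` is the
# gram range defining one serving where the instrument states one
# (midpoints are used for FFQ conversion, see ffq_mapping.yaml).
#
# Item 7 is printed as "2-3 or more servings a week"; the registry uses the
# lower bound (>= 2) and the threshold is editable.  Item 11 (sofrito) has
# no explicitly stated quantitative criterion; the default of >= 2 servings
# per week follows the adult MEDAS analogue and is likewise editable.
version: 1
items:
  - item_id: 1
    label: "Extra-virgin olive oil as the main culinary fat"
    unit: binary_preference
    direction: "yes"
    threshold: 1
  - item_id: 2
    label: "Olive oil, 3 or more tablespoons per day"
    unit: tablespoons_per_day
    direction: at_least
    threshold: 3
  - item_id: 3
    label: "Vegetables, 2 or more servings per day"
    unit: servings_per_day
    direction: at_least
    threshold: 2
    serving_grams: [50, 80]
    extra_condition:
      label: "At least one serving as raw vegetables or salad per week"
      unit: servings_per_week
      direction: at_least
      threshold: 1
  - item_id: 4
    label: "Fruit, 3 or more small fruits per day"
    unit: servings_per_day
    direction: at_least
    threshold: 3
    serving_grams: [100, 100]
  - item_id: 5
    label: "Whole grains instead of refined, 3 or more times per week"
    unit: times_per_week
    direction: at_least
    threshold: 3
  - item_id: 6
    label: "Fermented milk, plain yogurt or goat's/sheep's cheese, at least 1 serving per day"
    unit: servings_per_day
    direction: at_least
    threshold: 1
    serving_grams: [25, 125]
  - item_id: 7
    label: "Legumes, 2 or more servings per week"
    unit: servings_per_week
    direction: at_least
    threshold: 2
    serving_grams: [40, 40]
  - item_id: 8
    label: "Fish or seafood, 3 or more servings per week"
    unit: servings_per_week
    direction: at_least
    threshold: 3
    serving_grams: [40, 70]
  - item_id: 9
    label: "Nuts, at least 3 servings per week"
    unit: servings_per_week
    direction: at_least
    threshold: 3
    serving_grams: [15, 20]
  - item_id: 10
    label: "Preferably chicken, turkey or rabbit instead of red meat"
    unit: binary_preference
    direction: "yes"
    threshold: 1
  - item_id: 11
    label: "Sofrito, 2 or more servings per week"
    unit: servings_per_week
    direction: at_least
    threshold: 2
  - item_id: 12
    label: "Red meat, hamburgers, sausages or processed meat, less than 2 times per week"
    unit: times_per_week
    direction: less_than
    threshold: 2
  - item_id: 13
    label: "Butter or cream, less than 1 serving per day"
    unit: servings_per_day
    direction: less_than
    threshold: 1
    serving_grams: [12, 12]
  - item_id: 14
    label: "Carbonated and/or sugary beverages, less than 2 glasses per week"
    unit: times_per_week
    direction: less_than
    threshold: 2
  - item_id: 15
    label: "Chips, gummy worms or sweets, less than 1 time per week"
    unit: times_per_week
    direction: less_than
    threshold: 1
  - item_id: 16
    label: "Dairy desserts and vegetable drinks, less than 1 time per week"
    unit: times_per_week
    direction: less_than
    threshold: 1
  - item_id: 17
    label: "Pastries, stuffed cookies, sweets or cakes, less than 2 times per week"
    unit: times_per_week
    direction: less_than
    threshold: 2
  - item_id: 18
    label: "Pre-cooked or ready-to-eat food, less than 1 time per week"
    unit: times_per_week
    direction: less_than
    threshold: 1
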
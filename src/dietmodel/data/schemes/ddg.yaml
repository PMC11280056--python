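# Dutch Dietary Guidelines ("Wheel of Five"), daily amounts harmonized to
# grams per day (servings converted via standard Dutch portion sizes).
# Cheese sits in its own group in the guidelines; load_ddg() merges it into
# the dairy group so that both schemes expose one comparable dairy group
# (630 + 25 = 655 g/day).  Up to 15% of daily energy may come from foods
# outside the advised groups.
scheme_id: DDG
outside_energy_pct: 15
groups:
  - id: bread
    name: Bread (brown bread)
    amount_g: 205
  - id: cereal_potatoes
    name: Cereal products and potatoes
    amount_g: 105
  - id: vegetables
    name: Vegetables
    amount_g: 250
  - id: fruits
    name: Fruits
    servings: 2
    serving_g: 100
  - id: milk_dairy
    name: Milk and dairy products
    amount_g: 630
  - id: cheese
    name: Cheese
    amount_g: 25
  - id: meat
    name: Meat
    amount_g: 23.8
  - id: poultry
    name: Chicken, poultry
    amount_g: 23.8
  - id: eggs
    name: Eggs
    amount_g: 23.8
  - id: fish
    name: Fish
    amount_g: 14.3
  - id: legumes
    name: Legumes
    amount_g: 17.1
  - id: nuts
    name: Nuts (without salt)
    amount_g: 15
  - id: fats
    name: Fats and oils (spreadable and cooking fats)
    range: [40, 65]
  - id: drinks
    name: "Drinks: water, coffee, or tea"
    amount_g: 1500
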
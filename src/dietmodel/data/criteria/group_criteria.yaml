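# Ordered food-group assignment criteria (first satisfied criterion wins).
# This is a reconstruction: one criterion per food group combining descriptor
# flags, a maximum NOVA processing level, and coarse nutrient thresholds per
# 100 g.  Foods satisfying no criterion are EXCLUDED from both modelled diets
# (in practice this removes ultra-processed foods, which exceed every
# criterion's nova_max).
criteria:
  - group: whole_grains
    nova_max: 3
    require_flags: [whole_grain]
    nutrient_rules:
      - {nutrient: fiber, op: ">=", value: 3}
  - group: tubers
    nova_max: 3
    require_flags: [tuber]
  - group: vegetables
    nova_max: 3
    require_flags: [vegetable]
  - group: fruits
    nova_max: 3
    require_flags: [fruit]
  - group: dairy
    nova_max: 3
    require_flags: [dairy]
  - group: red_meat
    nova_max: 3
    require_flags: [red_meat]
  - group: poultry
    nova_max: 3
    require_flags: [poultry]
  - group: eggs
    nova_max: 3
    require_flags: [egg]
  - group: fish
    nova_max: 3
    require_flags: [fish]
  - group: legumes
    nova_max: 3
    require_flags: [legume]
  - group: nuts
    nova_max: 3
    require_flags: [nut]
  - group: added_fats
    nova_max: 3
    require_flags: [added_fat]
    nutrient_rules:
      - {nutrient: total_fat, op: ">=", value: 40}
  - group: added_sugars
    nova_max: 3
    require_flags: [added_sugar]
    forbid_flags: [soft_drink]
    nutrient_rules:
      - {nutrient: mono_di_saccharides, op: ">=", value: 50}
  - group: drinks
    nova_max: 3
    require_flags: [beverage]
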
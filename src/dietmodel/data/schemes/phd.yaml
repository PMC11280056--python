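# Planetary Health Diet (EAT-Lancet reference diet), adult intake targets in
# grams per day.  Red meat is stored as its published subgroups (beef/lamb and
# pork, equal caloric density); load_phd() merges them into a single red-meat
# group for comparison and diet building.  The two added-fat subgroups
# (saturated/palm + unsaturated oils) are carried as one merged group because
# composite foods cannot be attributed to a single fat subgroup.
scheme_id: PHD
outside_energy_pct: 0
groups:
  - id: whole_grains
    name: Rice, wheat, corn, and other
    amount_g: 232
  - id: tubers
    name: Potatoes and cassava
    amount_g: 50
  - id: vegetables
    name: All vegetables
    amount_g: 300
  - id: fruits
    name: All fruits
    amount_g: 200
  - id: dairy
    name: Dairy
    amount_g: 250
  - id: beef_lamb
    name: Beef and lamb
    amount_g: 7
  - id: pork
    name: Pork
    amount_g: 7
  - id: poultry
    name: Chicken and other poultry
    amount_g: 29
  - id: eggs
    name: Eggs
    amount_g: 13
  - id: fish
    name: Fish
    amount_g: 28
  - id: legumes
    name: Legumes
    amount_g: 75
  - id: nuts
    name: Nuts
    amount_g: 50
  - id: added_fats
    name: Added fats (saturated + unsaturated oils)
    amount_g: 51.8
  - id: added_sugars
    name: Added sugars
    amount_g: 31
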
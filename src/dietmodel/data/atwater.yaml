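# Atwater energy-conversion factors, kcal per gram.  Sub-fractions of a
# macronutrient (e.g. saturated fat, polysaccharides) use the parent factor
# when expressed as percent of energy.
factors:
  carbohydrate: 4
  protein: 4
  total_fat: 9
  fiber: 2
  alcohol: 7
fat_fractions:
  - saturated_fat
  - monounsaturated_fat
  - polyunsaturated_fat
  - cis_unsaturated_fat
  - trans_fat
  - linoleic_acid
  - alpha_linolenic_acid
carbohydrate_fractions:
  - mono_di_saccharides
  - sugars
  - polysaccharides
protein_fractions:
  - vegetable_protein
  - animal_protein
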
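{
  "scheme_id": "DDG-NL",
  "sex": "both",
  "description": "Published whole-diet nutrient content of the healthy diet based on the Dutch Dietary Guidelines (daily totals).",
  "totals": {
    "energy_kcal": 1968,
    "carbohydrate": 215,
    "mono_di_saccharides": 100,
    "sugars": 33,
    "polysaccharides": 115,
    "fiber": 30,
    "protein": 91,
    "vegetable_protein": 32,
    "animal_protein": 59,
    "total_fat": 74,
    "saturated_fat": 19,
    "polyunsaturated_fat": 24,
    "linoleic_acid": 18,
    "alpha_linolenic_acid": 5.1,
    "epa": 67,
    "dha": 79,
    "monounsaturated_fat": 24,
    "cis_unsaturated_fat": 49,
    "trans_fat": 0.5,
    "cholesterol": 134,
    "vitamin_a": 2374,
    "vitamin_b1": 1.5,
    "vitamin_b2": 2.4,
    "vitamin_b3": 20,
    "vitamin_b6": 2.7,
    "vitamin_b9": 411,
    "vitamin_b12": 7.9,
    "vitamin_c": 165,
    "vitamin_d": 3.2,
    "vitamin_e": 16,
    "vitamin_k": 281,
    "calcium": 1652,
    "copper": 1.4,
    "iron": 12,
    "iodine": 175,
    "potassium": 4104,
    "magnesium": 423,
    "sodium": 1739,
    "phosphorus": 1735,
    "selenium": 55,
    "zinc": 12,
    "water": 2999
  }
}
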
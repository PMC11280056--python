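{
  "scheme_id": "PHD-NL",
  "sex": "both",
  "description": "Published whole-diet nutrient content of the Planetary Health Diet operationalized with Dutch foods (daily totals).",
  "totals": {
    "energy_kcal": 1952,
    "carbohydrate": 179,
    "mono_di_saccharides": 53,
    "sugars": 2.87,
    "polysaccharides": 126,
    "fiber": 39,
    "protein": 82,
    "vegetable_protein": 51,
    "animal_protein": 31,
    "total_fat": 92,
    "saturated_fat": 21,
    "polyunsaturated_fat": 29,
    "linoleic_acid": 23,
    "alpha_linolenic_acid": 4.6,
    "epa": 120,
    "dha": 160,
    "monounsaturated_fat": 35,
    "cis_unsaturated_fat": 63,
    "trans_fat": 0.6,
    "cholesterol": 149,
    "vitamin_a": 1740,
    "vitamin_b1": 1.6,
    "vitamin_b2": 1.7,
    "vitamin_b3": 22,
    "vitamin_b6": 2.1,
    "vitamin_b9": 455,
    "vitamin_b12": 6.0,
    "vitamin_c": 130,
    "vitamin_d": 4.2,
    "vitamin_e": 19,
    "vitamin_k": 303,
    "calcium": 794,
    "copper": 1.7,
    "iron": 14,
    "iodine": 209,
    "potassium": 3517,
    "magnesium": 463,
    "sodium": 1765,
    "phosphorus": 1524,
    "selenium": 93,
    "zinc": 11,
    "water": 1077
  }
}
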
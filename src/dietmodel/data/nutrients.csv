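nutrient,display_name,unit,role
energy_kcal,Energy,kcal,energy
carbohydrate,Carbohydrates,g,macro
mono_di_saccharides,Mono- and disaccharides,g,macro
sugars,Sugars,g,macro
polysaccharides,Polysaccharides,g,macro
fiber,Fiber,g,macro
protein,Protein,g,macro
vegetable_protein,Vegetable protein,g,macro
animal_protein,Animal protein,g,macro
total_fat,Total fat,g,macro
saturated_fat,Saturated fat,g,fatty_acid
monounsaturated_fat,Monounsaturated fat,g,fatty_acid
polyunsaturated_fat,Polyunsaturated fat,g,fatty_acid
cis_unsaturated_fat,"Unsaturated fat, cis",g,fatty_acid
trans_fat,Trans fat,g,fatty_acid
linoleic_acid,Linoleic acid,g,fatty_acid
alpha_linolenic_acid,Alpha-linolenic acid,g,fatty_acid
epa,Eicosapentaenoic acid,mg,fatty_acid
dha,Docosahexaenoic acid,mg,fatty_acid
cholesterol,Cholesterol,mg,fatty_acid
alcohol,Alcohol,g,macro
vitamin_a,Vitamin A (RAE),ug,vitamin
vitamin_b1,Vitamin B1 (thiamin),mg,vitamin
vitamin_b2,Vitamin B2 (riboflavin),mg,vitamin
vitamin_b3,Vitamin B3 (niacin),mg,vitamin
vitamin_b6,Vitamin B6,mg,vitamin
vitamin_b9,Vitamin B9 (folate),ug,vitamin
vitamin_b12,Vitamin B12,ug,vitamin
vitamin_c,Vitamin C,mg,vitamin
vitamin_d,Vitamin D,ug,vitamin
vitamin_e,Vitamin E,mg,vitamin
vitamin_k,Vitamin K,ug,vitamin
calcium,Calcium,mg,mineral
copper,Copper,mg,mineral
iron,Iron,mg,mineral
iodine,Iodine,ug,mineral
potassium,Potassium,mg,mineral
magnesium,Magnesium,mg,mineral
sodium,Sodium,mg,mineral
phosphorus,Phosphorus,mg,mineral
selenium,Selenium,ug,mineral
zinc,Zinc,mg,mineral
water,Water,g,water
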
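nutrient,sex,age_low,age_high,kind,value,unit,energy_ref_kcal,band,note
fiber,male,19,50,AI,40,g,,,
fiber,male,51,70,AI,35,g,,,
fiber,female,19,50,AI,30,g,,,
fiber,female,51,70,AI,25,g,,,
carbohydrate,both,19,70,EN_PCT,40,%En,,,
protein,male,19,50,EN_PCT,8,%En,,,back-derived from published %DRV ranges
protein,male,51,70,EN_PCT,9,%En,,,back-derived from published %DRV ranges
protein,female,19,50,EN_PCT,9,%En,,,back-derived from published %DRV ranges
protein,female,51,70,EN_PCT,10,%En,,,back-derived from published %DRV ranges
total_fat,both,19,70,EN_PCT,20,%En,,low,
total_fat,both,19,70,EN_PCT,40,%En,,high,
saturated_fat,both,19,70,EN_PCT_UL,10,%En,,,
polyunsaturated_fat,both,19,70,EN_PCT_UL,12,%En,,,
trans_fat,both,19,70,EN_PCT_UL,1,%En,,,
alpha_linolenic_acid,both,19,70,EN_PCT,1,%En,,,
marine_fatty_acids,both,19,70,AI,200,mg,,,EPA + DHA
vitamin_a,male,19,50,EAR,615,ug,,,
vitamin_a,female,19,50,EAR,525,ug,,,
vitamin_b1,male,19,50,EAR,0.83,mg,2700,,reference scaled to a 2700 kcal/day diet
vitamin_b1,female,19,50,EAR,0.61,mg,2000,,reference scaled to a 2000 kcal/day diet
vitamin_b2,both,19,50,EAR,1.3,mg,,,
vitamin_b3,male,19,50,EAR,15,mg,2700,,reference scaled to a 2700 kcal/day diet
vitamin_b3,female,19,50,EAR,11,mg,2000,,reference scaled to a 2000 kcal/day diet
vitamin_b6,both,19,50,EAR,1.1,mg,,,
vitamin_b9,both,19,50,EAR,200,ug,,,
vitamin_b12,both,19,50,EAR,2,ug,,,
vitamin_c,male,19,50,EAR,60,mg,,,
vitamin_c,female,19,50,EAR,50,mg,,,
vitamin_d,both,19,50,EAR,10,ug,,,
vitamin_e,male,19,50,AI,13,mg,,,
vitamin_e,female,19,50,AI,11,mg,,,
vitamin_k,both,19,50,AI,70,ug,,,
calcium,both,19,50,EAR,860,mg,,,working value; see calcium_alt
calcium,both,19,50,EAR,750,mg,,,calcium_alt
copper,both,19,50,EAR,0.7,mg,,,
iron,male,19,50,EAR,6,mg,,,
iron,female,19,50,EAR,7,mg,,,
iodine,both,19,50,EAR,150,ug,,,
potassium,both,19,50,AI,3500,mg,,,
magnesium,male,19,50,AI,350,mg,,,
magnesium,female,19,50,AI,300,mg,,,
sodium,both,19,50,UL,2400,mg,,,maximum recommended intake
phosphorus,both,19,50,AI,550,mg,,,
selenium,both,19,50,AI,70,ug,,,
zinc,male,19,50,EAR,12.1,mg,,,decimal-corrected
zinc,female,19,50,EAR,15.5,mg,,,decimal-corrected
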
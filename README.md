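# dietmodel

Theoretical diet modelling for nutritional epidemiology: build whole-diet
nutrient profiles for food-based dietary recommendations and score their
nutritional adequacy against Dietary Reference Values (DRVs).

Dietary recommendations are phrased in food groups ("250 g dairy per
day"), but adequacy questions — does following the advice deliver enough
vitamin D, calcium, fiber? — live at the nutrient level. `dietmodel`
bridges the two: it takes a food-composition table (nutrient densities
per 100 g, NEVO-style), a consumption survey (who ate how many grams of
what), and one or more diet schemes, and computes what eating exactly the
recommended amounts of each group would supply, given the foods the
population actually eats. Two schemes are packaged: the EAT-Lancet
**Planetary Health Diet (PHD)** and the Dutch Dietary Guidelines
(**DDG**, "Wheel of Five"), with the explicit food-group correspondence
needed to compare them.

## The model

For each food group *g* of a scheme, the group's mean density per 100 g
is the consumption-weighted mean over survey records:

    D_g = Σ_r (grams_r × density_food(r)) / Σ_r grams_r

restricted to foods assigned to *g* by NOVA processing level (1–4,
ordered first-match rules) plus nutrient criteria; foods meeting no
criterion are excluded. The whole-diet daily total is then a linear
scaling to the scheme's recommended grams A_g (per sex):

    T = Σ_g D_g × A_g / 100

Derived accounting: %En of a macronutrient = grams × Atwater factor /
total kcal × 100 (factors 4/4/9/2/7 kcal/g for carbohydrate, protein,
fat, fiber, alcohol); marine fatty acids = EPA + DHA; protein is
partitioned into animal and vegetable sources by group label. Adequacy:
%DRV = intake / reference × 100, with the EAR preferred and the AI as
fallback, upper limits for sodium and the fat fractions, energy-percent
references converted to grams at the diet's own energy, and age-band
pairs yielding %DRV ranges. See `docs/methods.md` for conventions and
limitations.

Because the real survey and composition data are not redistributable, a
synthetic-data module generates both with known ground truth (planted
group labels, NOVA levels, target densities, and an excluded-food
fraction), so the whole pipeline is testable end to end.

## Worked example

Score the packaged published diet profiles (daily nutrient totals of the
PHD and DDG operationalized with Dutch foods):

```python
from dietmodel import run_pipeline

bundle = run_pipeline({"profiles": ["phd_nl", "ddg_nl"]})
print(bundle.energy_shares.query("nutrient in ('carbohydrate','total_fat')").to_string(index=False))
print(bundle.protein.round(1).to_string(index=False))
phd = bundle.adequacy["PHD-NL"].set_index("nutrient")
print(phd.loc[["fiber", "vitamin_d", "calcium", "sodium"]].round(1).to_string())
```

prints

```
  diet     nutrient  grams  percent_energy  percent_energy_rounded
PHD-NL carbohydrate  179.0       36.680328                    37.0
PHD-NL    total_fat   92.0       42.418033                    42.0
DDG-NL carbohydrate  215.0       43.699187                    44.0
DDG-NL    total_fat   74.0       33.841463                    34.0

  diet  total_protein_g  animal_protein_g  vegetable_protein_g  animal_pct  vegetable_pct
PHD-NL             82.0              31.0                 51.0        37.8           62.2
DDG-NL             91.0              59.0                 32.0        64.8           35.2

              sex  intake reference_kind  reference_value  pct_drv_low  pct_drv_high status
fiber      female    39.0             AI             30.0        130.0         156.0  meets
vitamin_d  female     4.2            EAR             10.0         42.0          42.0  below
calcium    female   794.0            EAR            860.0         92.3          92.3  below
sodium     female  1765.0             UL           2400.0         73.5          73.5  meets
```

Reading the output: the PHD draws most energy from fat (42 %En) and the
DDG from carbohydrates (44 %En); protein sources are roughly mirrored
(62% vegetable in the PHD vs 65% animal in the DDG); the PHD meets the
fiber reference with room to spare (130–156 %DRV across the two adult
age bands) but falls short on vitamin D and calcium, while sodium stays
under its 2400 mg maximum.

The full survey-mode pipeline runs from the shell:

```bash
dietmodel synth --n-foods 120 --n-participants 500 --seed 1 --out data/
dietmodel compare-schemes            # PHD vs DDG grams/day differences
dietmodel adequacy --profile phd_nl  # score a packaged profile
```

or from a config file (`dietmodel run --config config.yaml`) referencing
a composition CSV, a consumption CSV, schemes, criteria and the DRV
registry; it emits comparison, content, adequacy and protein-partition
tables (TSV), diet profiles (JSON), water totals and an exclusion log.

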
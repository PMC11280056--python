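# Methods

## The modelling problem

`dietmodel` builds *theoretical diets*: given a food-based dietary
recommendation (food groups with grams/day) and data on what a population
actually eats, it computes the whole-diet nutrient supply that following
the recommendation would deliver, and scores that supply against Dietary
Reference Values (DRVs). Two schemes are packaged — the EAT-Lancet
Planetary Health Diet (PHD) and the Dutch Dietary Guidelines (DDG, "Wheel
of Five") — together with the explicit group correspondence needed to
compare them.

The pipeline has five stages:

1. **Scheme harmonization.** Food groups of the two schemes are paired by
   food nature through an explicit mapping (never name matching — the
   judgment call is configuration, not code). Servings are converted to
   grams (`servings × serving size`); range recommendations (DDG fats,
   40–65 g/day) collapse to their midpoint (52.5 g/day) for diet building
   while retaining the endpoints for reporting. Groups present in only one
   scheme (added sugars in the PHD, drinks in the DDG) are reported as
   unmatched with their difference taken against zero.
2. **Food grouping.** Each survey food gets a NOVA processing level
   (1–4) from an ordered first-match rule table over descriptor flags, and
   is then assigned to a food group by an ordered list of criteria (flags +
   maximum NOVA level + nutrient thresholds per 100 g). Foods satisfying no
   criterion are excluded from both modelled diets; exclusions are counted
   and logged. The packaged criteria are a *reconstruction* — one coarse
   criterion per group — because no authoritative machine-readable criteria
   set exists; they are plain YAML and fully replaceable.
3. **Group composition.** Each group's mean nutrient density per 100 g is
   the consumption-weighted mean over survey records,
   Σ(grams × density)/Σ(grams). Weighting by observed intake is the
   default because it best represents the foods a population actually
   eats; an unweighted mean over distinct foods is available
   (`weighted=False` / `group_mean: unweighted`) since the averaging
   convention is a genuinely open choice. A scheme group with no
   supporting consumption fails loudly rather than silently contributing
   zeros.
4. **Diet building.** Per-group contribution = group density ×
   recommended grams(sex) / 100; the diet total is the sum over groups.
   Totals are linear in both amounts and densities, and contributions sum
   exactly to the total (accumulation runs in stable sorted order so runs
   are bit-reproducible). Sex enters only through the scheme amounts;
   group densities are sex-pooled.
5. **Accounting and adequacy.** Derived quantities (energy shares,
   protein partition, marine fatty acids) and %DRV scoring, described
   below.

## Nutrient panel and units

A packaged dictionary (`data/nutrients.csv`) fixes the identifier, unit
and aggregation role of every nutrient carried through the pipeline:
energy kcal; macronutrients and fat fractions g; EPA/DHA mg; vitamins µg
or mg; minerals mg or µg; water g. Unknown identifiers are rejected at
load time; missing cells in a composition table are imputed as 0 with a
logged count (composition databases are sparse, and whole-diet sums treat
absent as zero). Vegetable and animal protein appear as dictionary
entries so that published daily totals carrying that split can be loaded
as profiles; in survey mode the same split is computed from group labels
and the two routes are cross-checked in tests.

## Energy accounting

Percent of energy uses Atwater factors — carbohydrate 4, protein 4, fat
9, fiber 2, alcohol 7 kcal/g; fat/carbohydrate/protein sub-fractions use
their parent factor. Total energy is taken from the composition table's
energy field, **not** re-derived from macronutrients, so the
carbohydrate+protein+fat energy shares close only approximately (a 90–110%
sanity band is property-tested). Printed-style rounding is
round-half-away-from-zero at the conventional precision (integer for
macros, one decimal for saturated/trans fat and alpha-linolenic acid);
unrounded values are always reported alongside, because published tables
are internally rounded and exact agreement of re-derived percentages with
printed ones cannot be forced in general.

## Adequacy scoring

The DRV registry (`data/drv_registry.csv`) stores one row per nutrient,
sex and age band with a reference kind:

* `EAR` (estimated average requirement) preferred; `AI` (adequate intake)
  used where no EAR exists (vitamins E and K, potassium, magnesium,
  phosphorus, selenium, fiber, marine fatty acids);
* `UL` — maximum recommended intake (sodium, 2400 mg);
* `EN_PCT` / `EN_PCT_UL` — references expressed as percent of energy
  (carbohydrate 40 %En; total fat band 20–40 %En; upper limits for
  saturated fat 10, polyunsaturated fat 12 and trans fat 1 %En;
  alpha-linolenic acid 1 %En). These convert to gram equivalents at the
  diet's own energy before %DRV is computed.

%DRV = intake / reference × 100 per age band; references with two adult
bands (fiber: 30/25 g for women 19–50/51–70, 40/35 g for men) yield a
low–high range, e.g. 39 g of fiber → 130–156 %DRV for women. The status
call uses the 19–50 band: strictly below → `below`; at or above →
`meets`; above a band's high endpoint or a maximum → `above-upper-limit`;
intake exactly at the reference counts as `meets` (only strict shortfalls
are flagged). A nutrient absent from the registry is returned as
`not-assessed`, never dropped.

Two documented registry irregularities: calcium stores both 750 and
860 mg — the working value 860 is the default and the 805 average is
available behind `calcium_policy="average"` (status calls agree under
both); zinc references are stored decimal-corrected at 12.1/15.5 mg, as
the uncorrected printed values would exceed any plausible zinc reference
tenfold. Protein %En references (8–9 %En men, 9–10 %En women by age band)
are back-derived for documentation and range reporting, not authoritative
values.

## Synthetic data

Real inputs (a national food-composition database and consumption survey)
are not redistributable, so the generator produces structurally equivalent
stand-ins with known ground truth:

* **Densities**: per group, each *component* nutrient is log-normal around
  the group's target density with unit mean and CV 0.2 (default).
  Aggregates are derived, not drawn — carbohydrate = mono/di- +
  polysaccharides, total fat = the sum of its fractions, energy = Atwater
  from the sampled macros — so every generated food is internally
  consistent and at CV = 0 equals its group target exactly.
* **Intakes**: every participant consumes every food, gamma-distributed
  grams (CV 0.6 default) around the group's population intake divided
  equally over the group's foods; deterministic at CV 0.
* **Flags**: descriptor flags are emitted consistently with the packaged
  NOVA rules and criteria, so the classifier recovers the planted labels;
  a planted 10% of foods are ultra-processed snacks that satisfy no
  criterion and must be excluded.
* One shared seed drives both generators through independent substreams,
  so catalog and survey are separately reproducible.

Default group targets are realistic per-100 g densities for Dutch-style
food groups (wholemeal bread, boiled potatoes, mixed vegetables, …,
margarine-like added fats, water/tea/coffee drinks); under them the PHD
scheme lands near 1950 kcal/day with ~63% vegetable protein, i.e. in the
plausible range for this kind of modelling. What the generator does *not*
emulate: real marginal distributions and between-nutrient correlations of
a composition database, 2-day-recall measurement error, survey weights,
or participant-level food selection. Passing tests therefore demonstrate
correctness of the pipeline's arithmetic and classification logic under a
controlled generative model, not fidelity to any real survey.

Problem sizes in the test suite and acceptance script (catalogs of 30–560
foods, 5–300 participants) are chosen so each check isolates one property
at adequate precision; group-mean recovery error is property-tested to
shrink like CV/√(foods per group).

## Numerical choices

* Accumulation in stable sorted order everywhere totals are formed →
  bit-reproducible results across runs.
* Round-half-away-from-zero, never banker's rounding, for printed-style
  values.
* Noise-free parameter recovery is asserted at 1e-9 relative tolerance;
  conservation identities at 1e-12.
* First-match-wins ordering makes NOVA classification and group
  assignment deterministic and independent of catalog order (permutation
  is tested); unmatched foods default to NOVA 4 — conservative, since
  ultra-processed foods fall outside every advised group.

## Known limitations

* The packaged grouping criteria are a coarse reconstruction; real
  applications should supply their own criteria YAML.
* No nutrient retention/cooking-loss factors, survey weighting,
  within-person variance modelling, bioavailability adjustment (e.g.
  heme vs non-heme iron), or energy standardization of diets.
* Published diet totals are carried as fixture profiles with totals only
  (no per-group contributions), so group-resolved accounting is available
  only in survey mode.
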
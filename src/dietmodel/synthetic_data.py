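"""Synthetic NEVO-like food catalog and FCS-like consumption survey with ground truth.

The real inputs of the pipeline — a national food-composition database and
individual-level consumption survey — are not redistributable, so this
module generates structurally equivalent stand-ins with *known* ground
truth: every food carries a true group label and NOVA level, every group a
true mean density vector, and a planted fraction of foods satisfies no
grouping criterion (emulating ultra-processed products excluded from both
modelled diets).

Generative model
----------------
* Densities: per group, each nutrient is drawn log-normally around the
  group's target density with a stated coefficient of variation (default
  0.2) and unit mean, so the group target *is* the expected density.
  Aggregate fields are derived, not drawn: carbohydrate = mono/di- +
  polysaccharides, total fat = saturated + mono- + poly- + trans, cis
  unsaturated = mono- + poly-, energy = Atwater (4/4/9/2 kcal per g of
  carbohydrate/protein/fat/fiber), and the animal/vegetable protein split
  follows the group label.  At CV = 0 every food equals its group target
  exactly.
* Intakes: every participant consumes every food, with gamma-distributed
  grams (CV default 0.6) around the group's population intake divided
  equally over the group's foods; at CV = 0 intakes are deterministic.
* Descriptor flags are emitted consistently with the packaged NOVA rules
  and grouping criteria, so the classifier recovers the planted labels.

Both generators draw from independent substreams of one shared seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diet_builder import ConsumptionRecord
from .food_composition import FoodRecord, NutrientVector, write_composition_table
from .food_grouping import EXCLUDED

__all__ = [
    "ANIMAL_GROUPS",
    "VEGETABLE_GROUPS",
    "DEFAULT_GROUP_TARGETS",
    "DEFAULT_GROUP_INTAKE_G",
    "GROUP_FLAGS",
    "GroundTruth",
    "generate_composition_table",
    "generate_consumption_survey",
    "write_consumption_csv",
]

#: groups whose protein counts as animal-source
ANIMAL_GROUPS = frozenset({"dairy", "red_meat", "poultry", "eggs", "fish"})
VEGETABLE_GROUPS = frozenset(
    {"whole_grains", "tubers", "vegetables", "fruits", "legumes", "nuts",
     "added_fats", "added_sugars", "drinks"}
)

#: descriptor flags emitted per group, consistent with the packaged NOVA
#: rules and grouping criteria (EXCLUDED foods are ultra-processed snacks)
GROUP_FLAGS: dict[str, tuple[str, ...]] = {
    "whole_grains": ("grain", "whole_grain", "processed"),
    "tubers": ("tuber", "raw"),
    "vegetables": ("vegetable", "raw_vegetable"),
    "fruits": ("fruit", "fresh_fruit"),
    "dairy": ("dairy", "processed"),
    "red_meat": ("red_meat", "raw"),
    "poultry": ("poultry", "raw"),
    "eggs": ("egg", "raw"),
    "fish": ("fish", "raw"),
    "legumes": ("legume", "raw"),
    "nuts": ("nut", "raw"),
    "added_fats": ("added_fat", "culinary_ingredient"),
    "added_sugars": ("added_sugar", "culinary_ingredient"),
    "drinks": ("beverage", "raw"),
    EXCLUDED: ("snack", "ultra_processed"),
}

#: NOVA level implied by each group's flags under the packaged rule table
GROUP_NOVA: dict[str, int] = {
    "whole_grains": 3,
    "tubers": 1,
    "vegetables": 1,
    "fruits": 1,
    "dairy": 3,
    "red_meat": 1,
    "poultry": 1,
    "eggs": 1,
    "fish": 1,
    "legumes": 1,
    "nuts": 1,
    "added_fats": 2,
    "added_sugars": 2,
    "drinks": 1,
    EXCLUDED: 4,
}

#: target *component* densities per 100 g; aggregates are derived (see module doc)
DEFAULT_GROUP_TARGETS: dict[str, dict[str, float]] = {
    "whole_grains": {
        "mono_di_saccharides": 2, "polysaccharides": 39, "fiber": 7, "protein": 9,
        "saturated_fat": 0.4, "monounsaturated_fat": 0.6, "polyunsaturated_fat": 0.8,
        "trans_fat": 0.02, "linoleic_acid": 0.7, "alpha_linolenic_acid": 0.06,
        "water": 38, "vitamin_b1": 0.25, "vitamin_b2": 0.1, "vitamin_b3": 4,
        "vitamin_b6": 0.2, "vitamin_b9": 40, "vitamin_e": 1, "vitamin_k": 2,
        "calcium": 30, "copper": 0.2, "iron": 2.5, "iodine": 30, "potassium": 220,
        "magnesium": 80, "sodium": 450, "phosphorus": 200, "selenium": 30, "zinc": 1.8,
    },
    "tubers": {
        "mono_di_saccharides": 1, "polysaccharides": 16, "fiber": 2, "protein": 2,
        "saturated_fat": 0.05, "monounsaturated_fat": 0.05, "polyunsaturated_fat": 0.1,
        "water": 79, "vitamin_c": 12, "vitamin_b6": 0.3, "potassium": 380,
        "magnesium": 22, "phosphorus": 50, "iron": 0.7, "zinc": 0.4, "sodium": 5,
        "vitamin_b1": 0.1, "vitamin_b9": 25, "selenium": 0.5, "calcium": 6,
        "copper": 0.1, "vitamin_b3": 1.2, "vitamin_e": 0.05, "vitamin_k": 2,
    },
    "vegetables": {
        "mono_di_saccharides": 2.5, "polysaccharides": 1.5, "fiber": 2.5, "protein": 1.8,
        "saturated_fat": 0.1, "monounsaturated_fat": 0.1, "polyunsaturated_fat": 0.2,
        "water": 92, "vitamin_a": 150, "vitamin_c": 30, "vitamin_b9": 80,
        "vitamin_k": 100, "potassium": 280, "calcium": 45, "magnesium": 15,
        "iron": 0.9, "sodium": 20, "vitamin_e": 1, "vitamin_b2": 0.08,
        "vitamin_b6": 0.1, "vitamin_b1": 0.06, "vitamin_b3": 0.7, "selenium": 0.8,
        "zinc": 0.4, "copper": 0.06, "iodine": 3, "phosphorus": 40,
    },
    "fruits": {
        "mono_di_saccharides": 10, "polysaccharides": 2, "fiber": 2, "protein": 0.8,
        "saturated_fat": 0.1, "monounsaturated_fat": 0.1, "polyunsaturated_fat": 0.1,
        "water": 85, "vitamin_c": 40, "potassium": 200, "vitamin_b9": 20,
        "vitamin_a": 20, "calcium": 10, "magnesium": 10, "iron": 0.3,
        "vitamin_b6": 0.08, "vitamin_e": 0.5, "vitamin_k": 5, "sodium": 2,
        "zinc": 0.1, "copper": 0.08, "vitamin_b1": 0.03, "vitamin_b2": 0.03,
        "vitamin_b3": 0.4, "selenium": 0.2, "phosphorus": 15,
    },
    "dairy": {
        "mono_di_saccharides": 4.5, "sugars": 1.5, "protein": 4,
        "saturated_fat": 1.9, "monounsaturated_fat": 0.8, "polyunsaturated_fat": 0.1,
        "trans_fat": 0.1, "water": 87, "calcium": 120, "vitamin_b2": 0.18,
        "vitamin_b12": 0.4, "phosphorus": 95, "potassium": 160, "zinc": 0.5,
        "iodine": 15, "sodium": 45, "vitamin_a": 30, "vitamin_d": 0.05,
        "selenium": 1.5, "magnesium": 11, "vitamin_b1": 0.04, "vitamin_b6": 0.04,
        "vitamin_b3": 0.1, "cholesterol": 10, "vitamin_b9": 5, "vitamin_c": 1,
    },
    "red_meat": {
        "protein": 21, "saturated_fat": 4, "monounsaturated_fat": 4.5,
        "polyunsaturated_fat": 0.8, "trans_fat": 0.3, "water": 68, "iron": 2,
        "zinc": 4, "vitamin_b12": 2, "vitamin_b6": 0.4, "vitamin_b3": 5,
        "vitamin_b1": 0.4, "sodium": 60, "potassium": 330, "phosphorus": 180,
        "selenium": 10, "cholesterol": 70, "vitamin_d": 0.3, "vitamin_a": 5,
        "copper": 0.1, "magnesium": 20, "vitamin_b2": 0.2, "vitamin_b9": 5,
    },
    "poultry": {
        "protein": 22, "saturated_fat": 1.7, "monounsaturated_fat": 2.5,
        "polyunsaturated_fat": 1.2, "water": 72, "iron": 0.7, "zinc": 1,
        "vitamin_b12": 0.4, "vitamin_b3": 8, "vitamin_b6": 0.5, "selenium": 12,
        "sodium": 70, "potassium": 300, "phosphorus": 200, "cholesterol": 80,
        "vitamin_b2": 0.15, "magnesium": 25, "vitamin_b1": 0.07, "vitamin_b9": 8,
        "vitamin_d": 0.1, "vitamin_a": 15,
    },
    "eggs": {
        "mono_di_saccharides": 0.3, "protein": 12.5, "saturated_fat": 3,
        "monounsaturated_fat": 4, "polyunsaturated_fat": 1.5, "water": 76,
        "iron": 1.9, "zinc": 1.3, "vitamin_b12": 1.6, "vitamin_b2": 0.4,
        "vitamin_d": 1.8, "vitamin_a": 180, "selenium": 23, "cholesterol": 390,
        "vitamin_b9": 45, "calcium": 55, "phosphorus": 190, "sodium": 130,
        "potassium": 130, "magnesium": 12, "vitamin_b1": 0.06, "vitamin_b6": 0.1,
        "vitamin_b3": 0.1, "vitamin_e": 1.9,
    },
    "fish": {
        "protein": 19, "saturated_fat": 1.7, "monounsaturated_fat": 3,
        "polyunsaturated_fat": 2.2, "epa": 500, "dha": 700, "water": 70,
        "vitamin_d": 5, "vitamin_b12": 3, "selenium": 30, "iodine": 30,
        "sodium": 80, "potassium": 350, "phosphorus": 220, "iron": 0.5,
        "zinc": 0.5, "vitamin_e": 1, "vitamin_b3": 6, "vitamin_b6": 0.4,
        "vitamin_b2": 0.15, "vitamin_a": 25, "cholesterol": 60,
        "alpha_linolenic_acid": 0.1, "linoleic_acid": 0.2, "calcium": 20,
        "magnesium": 30,
    },
    "legumes": {
        "mono_di_saccharides": 1.5, "polysaccharides": 12.5, "fiber": 7, "protein": 8,
        "saturated_fat": 0.1, "monounsaturated_fat": 0.2, "polyunsaturated_fat": 0.4,
        "water": 69, "iron": 2, "zinc": 1, "magnesium": 40, "vitamin_b9": 80,
        "potassium": 300, "vitamin_b1": 0.15, "copper": 0.25, "phosphorus": 120,
        "calcium": 45, "selenium": 2, "sodium": 5, "vitamin_b6": 0.15,
        "vitamin_b3": 0.8, "vitamin_e": 0.5, "vitamin_k": 10, "vitamin_b2": 0.06,
    },
    "nuts": {
        "mono_di_saccharides": 4.5, "polysaccharides": 2.5, "fiber": 8, "protein": 18,
        "saturated_fat": 6, "monounsaturated_fat": 30, "polyunsaturated_fat": 17,
        "linoleic_acid": 15, "alpha_linolenic_acid": 1.5, "water": 4, "vitamin_e": 12,
        "magnesium": 200, "iron": 3, "zinc": 3, "copper": 1.2, "potassium": 600,
        "vitamin_b1": 0.3, "vitamin_b9": 60, "selenium": 5, "calcium": 80,
        "phosphorus": 400, "vitamin_b3": 4, "vitamin_b6": 0.3, "sodium": 5,
        "vitamin_b2": 0.2, "vitamin_k": 3,
    },
    "added_fats": {
        "saturated_fat": 15, "monounsaturated_fat": 35, "polyunsaturated_fat": 28,
        "trans_fat": 0.5, "linoleic_acid": 25, "alpha_linolenic_acid": 2.5,
        "water": 15, "vitamin_e": 30, "vitamin_d": 0.75, "vitamin_a": 400,
        "sodium": 80, "vitamin_k": 50, "cholesterol": 5,
    },
    "added_sugars": {"mono_di_saccharides": 99, "sugars": 99, "water": 0.5},
    "drinks": {"water": 99, "potassium": 20, "magnesium": 2, "sodium": 1},
    EXCLUDED: {
        "mono_di_saccharides": 30, "sugars": 25, "polysaccharides": 25, "fiber": 2,
        "protein": 5, "saturated_fat": 10, "monounsaturated_fat": 7,
        "polyunsaturated_fat": 4, "trans_fat": 0.5, "water": 12, "sodium": 400,
        "potassium": 150, "calcium": 40, "iron": 1, "vitamin_e": 2, "cholesterol": 20,
    },
}

#: population intake per group, g/day, split equally over the group's foods
DEFAULT_GROUP_INTAKE_G: dict[str, float] = {
    "whole_grains": 130, "tubers": 70, "vegetables": 130, "fruits": 110,
    "dairy": 350, "red_meat": 70, "poultry": 30, "eggs": 25, "fish": 15,
    "legumes": 10, "nuts": 10, "added_fats": 40, "added_sugars": 40,
    "drinks": 1800, EXCLUDED: 150,
}


def derive_aggregates(components: dict[str, float], group: str) -> dict[str, float]:
    """Fill in the derived density fields for one food or group target."""
    d = dict(components)
    d["carbohydrate"] = d.get("mono_di_saccharides", 0.0) + d.get("polysaccharides", 0.0)
    d["cis_unsaturated_fat"] = d.get("monounsaturated_fat", 0.0) + d.get("polyunsaturated_fat", 0.0)
    d["total_fat"] = (
        d.get("saturated_fat", 0.0) + d["cis_unsaturated_fat"] + d.get("trans_fat", 0.0)
    )
    protein = d.get("protein", 0.0)
    if group in ANIMAL_GROUPS:
        d["animal_protein"], d["vegetable_protein"] = protein, 0.0
    else:
        d["animal_protein"], d["vegetable_protein"] = 0.0, protein
    d["energy_kcal"] = (
        4.0 * d["carbohydrate"] + 4.0 * protein + 9.0 * d["total_fat"]
        + 2.0 * d.get("fiber", 0.0) + 7.0 * d.get("alcohol", 0.0)
    )
    return d


@dataclass
class GroundTruth:
    """Everything the generators planted, for closed-loop testing."""

    seed: int
    cv: float
    excluded_fraction: float
    group_of: dict[str, str]  # food id -> true group (or EXCLUDED)
    nova_of: dict[str, int]  # food id -> true NOVA level
    group_targets: dict[str, dict[str, float]] = field(default_factory=dict)  # incl. aggregates

    def foods_in_group(self, group: str) -> list[str]:
        return sorted(f for f, g in self.group_of.items() if g == group)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "cv": self.cv,
                    "excluded_fraction": self.excluded_fraction,
                    "group_of": self.group_of,
                    "nova_of": self.nova_of,
                    "group_targets": self.group_targets,
                },
                indent=2,
                sort_keys=True,
            ),
            encoding="utf-8",
        )


def generate_composition_table(
    n_foods: int = 120,
    seed: int = 1,
    targets: dict[str, dict[str, float]] | None = None,
    cv: float = 0.2,
    excluded_fraction: float = 0.1,
    out_dir: str | Path | None = None,
) -> tuple[list[FoodRecord], GroundTruth]:
    """Generate a NEVO-like catalog of ``n_foods`` foods with planted groups.

    Foods are spread round-robin over the target groups after reserving the
    planted excluded fraction; densities are log-normal around the group
    targets with unit mean and coefficient of variation ``cv``.  Rerunning
    with the same arguments is bit-identical.
    """
    targets = targets if targets is not None else DEFAULT_GROUP_TARGETS
    groups = [g for g in targets if g != EXCLUDED]
    if n_foods < len(groups):
        raise ValueError(f"need at least one food per group: n_foods={n_foods} < {len(groups)} groups")

    n_excluded = int(round(n_foods * excluded_fraction)) if EXCLUDED in targets else 0
    plan: list[str] = []
    for i in range(n_foods - n_excluded):
        plan.append(groups[i % len(groups)])
    plan += [EXCLUDED] * n_excluded

    rng = np.random.default_rng([int(seed), 101])
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    counters: dict[str, int] = {}
    records: list[FoodRecord] = []
    group_of: dict[str, str] = {}
    nova_of: dict[str, int] = {}
    for group in plan:
        counters[group] = counters.get(group, 0) + 1
        food_id = f"{group.lower()}_{counters[group]:03d}"
        base = targets[group]
        nutrients = sorted(base)
        if sigma > 0:
            z = rng.standard_normal(len(nutrients))
            noisy = {
                n: base[n] * math.exp(sigma * z[i] - 0.5 * sigma * sigma)
                for i, n in enumerate(nutrients)
            }
        else:
            noisy = {n: float(base[n]) for n in nutrients}
        density = derive_aggregates(noisy, group)
        records.append(
            FoodRecord(
                food_id=food_id,
                name=f"synthetic {group.lower()} food {counters[group]}",
                flags=GROUP_FLAGS[group],
                density=NutrientVector(density),
            )
        )
        group_of[food_id] = group
        nova_of[food_id] = GROUP_NOVA[group]

    truth = GroundTruth(
        seed=int(seed),
        cv=float(cv),
        excluded_fraction=n_excluded / n_foods,
        group_of=group_of,
        nova_of=nova_of,
        group_targets={g: derive_aggregates(t, g) for g, t in targets.items()},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_composition_table(records, out_dir / "composition.csv")
        truth.to_json(out_dir / "ground_truth.json")
    return records, truth


def generate_consumption_survey(
    n_participants: int = 500,
    seed: int = 1,
    foods: list[FoodRecord] | None = None,
    truth: GroundTruth | None = None,
    group_intake_g: dict[str, float] | None = None,
    grams_cv: float = 0.6,
    out_dir: str | Path | None = None,
) -> list[ConsumptionRecord]:
    """Generate an FCS-like survey: every participant consumes every food.

    Grams per (participant, food) are gamma-distributed with mean = group
    intake / foods in group and coefficient of variation ``grams_cv``
    (deterministic at 0).  Uses a substream of the shared seed independent
    of the composition generator's.
    """
    if foods is None or truth is None:
        raise ValueError("generate the composition table first and pass foods + ground truth")
    group_intake_g = group_intake_g if group_intake_g is not None else DEFAULT_GROUP_INTAKE_G

    rng = np.random.default_rng([int(seed), 202])
    counts: dict[str, int] = {}
    for g in truth.group_of.values():
        counts[g] = counts.get(g, 0) + 1

    records: list[ConsumptionRecord] = []
    participant_ids = [f"p{i + 1:04d}" for i in range(n_participants)]
    for food in foods:
        group = truth.group_of[food.food_id]
        mean = group_intake_g.get(group, 0.0) / counts[group]
        if mean <= 0:
            continue
        if grams_cv > 0:
            shape = 1.0 / (grams_cv * grams_cv)
            grams = rng.gamma(shape=shape, scale=mean / shape, size=n_participants)
        else:
            grams = np.full(n_participants, mean)
        records.extend(
            ConsumptionRecord(pid, food.food_id, float(g))
            for pid, g in zip(participant_ids, grams)
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_consumption_csv(records, out_dir / "consumption.csv")
    return records


def write_consumption_csv(records: list[ConsumptionRecord], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(r.participant_id, r.food_id, r.grams) for r in records],
        columns=["participant_id", "food_id", "grams"],
    ).to_csv(path, index=False)
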
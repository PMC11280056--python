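"""Build theoretical diets: per-group mean densities scaled to scheme amounts.

The construction models a *theoretical diet*: what the whole-diet nutrient
supply would be if a population ate exactly the scheme's recommended grams
of each food group, where each group's nutrient density is the mean density
of the foods the population actually consumes in that group.

Group densities default to consumption-weighted means across survey records
(each record contributes its consumed mass as weight); an unweighted mean
over distinct foods is available as an alternative reading.  Scaling a
group's per-100 g density by its recommended grams/day and summing over
groups gives the daily nutrient totals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .food_composition import FoodRecord, NutrientVector
from .food_grouping import Assignment
from .scheme_harmonizer import DietScheme

logger = logging.getLogger("dietmodel")

__all__ = [
    "DietBuildError",
    "ConsumptionRecord",
    "GroupComposition",
    "DietProfile",
    "read_consumption",
    "group_mean_composition",
    "group_compositions",
    "build_diet",
    "water_content",
]


class DietBuildError(ValueError):
    """Raised when a diet cannot be built (empty groups, missing data)."""


@dataclass(frozen=True)
class ConsumptionRecord:
    """One survey observation: a participant consumed ``grams`` of a food in a day."""

    participant_id: str
    food_id: str
    grams: float

    def __post_init__(self):
        if self.grams < 0:
            raise DietBuildError(f"negative consumed mass for food {self.food_id!r}")


def read_consumption(path: str | Path) -> list[ConsumptionRecord]:
    """Read consumption records from CSV (``participant_id,food_id,grams``)."""
    df = pd.read_csv(path, dtype={"participant_id": str, "food_id": str})
    for col in ("participant_id", "food_id", "grams"):
        if col not in df.columns:
            raise DietBuildError(f"consumption file missing required column {col!r}")
    return [
        ConsumptionRecord(r.participant_id, r.food_id, float(r.grams))
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class GroupComposition:
    """Mean nutrient density per 100 g for one food group, with support stats."""

    group: str
    density: NutrientVector
    food_count: int
    total_mass: float

    def __post_init__(self):
        if self.food_count < 1:
            raise DietBuildError(f"group {self.group!r}: composition needs at least one food")


def group_mean_composition(
    records: Sequence[ConsumptionRecord],
    assignments: Mapping[str, Assignment],
    foods: Iterable[FoodRecord],
    group: str,
    weighted: bool = True,
) -> GroupComposition:
    """Mean nutrient density of one food group from survey consumption.

    ``weighted`` (default): density = Σ(record grams × food density) / Σ grams,
    i.e. each gram the population ate counts equally.  ``weighted=False``
    instead averages each distinct consumed food once.  A scheme group with
    no supporting consumption fails loudly — a diet cannot be built on it.
    """
    by_id = {f.food_id: f for f in foods}
    sums = NutrientVector.zeros()
    total_mass = 0.0
    consumed_food_ids: set[str] = set()

    # stable order: sort by (food_id, participant_id) so accumulation is reproducible
    for rec in sorted(records, key=lambda r: (r.food_id, r.participant_id)):
        asn = assignments.get(rec.food_id)
        if asn is None or asn.group != group:
            continue
        food = by_id.get(rec.food_id)
        if food is None:
            raise DietBuildError(f"consumption references food {rec.food_id!r} absent from composition table")
        if rec.grams <= 0:
            continue
        consumed_food_ids.add(rec.food_id)
        total_mass += rec.grams
        sums = sums + food.density * rec.grams

    if not consumed_food_ids:
        raise DietBuildError(f"no consumed food is assigned to group {group!r}")

    if weighted:
        density = sums * (1.0 / total_mass)
    else:
        acc = NutrientVector.zeros()
        for fid in sorted(consumed_food_ids):
            acc = acc + by_id[fid].density
        density = acc * (1.0 / len(consumed_food_ids))

    return GroupComposition(
        group=group, density=density, food_count=len(consumed_food_ids), total_mass=total_mass
    )


def group_compositions(
    records: Sequence[ConsumptionRecord],
    assignments: Mapping[str, Assignment],
    foods: Iterable[FoodRecord],
    groups: Iterable[str],
    weighted: bool = True,
) -> dict[str, GroupComposition]:
    foods = list(foods)
    return {
        g: group_mean_composition(records, assignments, foods, g, weighted=weighted)
        for g in groups
    }


@dataclass(frozen=True)
class DietProfile:
    """Whole-diet daily nutrient totals for one scheme and sex.

    ``contributions`` maps group id → that group's daily nutrient vector;
    the total is their component-wise sum (conserved by construction).
    """

    scheme_id: str
    sex: str
    total: NutrientVector
    contributions: dict[str, NutrientVector] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "scheme_id": self.scheme_id,
            "sex": self.sex,
            "totals": self.total.to_dict(),
            "contributions": {g: v.to_dict() for g, v in self.contributions.items()},
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "DietProfile":
        """Load a profile from JSON — also the entry point for fixture mode,
        where published daily totals are injected directly instead of being
        rebuilt from survey data."""
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            scheme_id=doc["scheme_id"],
            sex=doc.get("sex", "both"),
            total=NutrientVector(doc["totals"]),
            contributions={g: NutrientVector(v) for g, v in doc.get("contributions", {}).items()},
        )


def build_diet(
    scheme: DietScheme,
    compositions: Mapping[str, GroupComposition],
    sex: str = "female",
) -> DietProfile:
    """Scale per-group densities to the scheme's grams/day and sum.

    Per-group contribution = group density × grams(sex) / 100; range-valued
    recommendations use their midpoint grams.  Every scheme group must have
    a composition.
    """
    missing = [g for g in scheme.group_ids() if g not in compositions]
    if missing:
        raise DietBuildError(
            f"scheme {scheme.scheme_id!r}: no group composition for {', '.join(missing)}"
        )
    contributions: dict[str, NutrientVector] = {}
    total = NutrientVector.zeros()
    for group in scheme.groups:  # scheme order is stable
        grams = group.amount(sex)
        contrib = compositions[group.group_id].density * (grams / 100.0)
        contributions[group.group_id] = contrib
        total = total + contrib
    return DietProfile(scheme_id=scheme.scheme_id, sex=sex, total=total, contributions=contributions)


def water_content(profile: DietProfile) -> float:
    """Daily water supplied by foods and beverages (g/day), from the total vector."""
    return profile.total.get("water")
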
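"""Assign survey foods to diet-scheme food groups via NOVA level + nutrient criteria.

Foods are first given a NOVA processing level (1 = unprocessed/minimally
processed … 4 = ultra-processed) by an ordered rule table over their
descriptor flags, then assigned to a food group by an ordered list of
criteria combining required/forbidden flags, a maximum NOVA level, and
nutrient thresholds per 100 g.  First match wins in both stages, so the
outcome depends only on rule/criterion order, never on catalog order.
Foods satisfying no criterion are EXCLUDED from the modelled diets.

The packaged criteria are a reconstruction (one criterion per food group
with coarse thresholds); both the rule table and the criteria are plain
YAML and fully replaceable.
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .food_composition import NUTRIENTS, FoodRecord

logger = logging.getLogger("dietmodel")

__all__ = [
    "EXCLUDED",
    "GroupingError",
    "NovaRule",
    "GroupCriterion",
    "Assignment",
    "classify_nova",
    "assign_food_group",
    "assign_catalog",
    "load_nova_rules",
    "load_criteria",
]

EXCLUDED = "EXCLUDED"

_OPS = {">=": operator.ge, ">": operator.gt, "<=": operator.le, "<": operator.lt, "==": operator.eq}


class GroupingError(ValueError):
    """Raised for invalid rule tables or criteria configuration."""


@dataclass(frozen=True)
class NovaRule:
    level: int
    require_flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.level not in (1, 2, 3, 4):
            raise GroupingError(f"NOVA level must be 1-4, got {self.level}")

    def matches(self, food: FoodRecord) -> bool:
        return all(f in food.flags for f in self.require_flags)


@dataclass(frozen=True)
class GroupCriterion:
    """One food-group membership criterion.

    A food satisfies the criterion when its NOVA level is at most
    ``nova_max``, all required flags are present, no forbidden flag is
    present, and every nutrient threshold holds for its density per 100 g.
    """

    group: str
    nova_max: int = 4
    require_flags: tuple[str, ...] = ()
    forbid_flags: tuple[str, ...] = ()
    nutrient_rules: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self):
        if not (self.require_flags or self.forbid_flags or self.nutrient_rules):
            raise GroupingError(f"criterion for {self.group!r} has no predicate or flag")
        for nutrient, op, value in self.nutrient_rules:
            if nutrient not in NUTRIENTS:
                raise GroupingError(f"criterion for {self.group!r}: unknown nutrient {nutrient!r}")
            if op not in _OPS:
                raise GroupingError(f"criterion for {self.group!r}: unknown comparator {op!r}")
            if value < 0:
                raise GroupingError(f"criterion for {self.group!r}: negative threshold {value}")

    def satisfied_by(self, food: FoodRecord, level: int) -> bool:
        if level > self.nova_max:
            return False
        if any(f not in food.flags for f in self.require_flags):
            return False
        if any(f in food.flags for f in self.forbid_flags):
            return False
        return all(_OPS[op](food.density.get(nutrient), value) for nutrient, op, value in self.nutrient_rules)


@dataclass(frozen=True)
class Assignment:
    """The grouping outcome for one food (group id or EXCLUDED)."""

    food_id: str
    group: str
    criterion_index: int | None  # index of the triggering criterion, None if excluded
    nova_level: int

    @property
    def excluded(self) -> bool:
        return self.group == EXCLUDED


def classify_nova(food: FoodRecord, rules: Sequence[NovaRule]) -> int:
    """NOVA level of a food: first matching rule wins; no match defaults to 4."""
    if not rules:
        raise GroupingError("empty NOVA rule table")
    for rule in rules:
        if rule.matches(food):
            return rule.level
    logger.warning("food %s matches no NOVA rule; defaulting to level 4", food.food_id)
    return 4


def assign_food_group(
    food: FoodRecord, level: int, criteria: Sequence[GroupCriterion]
) -> Assignment:
    """Assign a food to the first criterion it satisfies, else EXCLUDED."""
    for i, crit in enumerate(criteria):
        if crit.satisfied_by(food, level):
            return Assignment(food_id=food.food_id, group=crit.group, criterion_index=i, nova_level=level)
    return Assignment(food_id=food.food_id, group=EXCLUDED, criterion_index=None, nova_level=level)


def assign_catalog(
    foods: Iterable[FoodRecord],
    rules: Sequence[NovaRule],
    criteria: Sequence[GroupCriterion],
) -> dict[str, Assignment]:
    """Classify and group every food in a catalog; logs the exclusion count."""
    assignments: dict[str, Assignment] = {}
    for food in foods:
        level = classify_nova(food, rules)
        assignments[food.food_id] = assign_food_group(food, level, criteria)
    n_excluded = sum(a.excluded for a in assignments.values())
    if n_excluded:
        logger.info(
            "food grouping: %d of %d foods satisfied no criterion and were excluded",
            n_excluded,
            len(assignments),
        )
    return assignments


# ---------------------------------------------------------------------------
# configuration loading


def _criteria_path(name: str):
    return resources.files("dietmodel").joinpath("data", "criteria", name)


def load_nova_rules(path: str | Path | None = None) -> list[NovaRule]:
    """Load the ordered NOVA rule table (packaged default when no path given)."""
    if path is None:
        with resources.as_file(_criteria_path("nova_rules.yaml")) as p:
            return load_nova_rules(p)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    rules = [
        NovaRule(level=int(r["level"]), require_flags=tuple(r.get("require_flags", ())))
        for r in doc.get("rules", [])
    ]
    if not rules:
        raise GroupingError(f"NOVA rule table {path} contains no rules")
    return rules


def load_criteria(path: str | Path | None = None) -> list[GroupCriterion]:
    """Load the ordered group criteria (packaged reconstruction when no path given)."""
    if path is None:
        with resources.as_file(_criteria_path("group_criteria.yaml")) as p:
            return load_criteria(p)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    criteria = []
    for c in doc.get("criteria", []):
        criteria.append(
            GroupCriterion(
                group=c["group"],
                nova_max=int(c.get("nova_max", 4)),
                require_flags=tuple(c.get("require_flags", ())),
                forbid_flags=tuple(c.get("forbid_flags", ())),
                nutrient_rules=tuple(
                    (r["nutrient"], r["op"], float(r["value"]))
                    for r in c.get("nutrient_rules", ())
                ),
            )
        )
    if not criteria:
        raise GroupingError(f"criteria file {path} contains no criteria")
    return criteria
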
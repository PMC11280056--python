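"""Derived accounting over a diet profile: energy shares, protein partition, marine fats.

Percent of energy (%En) uses Atwater factors (carbohydrate 4, protein 4,
fat 9, fiber 2, alcohol 7 kcal/g; fat sub-fractions use the fat factor) and
the diet's total energy as read from the composition table — the total is
*not* re-derived from macronutrients, so the %En of the macronutrients does
not close to exactly 100.

Rounded values use round-half-away-from-zero at the conventional printed
precision (integer for macros, one decimal for saturated/trans fat and
alpha-linolenic acid); unrounded values are always available alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import yaml

from .diet_builder import DietProfile

__all__ = [
    "AccountingError",
    "AtwaterTable",
    "load_atwater",
    "round_half_away",
    "EnergyShare",
    "energy_percent",
    "energy_shares",
    "ProteinPartition",
    "protein_partition",
    "marine_fatty_acids",
]


class AccountingError(ValueError):
    pass


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed nutrition tables)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


#: printed precision (decimal places) of %En per nutrient
_EN_PRECISION = {
    "saturated_fat": 1,
    "trans_fat": 1,
    "alpha_linolenic_acid": 1,
}


@dataclass(frozen=True)
class AtwaterTable:
    """kcal/g factors plus the fraction→parent-factor mapping."""

    factors: dict[str, float]
    fraction_of: dict[str, str]  # e.g. saturated_fat -> total_fat

    def factor(self, nutrient: str) -> float:
        key = self.fraction_of.get(nutrient, nutrient)
        try:
            return self.factors[key]
        except KeyError:
            raise AccountingError(f"no Atwater factor defined for {nutrient!r}") from None


def load_atwater(path=None) -> AtwaterTable:
    if path is None:
        with resources.as_file(
            resources.files("dietmodel").joinpath("data", "atwater.yaml")
        ) as p:
            return load_atwater(p)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    fraction_of = {}
    for frac in doc.get("fat_fractions", ()):
        fraction_of[frac] = "total_fat"
    for frac in doc.get("carbohydrate_fractions", ()):
        fraction_of[frac] = "carbohydrate"
    for frac in doc.get("protein_fractions", ()):
        fraction_of[frac] = "protein"
    return AtwaterTable(factors={k: float(v) for k, v in doc["factors"].items()}, fraction_of=fraction_of)


_DEFAULT_ATWATER = load_atwater()


@dataclass(frozen=True)
class EnergyShare:
    """One nutrient's contribution to daily energy."""

    nutrient: str
    grams: float
    factor: float  # kcal/g
    percent_energy: float  # unrounded %En
    percent_energy_rounded: float  # at printed precision

    @property
    def kcal(self) -> float:
        return self.grams * self.factor


def energy_percent(
    grams: float,
    nutrient: str,
    total_energy: float,
    factors: AtwaterTable | None = None,
) -> EnergyShare:
    """%En of a nutrient: grams × Atwater factor / total kcal × 100."""
    if total_energy <= 0:
        raise AccountingError(f"total energy must be > 0 kcal, got {total_energy}")
    if grams < 0:
        raise AccountingError(f"grams must be >= 0, got {grams}")
    factors = factors or _DEFAULT_ATWATER
    factor = factors.factor(nutrient)
    pct = grams * factor / total_energy * 100.0
    return EnergyShare(
        nutrient=nutrient,
        grams=grams,
        factor=factor,
        percent_energy=pct,
        percent_energy_rounded=round_half_away(pct, _EN_PRECISION.get(nutrient, 0)),
    )


_DEFAULT_EN_NUTRIENTS = (
    "carbohydrate",
    "protein",
    "total_fat",
    "saturated_fat",
    "polyunsaturated_fat",
    "trans_fat",
    "alpha_linolenic_acid",
)


def energy_shares(
    profile: DietProfile,
    nutrients: tuple[str, ...] = _DEFAULT_EN_NUTRIENTS,
    factors: AtwaterTable | None = None,
) -> dict[str, EnergyShare]:
    """Energy shares of the profile's macronutrients against its own total kcal."""
    total_kcal = profile.total.get("energy_kcal")
    return {
        n: energy_percent(profile.total.get(n), n, total_kcal, factors=factors) for n in nutrients
    }


@dataclass(frozen=True)
class ProteinPartition:
    """Split of daily protein into animal and vegetable sources."""

    total_g: float
    animal_g: float
    vegetable_g: float

    @property
    def animal_pct(self) -> float:
        return self.animal_g / self.total_g * 100.0 if self.total_g else 0.0

    @property
    def vegetable_pct(self) -> float:
        return self.vegetable_g / self.total_g * 100.0 if self.total_g else 0.0

    @classmethod
    def from_grams(cls, animal_g: float, vegetable_g: float) -> "ProteinPartition":
        return cls(total_g=animal_g + vegetable_g, animal_g=animal_g, vegetable_g=vegetable_g)


def protein_partition(
    profile: DietProfile,
    vegetable_groups: set[str] | None = None,
) -> ProteinPartition:
    """Partition the profile's protein into animal vs vegetable sources.

    With ``vegetable_groups`` given, every group of the profile must be
    labelled (member = vegetable source, non-member = animal source) and the
    split sums the per-group protein contributions.  Without it, the
    profile's own ``vegetable_protein``/``animal_protein`` components are
    used (the fixture-mode path for published totals).
    """
    if vegetable_groups is not None:
        if not profile.contributions:
            raise AccountingError("profile carries no per-group contributions to partition")
        animal = vegetable = 0.0
        for group, contrib in profile.contributions.items():
            if group in vegetable_groups:
                vegetable += contrib.get("protein")
            else:
                animal += contrib.get("protein")
        return ProteinPartition.from_grams(animal_g=animal, vegetable_g=vegetable)
    return ProteinPartition.from_grams(
        animal_g=profile.total.get("animal_protein"),
        vegetable_g=profile.total.get("vegetable_protein"),
    )


def marine_fatty_acids(epa_mg: float, dha_mg: float) -> float:
    """Marine (long-chain omega-3) fatty acids: EPA + DHA, mg/day."""
    if epa_mg < 0 or dha_mg < 0:
        raise AccountingError("EPA and DHA must be >= 0")
    return epa_mg + dha_mg
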
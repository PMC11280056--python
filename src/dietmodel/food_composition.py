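"""Food-composition table: nutrient dictionary, per-food nutrient densities, I/O.

The composition table mirrors the layout of national food-composition
databases such as the Dutch NEVO: one row per food, nutrient densities
expressed per 100 g edible portion.  All nutrient identifiers are validated
against a packaged nutrient dictionary that fixes the unit and aggregation
role (macro / fatty-acid / vitamin / mineral / water) of every nutrient
carried through the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("dietmodel")

__all__ = [
    "NUTRIENTS",
    "NutrientDictionary",
    "NutrientVector",
    "FoodRecord",
    "CompositionError",
    "read_composition_table",
    "write_composition_table",
    "scale_to_grams",
]


class CompositionError(ValueError):
    """Raised for malformed composition tables or invalid nutrient data."""


def _data_path(*parts: str):
    return resources.files("dietmodel").joinpath("data", *parts)


@dataclass(frozen=True)
class NutrientDictionary:
    """The packaged nutrient panel: identifier -> (display name, unit, role)."""

    table: pd.DataFrame

    @classmethod
    def load(cls) -> "NutrientDictionary":
        with resources.as_file(_data_path("nutrients.csv")) as p:
            df = pd.read_csv(p, dtype=str).set_index("nutrient")
        return cls(table=df)

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    def __contains__(self, nutrient: str) -> bool:
        return nutrient in self.table.index

    def unit(self, nutrient: str) -> str:
        return self.table.loc[nutrient, "unit"]

    def display_name(self, nutrient: str) -> str:
        return self.table.loc[nutrient, "display_name"]

    def role(self, nutrient: str) -> str:
        return self.table.loc[nutrient, "role"]


#: Module-level singleton; every NutrientVector validates against it.
NUTRIENTS = NutrientDictionary.load()


class NutrientVector:
    """A map nutrient id -> amount, unit-fixed per nutrient by the dictionary.

    Amounts are non-negative; unknown nutrient identifiers are rejected.
    Addition is component-wise (missing components count as zero), scalar
    multiplication scales every component.  The basis (per 100 g, per day,
    ...) is contextual and carried by the owning object.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float] | None = None):
        vals: dict[str, float] = {}
        for k, v in (values or {}).items():
            if k not in NUTRIENTS:
                raise CompositionError(f"unknown nutrient identifier: {k!r}")
            v = float(v)
            if v < 0:
                raise CompositionError(f"negative amount for {k!r}: {v}")
            vals[k] = v
        self._values = vals

    def get(self, nutrient: str, default: float = 0.0) -> float:
        if nutrient not in NUTRIENTS:
            raise CompositionError(f"unknown nutrient identifier: {nutrient!r}")
        return self._values.get(nutrient, default)

    def __getitem__(self, nutrient: str) -> float:
        return self.get(nutrient)

    def items(self):
        return self._values.items()

    def keys(self):
        return self._values.keys()

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        keys = set(self._values) | set(other._values)
        # stable accumulation order for bit-reproducible totals
        out = {k: self._values.get(k, 0.0) + other._values.get(k, 0.0) for k in sorted(keys)}
        return NutrientVector(out)

    def __mul__(self, factor: float) -> "NutrientVector":
        if factor < 0:
            raise CompositionError(f"negative scale factor: {factor}")
        return NutrientVector({k: v * factor for k, v in sorted(self._values.items())})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        if not isinstance(other, NutrientVector):
            return NotImplemented
        keys = set(self._values) | set(other._values)
        return all(self.get(k) == other.get(k) for k in keys)

    def allclose(self, other: "NutrientVector", rel: float = 1e-9, abs_tol: float = 1e-12) -> bool:
        keys = set(self._values) | set(other._values)
        for k in keys:
            a, b = self.get(k), other.get(k)
            if abs(a - b) > abs_tol + rel * max(abs(a), abs(b)):
                return False
        return True

    def __repr__(self) -> str:
        return f"NutrientVector({self._values!r})"

    @classmethod
    def zeros(cls) -> "NutrientVector":
        return cls({})


@dataclass
class FoodRecord:
    """One food: identity, free-text processing descriptors, density per 100 g."""

    food_id: str
    name: str
    flags: tuple[str, ...] = field(default_factory=tuple)
    density: NutrientVector = field(default_factory=NutrientVector.zeros)

    def has_flag(self, flag: str) -> bool:
        return flag in self.flags


_META_COLS = ("food_id", "name", "nova_descriptors")


def read_composition_table(path: str | Path) -> list[FoodRecord]:
    """Read a composition CSV into FoodRecords.

    Layout: ``food_id,name,nova_descriptors,<nutrient columns...>`` with
    semicolon-separated descriptor flags.  Missing nutrient cells are imputed
    as 0 (composition databases are sparse; whole-diet sums treat absent as
    zero) — the imputation count is logged.  Unknown nutrient columns and
    duplicate food ids abort the load.
    """
    df = pd.read_csv(path, dtype={"food_id": str, "name": str, "nova_descriptors": str})
    for col in _META_COLS:
        if col not in df.columns:
            raise CompositionError(f"composition table missing required column {col!r}")
    nutrient_cols = [c for c in df.columns if c not in _META_COLS]
    unknown = [c for c in nutrient_cols if c not in NUTRIENTS]
    if unknown:
        raise CompositionError(f"unknown nutrient column(s): {', '.join(unknown)}")
    dup = df["food_id"][df["food_id"].duplicated()]
    if not dup.empty:
        raise CompositionError(f"duplicate food id(s): {', '.join(sorted(set(dup)))}")

    n_missing = int(df[nutrient_cols].isna().sum().sum())
    if n_missing:
        logger.warning(
            "composition table %s: %d missing nutrient cell(s) imputed as 0", path, n_missing
        )
    df[nutrient_cols] = df[nutrient_cols].fillna(0.0)

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        flags_raw = d.get("nova_descriptors")
        flags = tuple(f for f in str(flags_raw).split(";") if f) if pd.notna(flags_raw) else ()
        density = NutrientVector({c: d[c] for c in nutrient_cols})
        records.append(FoodRecord(food_id=d["food_id"], name=d["name"], flags=flags, density=density))
    return records


def write_composition_table(records: Iterable[FoodRecord], path: str | Path) -> None:
    """Write FoodRecords back to the CSV layout accepted by the reader."""
    records = list(records)
    nutrient_cols = sorted({k for r in records for k in r.density.keys()})
    rows = []
    for r in records:
        row = {
            "food_id": r.food_id,
            "name": r.name,
            "nova_descriptors": ";".join(r.flags),
        }
        row.update({c: r.density.get(c) for c in nutrient_cols})
        rows.append(row)
    pd.DataFrame(rows, columns=list(_META_COLS) + nutrient_cols).to_csv(path, index=False)


def scale_to_grams(food: FoodRecord, grams: float) -> NutrientVector:
    """Nutrients supplied by ``grams`` of a food: density × grams / 100.

    Densities are per 100 g edible portion, so the scaling is linear and
    additive in the consumed mass.
    """
    if grams < 0:
        raise CompositionError(f"grams must be >= 0, got {grams}")
    return food.density * (grams / 100.0)
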
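"""Diet schemes: food-group recommendations, serving conversion, cross-scheme matching.

A *diet scheme* is a named set of food-group recommendations in grams/day
(optionally sex-differentiated, optionally given as a low–high range whose
point value is the midpoint).  Two packaged schemes are shipped: the
Planetary Health Diet (PHD, EAT-Lancet reference diet) and the Dutch Dietary
Guidelines (DDG, "Wheel of Five"), together with an explicit group mapping
between them.  Matching across schemes is judgment-based configuration — food
groups are paired by food nature, never by name similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

__all__ = [
    "SchemeError",
    "GroupRecommendation",
    "DietScheme",
    "GroupMatch",
    "servings_to_grams",
    "merge_groups",
    "match_groups",
    "comparison_table",
    "load_scheme",
    "load_phd",
    "load_ddg",
    "load_default_mapping",
]


class SchemeError(ValueError):
    """Raised for malformed schemes, mappings, or conversion inputs."""


@dataclass(frozen=True)
class GroupRecommendation:
    """One food group's recommended daily amount, in grams, by sex.

    ``amount_female``/``amount_male`` are point values; when the guideline
    states a range, ``low``/``high`` are kept for reporting and the point
    value is the range midpoint.
    """

    group_id: str
    name: str
    amount_female: float
    amount_male: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        if self.amount_female < 0 or self.amount_male < 0:
            raise SchemeError(f"group {self.group_id!r}: negative amount")
        if (self.low is None) != (self.high is None):
            raise SchemeError(f"group {self.group_id!r}: range needs both endpoints")
        if self.low is not None:
            if self.low > self.high:
                raise SchemeError(f"group {self.group_id!r}: range low > high")
            mid = (self.low + self.high) / 2.0
            for amt in (self.amount_female, self.amount_male):
                if abs(amt - mid) > 1e-9:
                    raise SchemeError(
                        f"group {self.group_id!r}: point value {amt} is not the range midpoint {mid}"
                    )

    @property
    def has_range(self) -> bool:
        return self.low is not None

    @property
    def sex_differentiated(self) -> bool:
        return self.amount_female != self.amount_male

    def amount(self, sex: str) -> float:
        if sex == "female":
            return self.amount_female
        if sex == "male":
            return self.amount_male
        raise SchemeError(f"unknown sex {sex!r} (expected 'female' or 'male')")


@dataclass(frozen=True)
class DietScheme:
    """A named, ordered set of group recommendations plus the outside-scheme
    energy allowance (% of daily energy permitted from non-listed foods)."""

    scheme_id: str
    groups: tuple[GroupRecommendation, ...]
    outside_energy_pct: float = 0.0

    def __post_init__(self):
        ids = [g.group_id for g in self.groups]
        if len(ids) != len(set(ids)):
            raise SchemeError(f"scheme {self.scheme_id!r}: duplicate group ids")
        if not 0 <= self.outside_energy_pct <= 100:
            raise SchemeError("outside_energy_pct must be in [0, 100]")

    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.groups]

    def __getitem__(self, group_id: str) -> GroupRecommendation:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def __contains__(self, group_id: str) -> bool:
        return group_id in self.group_ids()


def servings_to_grams(servings, serving_size):
    """Convert a servings/day recommendation to grams/day.

    Either argument may be a ``(low, high)`` pair; the result is then the
    ``(low_g, high_g, midpoint_g)`` triple.  Scalar inputs give the plain
    product servings × serving size.
    """

    def _as_range(x):
        if isinstance(x, (tuple, list)):
            lo, hi = float(x[0]), float(x[1])
            if lo > hi:
                raise SchemeError(f"range low > high: {x}")
            return lo, hi
        return float(x), float(x)

    s_lo, s_hi = _as_range(servings)
    g_lo, g_hi = _as_range(serving_size)
    if s_lo < 0:
        raise SchemeError(f"servings must be >= 0, got {servings}")
    if g_lo <= 0:
        raise SchemeError(f"serving size must be > 0, got {serving_size}")
    lo, hi = s_lo * g_lo, s_hi * g_hi
    if lo == hi:
        return lo
    return lo, hi, (lo + hi) / 2.0


def merge_groups(
    scheme: DietScheme,
    source_ids: Sequence[str],
    target_id: str,
    target_name: str | None = None,
) -> DietScheme:
    """Merge several groups into one whose amount is the per-sex sum.

    Used to harmonize group granularity across schemes (e.g. folding a
    separate cheese group into dairy, or collapsing the beef/lamb and pork
    red-meat subgroups, which share the same caloric density).  The merged
    group takes the list position of the first source group.
    """
    missing = [s for s in source_ids if s not in scheme]
    if missing:
        raise SchemeError(f"cannot merge: unknown group id(s) {missing} in scheme {scheme.scheme_id!r}")
    sources = [scheme[s] for s in source_ids]
    if len(sources) == 1 and sources[0].group_id == target_id:
        return scheme  # merging a group into itself is the identity

    def _end(g: GroupRecommendation, which: str) -> float:
        if g.has_range:
            return g.low if which == "low" else g.high
        # a point recommendation is a degenerate range
        return (g.amount_female + g.amount_male) / 2.0

    any_range = any(g.has_range for g in sources)
    merged = GroupRecommendation(
        group_id=target_id,
        name=target_name or " + ".join(g.name for g in sources),
        amount_female=sum(g.amount_female for g in sources),
        amount_male=sum(g.amount_male for g in sources),
        low=sum(_end(g, "low") for g in sources) if any_range else None,
        high=sum(_end(g, "high") for g in sources) if any_range else None,
    )
    out: list[GroupRecommendation] = []
    placed = False
    for g in scheme.groups:
        if g.group_id in source_ids:
            if not placed:
                out.append(merged)
                placed = True
            continue
        out.append(g)
    return replace(scheme, groups=tuple(out))


@dataclass(frozen=True)
class GroupMatch:
    """One row of a scheme comparison: a matched pair or an unmatched group.

    ``diff_*`` is the signed A − B difference of daily grams (unmatched
    groups are compared against 0).  When the B-side recommendation is a
    range, ``diff_low``/``diff_high`` give the A-point minus each endpoint.
    """

    a_id: str | None
    b_id: str | None
    status: str  # matched | unmatched-A-only | unmatched-B-only
    diff_female: float = 0.0
    diff_male: float = 0.0
    diff_low: float | None = None
    diff_high: float | None = None

    def __post_init__(self):
        if self.status == "matched":
            if self.a_id is None or self.b_id is None:
                raise SchemeError("matched rows need both group ids")
        elif self.status == "unmatched-A-only":
            if self.a_id is None or self.b_id is not None:
                raise SchemeError("unmatched-A-only rows carry the A id only")
        elif self.status == "unmatched-B-only":
            if self.b_id is None or self.a_id is not None:
                raise SchemeError("unmatched-B-only rows carry the B id only")
        else:
            raise SchemeError(f"unknown match status {self.status!r}")

    def difference(self, sex: str = "female") -> float:
        return self.diff_female if sex == "female" else self.diff_male


def match_groups(
    a: DietScheme, b: DietScheme, mapping: Sequence[tuple[str, str]]
) -> list[GroupMatch]:
    """Compare two schemes through an explicit (a-id, b-id) pair list.

    Pairs yield signed A − B gram differences per sex; groups absent from
    the mapping become unmatched rows with the difference taken against 0.
    Every id may appear in at most one pair.
    """
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    for a_id, b_id in mapping:
        if a_id not in a:
            raise SchemeError(f"mapping references unknown group {a_id!r} in scheme {a.scheme_id!r}")
        if b_id not in b:
            raise SchemeError(f"mapping references unknown group {b_id!r} in scheme {b.scheme_id!r}")
        if a_id in seen_a or b_id in seen_b:
            raise SchemeError(f"group referenced twice in mapping: ({a_id!r}, {b_id!r})")
        seen_a.add(a_id)
        seen_b.add(b_id)

    matches: list[GroupMatch] = []
    for a_id, b_id in mapping:
        ga, gb = a[a_id], b[b_id]
        diff_low = diff_high = None
        if gb.has_range and not ga.has_range:
            diff_low = ga.amount_female - gb.low
            diff_high = ga.amount_female - gb.high
        matches.append(
            GroupMatch(
                a_id=a_id,
                b_id=b_id,
                status="matched",
                diff_female=ga.amount_female - gb.amount_female,
                diff_male=ga.amount_male - gb.amount_male,
                diff_low=diff_low,
                diff_high=diff_high,
            )
        )
    for g in a.groups:
        if g.group_id not in seen_a:
            matches.append(
                GroupMatch(
                    a_id=g.group_id,
                    b_id=None,
                    status="unmatched-A-only",
                    diff_female=g.amount_female,
                    diff_male=g.amount_male,
                )
            )
    for g in b.groups:
        if g.group_id not in seen_b:
            matches.append(
                GroupMatch(
                    a_id=None,
                    b_id=g.group_id,
                    status="unmatched-B-only",
                    diff_female=-g.amount_female,
                    diff_male=-g.amount_male,
                )
            )
    return matches


def comparison_table(a: DietScheme, b: DietScheme, matches: Iterable[GroupMatch]):
    """Render matches as a tidy table (one row per match, grams and differences)."""
    import pandas as pd

    rows = []
    for m in matches:
        ga = a[m.a_id] if m.a_id else None
        gb = b[m.b_id] if m.b_id else None
        rows.append(
            {
                "group_a": ga.name if ga else "No equivalent group",
                "group_b": gb.name if gb else "No equivalent group",
                "a_g_per_day": ga.amount_female if ga else 0.0,
                "b_g_per_day": gb.amount_female if gb else 0.0,
                "b_range": f"{gb.low:g}-{gb.high:g}" if gb is not None and gb.has_range else "",
                "status": m.status,
                "difference_a_minus_b": m.diff_female,
                "difference_male": m.diff_male,
                "difference_vs_range_low": m.diff_low,
                "difference_vs_range_high": m.diff_high,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged scheme loading


def _scheme_path(name: str):
    return resources.files("dietmodel").joinpath("data", "schemes", name)


def load_scheme(path: str | Path) -> DietScheme:
    """Load a scheme from YAML (``amount_g``, ``servings``+``serving_g``, or ``range``)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _scheme_from_doc(doc)


def _scheme_from_doc(doc: dict) -> DietScheme:
    groups = []
    for g in doc.get("groups", []):
        low = high = None
        if "range" in g:
            low, high = float(g["range"][0]), float(g["range"][1])
            point = (low + high) / 2.0
            amount_f = float(g.get("amount_g_female", point))
            amount_m = float(g.get("amount_g_male", point))
        elif "servings" in g:
            grams = servings_to_grams(g["servings"], g["serving_g"])
            if isinstance(grams, tuple):
                low, high, point = grams
            else:
                point = grams
            amount_f = float(g.get("amount_g_female", point))
            amount_m = float(g.get("amount_g_male", point))
        else:
            amount_f = float(g.get("amount_g_female", g.get("amount_g")))
            amount_m = float(g.get("amount_g_male", g.get("amount_g")))
        groups.append(
            GroupRecommendation(
                group_id=g["id"],
                name=g.get("name", g["id"]),
                amount_female=amount_f,
                amount_male=amount_m,
                low=low,
                high=high,
            )
        )
    return DietScheme(
        scheme_id=doc["scheme_id"],
        groups=tuple(groups),
        outside_energy_pct=float(doc.get("outside_energy_pct", 0.0)),
    )


def load_phd(merge_red_meat: bool = True) -> DietScheme:
    """The packaged Planetary Health Diet scheme.

    With ``merge_red_meat`` (default) the beef/lamb and pork subgroups are
    collapsed into a single ``red_meat`` group (7 + 7 = 14 g/day), matching
    the granularity at which the two schemes are compared.
    """
    with resources.as_file(_scheme_path("phd.yaml")) as p:
        scheme = load_scheme(p)
    if merge_red_meat:
        scheme = merge_groups(scheme, ["beef_lamb", "pork"], "red_meat", "Beef, lamb, and pork")
    return scheme


def load_ddg(merge_cheese: bool = True) -> DietScheme:
    """The packaged Dutch Dietary Guidelines scheme.

    With ``merge_cheese`` (default) the cheese group is folded into dairy
    (630 + 25 = 655 g/day) so both schemes expose one comparable dairy group.
    """
    with resources.as_file(_scheme_path("ddg.yaml")) as p:
        scheme = load_scheme(p)
    if merge_cheese:
        scheme = merge_groups(scheme, ["milk_dairy", "cheese"], "dairy", "Milk and dairy products + cheese")
    return scheme


def load_default_mapping() -> list[tuple[str, str]]:
    """The packaged PHD↔DDG group correspondence (explicit configuration)."""
    with resources.as_file(_scheme_path("phd_ddg_mapping.yaml")) as p:
        with open(p, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    return [(a, b) for a, b in doc["pairs"]]
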
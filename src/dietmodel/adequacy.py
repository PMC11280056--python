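"""Dietary Reference Value registry and adequacy scoring (%DRV, status calls).

The packaged registry covers the adult nutrient panel: Estimated Average
Requirements (EAR) with Adequate Intake (AI) fallback, maximum-intake values
(sodium), percent-of-energy references and bands (carbohydrate, protein,
fat, saturated/trans/polyunsaturated fat, alpha-linolenic acid), and
age-band pairs (19–50 / 51–70) where references differ by age.  Scoring
conventions:

* EAR preferred, AI used only where no EAR exists;
* %DRV = intake / reference × 100, one value per age band (multi-band
  references yield a low–high range); the primary status call uses the
  19–50 adult band;
* intake exactly at the reference counts as "meets" (only strict
  shortfalls are flagged);
* calcium carries two reference values (750 and 860 mg) with an averaging
  rule; the working value 860 mg is the default and the 805 mg average is
  available via ``calcium_policy="average"``.
* zinc references are stored decimal-corrected (12.1 / 15.5 mg).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .diet_builder import DietProfile
from .nutrient_accounting import AtwaterTable, load_atwater, marine_fatty_acids

__all__ = [
    "AdequacyError",
    "DRVRecord",
    "AdequacyResult",
    "load_registry",
    "select_reference",
    "percent_drv",
    "classify",
    "adequacy_table",
]

_REQUIREMENT_KINDS = ("EAR", "AI", "EN_PCT")
_LIMIT_KINDS = ("UL", "EN_PCT_UL")


class AdequacyError(ValueError):
    pass


@dataclass(frozen=True)
class DRVRecord:
    """One reference value for a nutrient, sex, and age band."""

    nutrient: str
    sex: str  # female | male | both
    age_low: int
    age_high: int
    kind: str  # EAR | AI | UL | EN_PCT | EN_PCT_UL
    value: float
    unit: str
    energy_ref_kcal: float | None = None  # reference diet kcal for energy-scaled DRVs
    band: str | None = None  # low/high endpoint of an energy-percent band
    note: str | None = None

    def __post_init__(self):
        if self.value <= 0:
            raise AdequacyError(f"{self.nutrient}: reference value must be > 0")
        if self.age_low > self.age_high:
            raise AdequacyError(f"{self.nutrient}: age band low > high")

    def applies_to(self, sex: str) -> bool:
        return self.sex == "both" or self.sex == sex

    def scaled_value(self, diet_kcal: float) -> float:
        """Reference rescaled to a diet's energy (for energy-scaled DRVs)."""
        if not self.energy_ref_kcal:
            return self.value
        return self.value * diet_kcal / self.energy_ref_kcal


def load_registry(path: str | Path | None = None) -> list[DRVRecord]:
    """Load the DRV registry CSV (packaged default when no path given)."""
    if path is None:
        with resources.as_file(
            resources.files("dietmodel").joinpath("data", "drv_registry.csv")
        ) as p:
            return load_registry(p)
    df = pd.read_csv(path, dtype={"nutrient": str, "sex": str, "kind": str})
    records = []
    for r in df.itertuples(index=False):
        records.append(
            DRVRecord(
                nutrient=r.nutrient,
                sex=r.sex,
                age_low=int(r.age_low),
                age_high=int(r.age_high),
                kind=r.kind,
                value=float(r.value),
                unit=r.unit,
                energy_ref_kcal=float(r.energy_ref_kcal) if pd.notna(r.energy_ref_kcal) else None,
                band=r.band if pd.notna(r.band) else None,
                note=r.note if pd.notna(r.note) else None,
            )
        )
    return records


def select_reference(
    nutrient: str,
    sex: str,
    registry: list[DRVRecord],
    kinds: tuple[str, ...] = _REQUIREMENT_KINDS,
    calcium_policy: str = "table",
) -> list[DRVRecord]:
    """Select the reference records for a nutrient and sex.

    For requirement references the EAR is preferred and the AI is the
    fallback (energy-percent references stand on their own).  An empty list
    means the nutrient is not assessable against the requested kinds — the
    caller must surface a not-assessed result, never drop the nutrient
    silently.  Calcium follows its averaging rule: the default policy keeps
    the 860 mg working value; ``calcium_policy="average"`` averages the two
    stored values (→ 805 mg).
    """
    rows = [r for r in registry if r.nutrient == nutrient and r.applies_to(sex) and r.kind in kinds]

    if nutrient == "calcium" and any(r.note == "calcium_alt" for r in rows):
        main = [r for r in rows if r.note != "calcium_alt"]
        if calcium_policy == "average":
            all_vals = [r.value for r in rows]
            base = main[0]
            return [
                DRVRecord(
                    nutrient=base.nutrient,
                    sex=base.sex,
                    age_low=base.age_low,
                    age_high=base.age_high,
                    kind=base.kind,
                    value=sum(all_vals) / len(all_vals),
                    unit=base.unit,
                    note="average of stored reference values",
                )
            ]
        rows = main

    for kind in ("EAR", "AI", "EN_PCT", "UL", "EN_PCT_UL"):
        if kind not in kinds:
            continue
        selected = [r for r in rows if r.kind == kind]
        if selected:
            return selected
    return []


def _reference_grams(ref: DRVRecord, total_energy: float | None, atwater: AtwaterTable) -> float:
    """Gram-equivalent of an energy-percent reference for a given diet energy."""
    if total_energy is None or total_energy <= 0:
        raise AdequacyError(
            f"{ref.nutrient}: an energy-percent reference needs the diet's total energy"
        )
    return ref.value / 100.0 * total_energy / atwater.factor(ref.nutrient)


def percent_drv(
    intake: float,
    references: list[DRVRecord] | DRVRecord,
    total_energy: float | None = None,
    atwater: AtwaterTable | None = None,
):
    """%DRV of an intake against one or more reference records.

    Mass references give intake/value × 100; energy-percent references are
    first converted to the gram amount they imply at the diet's total
    energy.  A single reference yields a scalar; several (age bands or band
    endpoints) yield the ``(low, high)`` range of %DRV values.
    """
    if intake < 0:
        raise AdequacyError(f"intake must be >= 0, got {intake}")
    refs = [references] if isinstance(references, DRVRecord) else list(references)
    if not refs:
        raise AdequacyError("no reference records given")
    atwater = atwater or load_atwater()
    pcts = []
    for ref in refs:
        denom = (
            _reference_grams(ref, total_energy, atwater)
            if ref.kind in ("EN_PCT", "EN_PCT_UL")
            else ref.value
        )
        pcts.append(intake / denom * 100.0)
    if len(pcts) == 1:
        return pcts[0]
    return min(pcts), max(pcts)


@dataclass(frozen=True)
class AdequacyResult:
    """Adequacy call for one nutrient: %DRV (scalar or range) and status."""

    nutrient: str
    sex: str
    intake: float
    reference_kind: str | None
    reference_value: float | None
    pct_drv: float | tuple[float, float] | None
    status: str  # below | meets | above-upper-limit | not-assessed


def classify(
    intake: float,
    nutrient: str,
    sex: str,
    registry: list[DRVRecord],
    total_energy: float | None = None,
    adult_band: tuple[int, int] = (19, 50),
    calcium_policy: str = "table",
) -> AdequacyResult:
    """Adequacy status of an intake for one nutrient.

    Requirement references (EAR/AI/energy-percent): strictly below the
    19–50-band reference → "below", otherwise "meets"; an intake above the
    high endpoint of an energy-percent band → "above-upper-limit".
    Maximum-intake references (sodium, saturated/trans/polyunsaturated fat
    limits): above the limit → "above-upper-limit", otherwise "meets"
    (reported below the maximum).  A nutrient without any reference is
    "not-assessed".
    """
    atwater = load_atwater()
    refs = select_reference(nutrient, sex, registry, calcium_policy=calcium_policy)
    limits = select_reference(nutrient, sex, registry, kinds=_LIMIT_KINDS)

    if not refs and not limits:
        return AdequacyResult(nutrient, sex, intake, None, None, None, "not-assessed")

    if refs:
        pct = percent_drv(intake, refs, total_energy=total_energy, atwater=atwater)
        primary = [r for r in refs if (r.age_low, r.age_high) == adult_band] or refs
        lows = [r for r in primary if r.band != "high"]
        highs = [r for r in primary if r.band == "high"]

        status = "meets"
        for r in lows:
            denom = (
                _reference_grams(r, total_energy, atwater) if r.kind.startswith("EN_PCT") else r.value
            )
            if intake < denom:
                status = "below"
        for r in highs:
            denom = (
                _reference_grams(r, total_energy, atwater) if r.kind.startswith("EN_PCT") else r.value
            )
            if intake > denom:
                status = "above-upper-limit"
        result = AdequacyResult(nutrient, sex, intake, refs[0].kind, primary[0].value, pct, status)
    else:
        result = None

    if limits:
        lim = limits[0]
        denom = (
            _reference_grams(lim, total_energy, atwater) if lim.kind == "EN_PCT_UL" else lim.value
        )
        lim_pct = intake / denom * 100.0
        if intake > denom:
            return AdequacyResult(nutrient, sex, intake, lim.kind, lim.value, lim_pct, "above-upper-limit")
        if result is None:
            # a pure maximum-intake reference: under the cap means "meets"
            return AdequacyResult(nutrient, sex, intake, lim.kind, lim.value, lim_pct, "meets")
    return result


def adequacy_table(
    profile: DietProfile,
    sex: str,
    registry: list[DRVRecord] | None = None,
    calcium_policy: str = "table",
) -> pd.DataFrame:
    """Score a whole diet profile against the registry, one row per nutrient.

    Marine fatty acids are derived as EPA + DHA before scoring.  Nutrients
    present in the registry but absent from the profile score at intake 0;
    profile nutrients without any reference appear as not-assessed.
    """
    registry = registry if registry is not None else load_registry()
    total_energy = profile.total.get("energy_kcal")

    intakes: dict[str, float] = dict(profile.total.items())
    intakes["marine_fatty_acids"] = marine_fatty_acids(
        profile.total.get("epa"), profile.total.get("dha")
    )
    intakes.pop("energy_kcal", None)

    assessable = {r.nutrient for r in registry}
    rows = []
    for nutrient in sorted(set(intakes) | assessable):
        intake = intakes.get(nutrient, 0.0)
        res = classify(
            intake,
            nutrient,
            sex,
            registry,
            total_energy=total_energy,
            calcium_policy=calcium_policy,
        )
        pct = res.pct_drv
        rows.append(
            {
                "nutrient": nutrient,
                "sex": sex,
                "intake": intake,
                "reference_kind": res.reference_kind,
                "reference_value": res.reference_value,
                "pct_drv_low": pct[0] if isinstance(pct, tuple) else pct,
                "pct_drv_high": pct[1] if isinstance(pct, tuple) else pct,
                "status": res.status,
            }
        )
    return pd.DataFrame(rows)
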
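"""Group mean densities, diet building, and conservation properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietmodel.diet_builder import (
    ConsumptionRecord,
    DietBuildError,
    GroupComposition,
    build_diet,
    group_compositions,
    group_mean_composition,
    water_content,
)
from dietmodel.food_composition import FoodRecord, NutrientVector
from dietmodel.food_grouping import EXCLUDED, Assignment
from dietmodel.scheme_harmonizer import DietScheme, GroupRecommendation


def _food(food_id, **density):
    return FoodRecord(food_id=food_id, name=food_id, density=NutrientVector(density))


def _assign(food_id, group):
    return Assignment(food_id=food_id, group=group, criterion_index=0, nova_level=1)


def _scheme(*amounts):
    return DietScheme(
        scheme_id="S",
        groups=tuple(
            GroupRecommendation(group_id=g, name=g, amount_female=a, amount_male=a)
            for g, a in amounts
        ),
    )


class TestGroupMeanComposition:
    def test_single_food_gives_its_density(self):
        foods = [_food("f1", calcium=40, water=80)]
        comp = group_mean_composition(
            [ConsumptionRecord("p1", "f1", 120)], {"f1": _assign("f1", "g")}, foods, "g"
        )
        assert comp.density == foods[0].density
        assert comp.food_count == 1

    def test_equal_masses_give_symmetric_mean(self):
        foods = [_food("f1", calcium=40), _food("f2", calcium=80)]
        records = [ConsumptionRecord("p1", "f1", 100), ConsumptionRecord("p1", "f2", 100)]
        asn = {"f1": _assign("f1", "g"), "f2": _assign("f2", "g")}
        comp = group_mean_composition(records, asn, foods, "g")
        assert comp.density.get("calcium") == pytest.approx(60)

    def test_weighting_follows_consumed_mass(self):
        foods = [_food("f1", calcium=40), _food("f2", calcium=80)]
        records = [ConsumptionRecord("p1", "f1", 300), ConsumptionRecord("p1", "f2", 100)]
        asn = {"f1": _assign("f1", "g"), "f2": _assign("f2", "g")}
        weighted = group_mean_composition(records, asn, foods, "g")
        unweighted = group_mean_composition(records, asn, foods, "g", weighted=False)
        assert weighted.density.get("calcium") == pytest.approx(50)  # (300*40+100*80)/400
        assert unweighted.density.get("calcium") == pytest.approx(60)

    def test_empty_group_fails_loudly(self):
        foods = [_food("f1", calcium=1)]
        with pytest.raises(DietBuildError, match="'ghost'"):
            group_mean_composition([], {"f1": _assign("f1", "g")}, foods, "ghost")

    def test_synthetic_group_means_match_brute_force(self, synth_bundle):
        """Weighted means agree with an independent numpy computation."""
        foods, truth, records, assignments = synth_bundle
        by_id = {f.food_id: f for f in foods}
        groups = sorted(set(truth.group_of.values()) - {EXCLUDED})
        comps = group_compositions(records, assignments, foods, groups)
        for group in groups:
            mask = [r for r in records if truth.group_of[r.food_id] == group]
            w = np.array([r.grams for r in mask])
            for nutrient in ("energy_kcal", "protein", "calcium", "water"):
                dens = np.array([by_id[r.food_id].density.get(nutrient) for r in mask])
                expected = float(np.sum(w * dens) / np.sum(w))
                assert comps[group].density.get(nutrient) == pytest.approx(expected, rel=1e-9)


class TestBuildDiet:
    def test_single_group_100g_returns_density(self):
        comp = GroupComposition("g", NutrientVector({"calcium": 55, "water": 70}), 1, 100)
        profile = build_diet(_scheme(("g", 100)), {"g": comp})
        assert profile.total == comp.density

    def test_missing_composition_rejected(self):
        with pytest.raises(DietBuildError, match="no group composition"):
            build_diet(_scheme(("g", 100)), {})

    @given(
        scale=st.floats(min_value=0.1, max_value=10),
        a1=st.floats(min_value=0, max_value=500),
        a2=st.floats(min_value=0, max_value=500),
        d1=st.floats(min_value=0, max_value=90),
        d2=st.floats(min_value=0, max_value=90),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_totals_linear_in_scheme_amounts(self, scale, a1, a2, d1, d2):
        comps = {
            "g1": GroupComposition("g1", NutrientVector({"protein": d1}), 1, 1),
            "g2": GroupComposition("g2", NutrientVector({"protein": d2}), 1, 1),
        }
        base = build_diet(_scheme(("g1", a1), ("g2", a2)), comps)
        scaled = build_diet(_scheme(("g1", a1 * scale), ("g2", a2 * scale)), comps)
        assert scaled.total.get("protein") == pytest.approx(
            base.total.get("protein") * scale, rel=1e-9, abs=1e-9
        )

    def test_contributions_sum_to_total(self, synth_bundle, phd):
        foods, truth, records, assignments = synth_bundle
        groups = sorted(set(truth.group_of.values()) - {EXCLUDED})
        comps = group_compositions(records, assignments, foods, groups)
        profile = build_diet(phd, comps, sex="female")
        summed = NutrientVector.zeros()
        for contrib in profile.contributions.values():
            summed = summed + contrib
        assert summed.allclose(profile.total, rel=1e-12)

    def test_noise_free_recovery_is_matrix_product(self, synth_bundle_cv0, phd):
        """With densities at targets and deterministic intakes, totals equal
        the analytic product target-density x scheme-grams / 100."""
        foods, truth, records, assignments = synth_bundle_cv0
        groups = sorted(set(truth.group_of.values()) - {EXCLUDED})
        comps = group_compositions(records, assignments, foods, groups)
        profile = build_diet(phd, comps, sex="female")
        for nutrient in ("energy_kcal", "protein", "calcium", "fiber", "water", "epa"):
            expected = sum(
                truth.group_targets[g].get(nutrient, 0.0) * phd[g].amount_female / 100.0
                for g in phd.group_ids()
            )
            assert profile.total.get(nutrient) == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_sex_differentiated_amounts_flow_through(self):
        scheme = DietScheme(
            scheme_id="S",
            groups=(
                GroupRecommendation(group_id="g", name="g", amount_female=100, amount_male=200),
            ),
        )
        comp = {"g": GroupComposition("g", NutrientVector({"protein": 10}), 1, 1)}
        assert build_diet(scheme, comp, sex="female").total.get("protein") == 10
        assert build_diet(scheme, comp, sex="male").total.get("protein") == 20


class TestWaterContent:
    def test_zero_water_densities(self):
        comp = {"g": GroupComposition("g", NutrientVector({"protein": 10}), 1, 1)}
        assert water_content(build_diet(_scheme(("g", 500)), comp)) == 0.0

    def test_beverage_group_scaling(self):
        comp = {"drinks": GroupComposition("drinks", NutrientVector({"water": 99}), 1, 1)}
        profile = build_diet(_scheme(("drinks", 1500)), comp)
        assert water_content(profile) == pytest.approx(1485)

    def test_synthetic_water_equals_sum_over_groups(self, synth_bundle, phd):
        foods, truth, records, assignments = synth_bundle
        groups = sorted(set(truth.group_of.values()) - {EXCLUDED})
        comps = group_compositions(records, assignments, foods, groups)
        profile = build_diet(phd, comps)
        brute = sum(c.get("water") for c in profile.contributions.values())
        assert water_content(profile) == pytest.approx(brute, rel=1e-12)
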
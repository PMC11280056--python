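"""DRV selection (EAR-else-AI), %DRV computation, and adequacy status calls."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietmodel.adequacy import (
    DRVRecord,
    adequacy_table,
    classify,
    percent_drv,
    select_reference,
)


class TestSelectReference:
    def test_selenium_resolves_to_adequate_intake(self, registry):
        refs = select_reference("selenium", "male", registry)
        assert len(refs) == 1
        assert refs[0].kind == "AI"
        assert refs[0].value == 70

    def test_vitamin_d_resolves_to_ear_for_both_sexes(self, registry):
        for sex in ("female", "male"):
            refs = select_reference("vitamin_d", sex, registry)
            assert refs[0].kind == "EAR"
            assert refs[0].value == 10

    def test_unknown_nutrient_yields_empty_selection(self, registry):
        assert select_reference("boron", "female", registry) == []

    def test_ear_preferred_over_ai_when_both_exist(self):
        rows = [
            DRVRecord("x", "both", 19, 50, "AI", 99, "mg"),
            DRVRecord("x", "both", 19, 50, "EAR", 50, "mg"),
        ]
        refs = select_reference("x", "female", rows)
        assert [r.kind for r in refs] == ["EAR"]

    def test_calcium_default_uses_working_value(self, registry):
        refs = select_reference("calcium", "female", registry)
        assert [r.value for r in refs] == [860]

    def test_calcium_average_policy(self, registry):
        refs = select_reference("calcium", "female", registry, calcium_policy="average")
        assert refs[0].value == pytest.approx(805)  # mean of 750 and 860

    def test_upper_limits_not_returned_as_requirements(self, registry):
        assert select_reference("sodium", "female", registry) == []
        lims = select_reference("sodium", "female", registry, kinds=("UL",))
        assert lims[0].value == 2400

    def test_every_registry_nutrient_resolves(self, registry):
        """EAR-else-AI (or energy-percent / limit) selection is total."""
        for nutrient in {r.nutrient for r in registry}:
            for sex in ("female", "male"):
                reqs = select_reference(nutrient, sex, registry)
                lims = select_reference(nutrient, sex, registry, kinds=("UL", "EN_PCT_UL"))
                assert reqs or lims, f"{nutrient}/{sex} resolves to no reference"


class TestPercentDrv:
    def test_fiber_range_across_age_bands(self, registry):
        refs = select_reference("fiber", "female", registry)
        low, high = percent_drv(39, refs)
        assert (low, high) == (130.0, 156.0)  # 39/30 and 39/25

    def test_intake_equal_to_reference_is_100(self):
        ref = DRVRecord("iron", "both", 19, 50, "EAR", 7, "mg")
        assert percent_drv(7, ref) == 100.0

    def test_energy_percent_reference_converts_to_grams(self, registry):
        # 40 %En carbohydrate of 1952 kcal = 195.2 g -> 179 g is 91.7 %DRV
        refs = select_reference("carbohydrate", "female", registry)
        assert percent_drv(179, refs, total_energy=1952) == pytest.approx(91.70, abs=0.01)

    @given(
        intake=st.floats(min_value=0, max_value=1e4),
        scale=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_and_scale_equivariant(self, intake, scale):
        ref = DRVRecord("iron", "both", 19, 50, "EAR", 7, "mg")
        base = percent_drv(intake, ref)
        assert percent_drv(intake * scale, ref) == pytest.approx(base * scale, rel=1e-9)
        if scale > 1 and intake > 0:
            assert percent_drv(intake * scale, ref) > base


class TestClassify:
    def test_vitamin_d_below_in_both_diets(self, registry, phd_nl, ddg_nl):
        for profile in (phd_nl, ddg_nl):
            res = classify(profile.total.get("vitamin_d"), "vitamin_d", "female", registry)
            assert res.status == "below"

    def test_calcium_below_in_phd_only(self, registry):
        assert classify(794, "calcium", "female", registry).status == "below"
        assert classify(1652, "calcium", "female", registry).status == "meets"

    def test_calcium_status_robust_to_averaging_policy(self, registry):
        for policy in ("table", "average"):
            assert classify(794, "calcium", "female", registry, calcium_policy=policy).status == "below"

    def test_intake_exactly_at_reference_meets(self, registry):
        assert classify(10, "vitamin_d", "female", registry).status == "meets"

    def test_sodium_under_maximum_reports_meets(self, registry, phd_nl, ddg_nl):
        for profile in (phd_nl, ddg_nl):
            res = classify(profile.total.get("sodium"), "sodium", "female", registry)
            assert res.status == "meets"
        assert classify(3000, "sodium", "female", registry).status == "above-upper-limit"

    def test_energy_band_statuses_for_total_fat(self, registry):
        # 42 %En exceeds the 20-40 %En fat band; 34 %En sits inside it
        res_high = classify(92, "total_fat", "female", registry, total_energy=1952)
        assert res_high.status == "above-upper-limit"
        res_ok = classify(74, "total_fat", "female", registry, total_energy=1968)
        assert res_ok.status == "meets"

    def test_unknown_nutrient_is_not_assessed_never_dropped(self, registry, phd_nl):
        res = classify(1.0, "alcohol", "female", registry)
        assert res.status == "not-assessed"
        table = adequacy_table(phd_nl, sex="female", registry=registry)
        assert set(table.nutrient) >= set(dict(phd_nl.total.items())) - {"energy_kcal"}


class TestAdequacyTable:
    def test_published_status_calls(self, registry, phd_nl, ddg_nl):
        phd = adequacy_table(phd_nl, sex="female", registry=registry).set_index("nutrient")
        ddg = adequacy_table(ddg_nl, sex="female", registry=registry).set_index("nutrient")
        assert phd.loc["vitamin_d", "status"] == "below"
        assert ddg.loc["vitamin_d", "status"] == "below"
        assert phd.loc["calcium", "status"] == "below"
        assert ddg.loc["calcium", "status"] == "meets"
        assert phd.loc["sodium", "status"] == "meets"
        assert phd.loc["marine_fatty_acids", "pct_drv_low"] == pytest.approx(140)
        assert ddg.loc["marine_fatty_acids", "pct_drv_low"] == pytest.approx(73)

    def test_micronutrients_meet_requirements_where_published(self, registry, phd_nl):
        table = adequacy_table(phd_nl, sex="female", registry=registry).set_index("nutrient")
        for nutrient in ("vitamin_a", "vitamin_b2", "vitamin_b6", "vitamin_b12", "iron", "selenium"):
            assert table.loc[nutrient, "status"] == "meets", nutrient
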
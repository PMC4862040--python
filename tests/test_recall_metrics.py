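"""Per-respondent metrics: servings, energy density, GI/GL, BMI, profile aggregation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcst.config import GIConfig
from hcst.food_model_io import (
    FoodGroup,
    FoodRecord,
    NutrientProfilePerRA,
    RecallItem,
    Respondent,
    Sex,
    Tier,
)
from hcst.recall_metrics import (
    bmi,
    build_profile,
    dietary_gi,
    energy_density,
    glycemic_load,
    resolve_gi,
    servings_of,
)
from hcst.tier_classifier import classify_foods


def food(fid, group=FoodGroup.VEG_FRUIT, subgroup="fruit", kcal100=100,
         grams_serving=50, beverage=False, gi=None, **prof):
    p = dict(fat=0.5, satfat=0.1, sugars=2, sodium=10)
    p.update(prof)
    return FoodRecord(
        food_id=fid, food_group=group, subgroup=subgroup,
        profile=NutrientProfilePerRA(
            total_fat_g=p["fat"], sat_fat_g=p["satfat"],
            sugars_g=p["sugars"], sodium_mg=p["sodium"],
        ),
        energy_kcal_per_100g=kcal100, grams_per_RA=50, grams_per_serving=grams_serving,
        is_beverage=beverage, gi_value=gi,
    )


def item(fid, grams, kcal, carb=0.0, **nut):
    nutrients = {"carb_g": carb}
    nutrients.update(nut)
    return RecallItem(respondent_id="r", food_id=fid, amount_g=grams,
                      energy_kcal=kcal, nutrient_amounts=nutrients)


class TestServings:
    def test_ratio_of_amount_to_serving_weight(self):
        assert servings_of(item("a", 150, 100), food("a", grams_serving=50)) == 3.0

    def test_fractional_servings_are_kept(self):
        assert servings_of(item("a", 25, 50), food("a", grams_serving=50)) == 0.5


class TestEnergyDensity:
    def test_single_food(self):
        foods = {"a": food("a")}
        assert energy_density([item("a", 250, 500)], foods) == 2.0

    def test_beverages_are_excluded(self):
        foods = {"a": food("a"), "b": food("b", beverage=True)}
        items = [item("a", 250, 500), item("b", 330, 140)]
        assert energy_density(items, foods) == 2.0

    def test_two_foods(self):
        foods = {"a": food("a"), "b": food("b")}
        items = [item("a", 100, 200), item("b", 300, 100)]
        assert energy_density(items, foods) == pytest.approx(0.75)

    def test_all_beverage_day_is_undefined(self):
        foods = {"b": food("b", beverage=True)}
        assert energy_density([item("b", 330, 140)], foods) is None


class TestGlycemic:
    def test_gl_formula(self):
        assert glycemic_load(50, 30) == 15.0
        assert glycemic_load(0, 30) == 0.0

    def test_dietary_gi_is_carb_weighted(self):
        foods = {"a": food("a", gi=40), "b": food("b", gi=80)}
        items = [item("a", 100, 100, carb=50), item("b", 100, 100, carb=25)]
        gi, gl = dietary_gi(items, foods, GIConfig())
        assert gi == pytest.approx((40 * 50 + 80 * 25) / 75)
        assert gl == pytest.approx(40 * 50 / 100 + 80 * 25 / 100)

    def test_no_carbs_means_undefined_gi_and_zero_gl(self):
        foods = {"a": food("a", gi=40)}
        gi, gl = dietary_gi([item("a", 100, 100, carb=0)], foods, GIConfig())
        assert gi is None and gl == 0.0

    def test_gi_lies_between_item_extremes(self):
        foods = {"a": food("a", gi=40), "b": food("b", gi=80)}
        items = [item("a", 100, 100, carb=33), item("b", 100, 100, carb=12)]
        gi, _ = dietary_gi(items, foods, GIConfig())
        assert 40 <= gi <= 80

    def test_assignment_hierarchy(self):
        cfg = GIConfig(default=55, subgroup_medians={"fruit": 50})
        assert resolve_gi(food("a", gi=62), cfg) == 62
        assert resolve_gi(food("a"), cfg) == 50
        assert resolve_gi(food("a", subgroup="potatoes", group=FoodGroup.VEG_FRUIT), cfg) == 55


class TestBMI:
    def test_closed_form(self):
        assert bmi(40, 1.40) == pytest.approx(20.408, abs=1e-3)
        assert bmi(16, 1.0) == 16.0

    def test_linear_in_weight(self):
        assert bmi(80, 1.40) == pytest.approx(2 * bmi(40, 1.40))

    def test_nonpositive_inputs_error(self):
        with pytest.raises(ValueError):
            bmi(0, 1.4)


def respondent(**kw):
    defaults = dict(respondent_id="r", age_years=10, sex=Sex.F, weight_kg=32,
                    height_m=1.38, survey_weight=1.0)
    defaults.update(kw)
    return Respondent(**defaults)


class TestBuildProfile:
    def toy_day(self, config):
        foods = {
            "t1": food("t1", kcal100=80),
            "t4": food("t4", group=FoodGroup.GRAIN, subgroup="baked_goods_desserts",
                       kcal100=400, fat=12, satfat=1, sugars=22, sodium=100),
            "bev": food("bev", group=FoodGroup.OTHER, subgroup="beverages",
                        kcal100=44, beverage=True),
        }
        assignments = classify_foods(list(foods.values()), config)
        items = [
            item("t1", 200, 160, carb=30, total_fat_g=1, protein_g=2),
            item("t4", 50, 200, carb=25, total_fat_g=6, protein_g=2),
            item("bev", 250, 110, carb=27, added_sugars_g=25),
        ]
        return foods, assignments, items

    def test_single_tier4_food_is_100_percent_nonrecommended(self, config):
        foods, assignments, _ = self.toy_day(config)
        p = build_profile(respondent(), [item("t4", 50, 200, carb=25)], foods, assignments)
        assert p.pct_energy_nonrecommended == 100.0

    def test_single_tier1_food_is_0_percent(self, config):
        foods, assignments, _ = self.toy_day(config)
        p = build_profile(respondent(), [item("t1", 100, 80, carb=15)], foods, assignments)
        assert p.pct_energy_nonrecommended == 0.0

    def test_energy_is_conserved_across_tiers_and_categories(self, config):
        foods, assignments, items = self.toy_day(config)
        p = build_profile(respondent(), items, foods, assignments)
        assert sum(p.energy_by_tier.values()) == pytest.approx(p.total_energy_kcal, abs=0.1)
        assert p.total_energy_kcal == pytest.approx(470)
        # high-calorie beverage (44 kcal/100 g) plus the tier-4 pastry are non-recommended
        assert p.pct_energy_nonrecommended == pytest.approx(100 * 310 / 470)

    def test_removing_a_tier4_item_never_raises_the_percentage(self, config):
        foods, assignments, items = self.toy_day(config)
        full = build_profile(respondent(), items, foods, assignments)
        reduced = build_profile(respondent(), [items[0], items[2]], foods, assignments)
        assert reduced.pct_energy_nonrecommended <= full.pct_energy_nonrecommended

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 10))
    def test_nutrient_density_invariant_under_uniform_scaling(self, scale, config):
        foods, assignments, items = self.toy_day(config)
        base = build_profile(respondent(), items, foods, assignments)
        scaled_items = [
            RecallItem(
                respondent_id=i.respondent_id, food_id=i.food_id,
                amount_g=i.amount_g * scale, energy_kcal=i.energy_kcal * scale,
                nutrient_amounts={k: v * scale for k, v in i.nutrient_amounts.items()},
            )
            for i in items
        ]
        scaled = build_profile(respondent(), scaled_items, foods, assignments)
        for k in base.nutrient_density:
            assert math.isclose(scaled.nutrient_density[k], base.nutrient_density[k],
                                rel_tol=1e-9)
        assert math.isclose(scaled.pct_energy_nonrecommended,
                            base.pct_energy_nonrecommended, rel_tol=1e-9)

    def test_zero_energy_day_is_flagged_invalid(self, config):
        foods, assignments, _ = self.toy_day(config)
        p = build_profile(respondent(), [item("t1", 100, 0)], foods, assignments)
        assert not p.valid and p.nutrient_density == {}


class TestCohortInvariants:
    def test_energy_conservation_and_tier_ordering_on_cohort(self, profiles2000):
        for p in profiles2000:
            assert sum(p.energy_by_tier.values()) == pytest.approx(
                p.total_energy_kcal, abs=0.1
            )
            for g in (FoodGroup.VEG_FRUIT, FoodGroup.GRAIN,
                      FoodGroup.MILK_ALT, FoodGroup.MEAT_ALT):
                assert p.servings_in_tiers(g, 3) <= p.servings_in_tiers(g, 4) + 1e-12

    def test_servings_additivity_matches_items(self, cohort2000, foods, assignments,
                                               profiles2000):
        respondents, items, _ = cohort2000
        rid = respondents[0].respondent_id
        own = [i for i in items if i.respondent_id == rid]
        by_id = {f.food_id: f for f in foods}
        total = 0.0
        for it in own:
            asg = assignments[it.food_id]
            if asg.tier is not Tier.NOT_RECOMMENDED:
                total += servings_of(it, by_id[it.food_id])
        p = profiles2000[0]
        assert sum(p.servings.values()) == pytest.approx(total)
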
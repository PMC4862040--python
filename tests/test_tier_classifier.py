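"""Rule-engine behaviour: threshold exceedances, the step-1 decision table
(checked against an independent brute-force oracle), step-2 adjustments, and
other-food categorization."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcst.config import Step2Rule
from hcst.food_model_io import (
    FoodGroup,
    FoodRecord,
    NutrientProfilePerRA,
    OtherCategory,
    ThresholdSet,
    Tier,
)
from hcst.tier_classifier import (
    apply_step2,
    categorize_other,
    classify,
    classify_step1,
    exceedances,
)

MAIN_GROUPS = [FoodGroup.VEG_FRUIT, FoodGroup.GRAIN, FoodGroup.MILK_ALT, FoodGroup.MEAT_ALT]


def oracle_tier(fat, satfat, sugars, sodium, group) -> int:
    """Independent transcription of the published tier rules, value by value."""
    n_lower = sum([fat > 3, sugars > 6, sodium > 140])
    up_fat, up_sug, up_sod, up_sat = fat > 10, sugars > 19, sodium > 360, satfat > 2
    if group in (FoodGroup.VEG_FRUIT, FoodGroup.GRAIN):
        n_upper = sum([up_fat, up_sug, up_sod, up_sat])
        if n_upper >= 2:
            return 4
        if n_upper == 1:
            return 3
        return {0: 1, 1: 2, 2: 2, 3: 3}[n_lower]
    n_upper3 = sum([up_fat, up_sug, up_sod])
    if n_upper3 >= 2:
        return 4
    if n_upper3 == 1:
        return 3
    if up_sat:
        return 3
    return {0: 1, 1: 2, 2: 2, 3: 3}[n_lower]


def profile(fat, satfat, sugars, sodium):
    return NutrientProfilePerRA(
        total_fat_g=fat, sat_fat_g=satfat, sugars_g=sugars, sodium_mg=sodium
    )


def make_food(group=FoodGroup.GRAIN, subgroup="whole_grains", flags=(), **prof):
    defaults = dict(fat=4, satfat=0.5, sugars=2, sodium=50)
    defaults.update(prof)
    return FoodRecord(
        food_id="f", food_group=group, subgroup=subgroup,
        profile=profile(**defaults), energy_kcal_per_100g=250,
        grams_per_RA=50, grams_per_serving=40, adjustment_flags=frozenset(flags),
    )


class TestExceedances:
    def test_boundary_values_do_not_exceed(self):
        lo, up = exceedances(profile(3.0, 2.0, 6.0, 140.0), ThresholdSet())
        assert lo == frozenset() and up == frozenset()

    def test_upper_fat_implies_lower_fat(self):
        lo, up = exceedances(profile(10.5, 0.5, 2, 100), ThresholdSet())
        assert lo == {"fat"} and up == {"fat"}

    def test_satfat_has_no_lower_threshold(self):
        lo, up = exceedances(profile(2.5, 2.5, 2, 50), ThresholdSet())
        assert lo == frozenset() and up == {"satfat"}


class TestStep1DecisionTable:
    @pytest.mark.parametrize(
        "group,prof,expected",
        [
            (FoodGroup.VEG_FRUIT, (0.2, 0.05, 4, 5), Tier.TIER1),
            (FoodGroup.GRAIN, (12, 1, 20, 100), Tier.TIER4),
            (FoodGroup.MILK_ALT, (8, 5, 12, 120), Tier.TIER3),
            (FoodGroup.MEAT_ALT, (15, 6, 1, 500), Tier.TIER4),
            (FoodGroup.VEG_FRUIT, (15, 6, 1, 100), Tier.TIER4),
            (FoodGroup.GRAIN, (4, 0.5, 7, 150), Tier.TIER3),  # all three lowers
            (FoodGroup.MEAT_ALT, (4, 0.5, 7, 150), Tier.TIER3),
            (FoodGroup.VEG_FRUIT, (4, 0.5, 2, 50), Tier.TIER2),
        ],
    )
    def test_worked_examples(self, group, prof, expected):
        assert classify_step1(profile(*prof), group).tier is expected

    def test_other_group_is_rejected(self):
        with pytest.raises(ValueError):
            classify_step1(profile(1, 0, 1, 1), FoodGroup.OTHER)

    def test_oracle_equivalence_on_boundary_grid(self):
        fat_grid = [0, 1, 2.9, 3, 3.1, 5, 9.9, 10, 10.1, 15]
        sugars_grid = [0, 5.9, 6, 6.1, 18.9, 19, 19.1, 25]
        sodium_grid = [0, 139, 140, 141, 359, 360, 361, 500]
        satfat_grid = [0, 1.9, 2, 2.1]
        n = 0
        for fat, sug, sod, sf in itertools.product(
            fat_grid, sugars_grid, sodium_grid, satfat_grid
        ):
            sf = min(sf, fat)
            p = profile(fat, sf, sug, sod)
            for group in MAIN_GROUPS:
                got = classify_step1(p, group).tier.number
                assert got == oracle_tier(fat, sf, sug, sod, group), (fat, sf, sug, sod, group)
                n += 1
        assert n >= 10_000


profiles_strategy = st.tuples(
    st.floats(0, 30), st.floats(0, 1), st.floats(0, 50), st.floats(0, 1000)
).map(lambda t: profile(t[0], t[0] * t[1], t[2], t[3]))


class TestStep1Properties:
    @settings(max_examples=300, derandomize=True)
    @given(p=profiles_strategy, group=st.sampled_from(MAIN_GROUPS))
    def test_exactly_one_tier_produced(self, p, group):
        asg = classify_step1(p, group)
        assert asg.tier in (Tier.TIER1, Tier.TIER2, Tier.TIER3, Tier.TIER4)

    @settings(max_examples=300, derandomize=True)
    @given(
        p=profiles_strategy,
        group=st.sampled_from(MAIN_GROUPS),
        nutrient=st.sampled_from(["total_fat_g", "sat_fat_g", "sugars_g", "sodium_mg"]),
        bump=st.floats(0.01, 30),
    )
    def test_monotone_in_each_nutrient(self, p, group, nutrient, bump):
        values = p.model_dump()
        values[nutrient] += bump
        if nutrient == "total_fat_g":
            pass
        elif nutrient == "sat_fat_g":
            values["total_fat_g"] = max(values["total_fat_g"], values["sat_fat_g"])
        bumped = NutrientProfilePerRA(**values)
        assert (
            classify_step1(bumped, group).tier.number
            >= classify_step1(p, group).tier.number
        )

    @settings(max_examples=300, derandomize=True)
    @given(p=profiles_strategy)
    def test_groups_agree_when_satfat_upper_not_exceeded(self, p):
        if p.sat_fat_g > 2:
            return
        tiers = {classify_step1(p, g).tier for g in MAIN_GROUPS}
        assert len(tiers) == 1

    @settings(max_examples=300, derandomize=True)
    @given(fat=st.floats(2.01, 10), sugars=st.floats(0, 19), sodium=st.floats(0, 360))
    def test_satfat_only_upper_is_tier3_in_all_groups(self, fat, sugars, sodium):
        p = profile(fat, min(fat, 2.01 + (fat - 2.01) / 2 + 0.001), sugars, sodium)
        if p.sat_fat_g <= 2:
            return
        for g in MAIN_GROUPS:
            assert classify_step1(p, g).tier is Tier.TIER3


WHOLE_GRAIN_RULE = Step2Rule(
    name="whole_grain_natural_oils",
    flag="whole_grain_natural_oils",
    from_tier=2,
    to_tier=1,
    requires_exceeded_lower=("fat",),
)


class TestStep2:
    def test_whole_grain_oil_rule_promotes_tier2_to_tier1(self):
        food = make_food(flags=["whole_grain_natural_oils"], fat=4, satfat=0.5)
        step1 = classify_step1(food.profile, food.food_group)
        assert step1.tier is Tier.TIER2 and "fat" in step1.exceeded_lower
        adjusted = apply_step2(step1, food, [WHOLE_GRAIN_RULE])
        assert adjusted.tier is Tier.TIER1
        assert adjusted.step2_rule_applied == "whole_grain_natural_oils"

    def test_rule_does_not_fire_from_tier3(self):
        food = make_food(flags=["whole_grain_natural_oils"], fat=4, sugars=7, sodium=150)
        step1 = classify_step1(food.profile, food.food_group)
        assert step1.tier is Tier.TIER3
        assert apply_step2(step1, food, [WHOLE_GRAIN_RULE]) == step1

    def test_no_flags_is_identity(self):
        food = make_food(fat=4)
        step1 = classify_step1(food.profile, food.food_group)
        assert apply_step2(step1, food, [WHOLE_GRAIN_RULE]) == step1


def other_food(subgroup, kcal100=50, water=False):
    return FoodRecord(
        food_id="o", food_group=FoodGroup.OTHER, subgroup=subgroup,
        profile=profile(0, 0, 5, 10), energy_kcal_per_100g=kcal100,
        grams_per_RA=250, grams_per_serving=250, is_beverage=True, is_water=water,
    )


CATEGORY_MAP = {
    "water": "WATER",
    "beverages": "BEVERAGE_SPLIT",
    "alcoholic_beverages": "ALCOHOLIC_BEVERAGE",
}


class TestOtherFoods:
    def test_beverage_at_cutoff_is_high_calorie(self):
        asg = categorize_other(other_food("beverages", 40.0), CATEGORY_MAP)
        assert asg.other_category is OtherCategory.HIGH_CAL_BEVERAGE

    def test_beverage_below_cutoff_is_low_calorie(self):
        asg = categorize_other(other_food("beverages", 39.9), CATEGORY_MAP)
        assert asg.other_category is OtherCategory.LOW_CAL_BEVERAGE

    def test_water_is_recommended(self):
        asg = categorize_other(other_food("water", 0, water=True), CATEGORY_MAP)
        assert asg.other_category is OtherCategory.WATER
        assert asg.recommended_other and not asg.is_nonrecommended_energy

    def test_unmapped_subgroup_falls_back_to_uncategorized(self):
        asg = categorize_other(other_food("mystery"), CATEGORY_MAP)
        assert asg.other_category is OtherCategory.UNCATEGORIZED


class TestClassifyComposition:
    def test_classify_is_deterministic_and_composes(self, foods, config):
        for food in foods[:40]:
            a1 = classify(food, config.thresholds, config.step2_rules,
                          config.other_category_map)
            a2 = classify(food, config.thresholds, config.step2_rules,
                          config.other_category_map)
            assert a1 == a2
            if food.food_group is not FoodGroup.OTHER:
                expected = apply_step2(
                    classify_step1(food.profile, food.food_group, config.thresholds),
                    food, config.step2_rules,
                )
                assert a1 == expected
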
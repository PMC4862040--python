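"""The HCST rule engine: threshold classification of foods into Tiers 1-4.

Step 1 places a food in a tier from its per-RA total fat, saturated fat,
sugars and sodium against a lower threshold triple (fat/sugars/sodium) and an
upper threshold quadruple (fat/sugars/sodium/saturated fat).  The Vegetables &
Fruits and Grain Products groups count a saturated-fat upper exceedance like
any other upper threshold; the Milk & Alternatives and Meat & Alternatives
groups — whose foods carry more intrinsic saturated fat — disregard saturated
fat for Tier 4 and demote a food to at most Tier 3 when saturated fat is its
only upper exceedance.

Step 2 applies declarative guidance adjustments (the shipped rule set moves
whole grains with naturally occurring oils from Tier 2 back to Tier 1 when
only the fat lower threshold is exceeded).

Foods outside the four main groups ("other" foods and beverages) are not
tiered but sorted into non-recommended categories, except water and
unsaturated fats/oils which the food guide recommends.
"""

from __future__ import annotations

import logging
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .config import Step2Rule
from .food_model_io import (
    RECOMMENDED_OTHER,
    FoodGroup,
    FoodRecord,
    NutrientProfilePerRA,
    OtherCategory,
    ThresholdSet,
    Tier,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TierAssignment",
    "exceedances",
    "classify_step1",
    "apply_step2",
    "categorize_other",
    "classify",
    "classify_foods",
]

#: Nutrients with a lower threshold.
LOWER_NUTRIENTS = ("fat", "sugars", "sodium")
#: Nutrients with an upper threshold.
UPPER_NUTRIENTS = ("fat", "sugars", "sodium", "satfat")


class TierAssignment(BaseModel):
    """Classification outcome with an audit trail of the thresholds that fired."""

    model_config = ConfigDict(frozen=True)

    tier: Tier
    other_category: Optional[OtherCategory] = None
    recommended_other: bool = False
    exceeded_lower: frozenset[str] = frozenset()
    exceeded_upper: frozenset[str] = frozenset()
    step2_rule_applied: Optional[str] = None

    @property
    def counts_toward_servings(self) -> bool:
        """Tier 1-3 foods provide EWCFG servings; Tier 4 and other foods do not."""
        return self.tier in (Tier.TIER1, Tier.TIER2, Tier.TIER3)

    @property
    def is_nonrecommended_energy(self) -> bool:
        """Whether the food's energy counts toward percent energy from
        Tier 4 plus non-recommended other foods (water and unsaturated
        oils are recommended and excluded)."""
        if self.tier is Tier.TIER4:
            return True
        return self.tier is Tier.NOT_RECOMMENDED and not self.recommended_other


def exceedances(
    profile: NutrientProfilePerRA, thresholds: ThresholdSet
) -> tuple[frozenset[str], frozenset[str]]:
    """Which lower and upper thresholds a profile strictly exceeds.

    A value exactly at a threshold does not exceed it.
    """
    lower = set()
    if profile.total_fat_g > thresholds.lower_fat_g:
        lower.add("fat")
    if profile.sugars_g > thresholds.lower_sugars_g:
        lower.add("sugars")
    if profile.sodium_mg > thresholds.lower_sodium_mg:
        lower.add("sodium")
    upper = set()
    if profile.total_fat_g > thresholds.upper_fat_g:
        upper.add("fat")
    if profile.sugars_g > thresholds.upper_sugars_g:
        upper.add("sugars")
    if profile.sodium_mg > thresholds.upper_sodium_mg:
        upper.add("sodium")
    if profile.sat_fat_g > thresholds.upper_satfat_g:
        upper.add("satfat")
    return frozenset(lower), frozenset(upper)


def classify_step1(
    profile: NutrientProfilePerRA,
    food_group: FoodGroup,
    thresholds: ThresholdSet | None = None,
) -> TierAssignment:
    """Step-1 threshold classification for a main-group food."""
    if food_group is FoodGroup.OTHER:
        raise ValueError("OTHER-group foods are categorized, not tiered; use categorize_other")
    thresholds = thresholds or ThresholdSet()
    lower, upper = exceedances(profile, thresholds)
    n_lower = len(lower)
    upper3 = upper - {"satfat"}
    satfat_upper = "satfat" in upper

    if food_group in (FoodGroup.VEG_FRUIT, FoodGroup.GRAIN):
        n_upper = len(upper)  # saturated fat counts like any other upper
        if n_upper >= 2:
            tier = Tier.TIER4
        elif n_upper == 1:
            tier = Tier.TIER3
        elif n_lower == 3:
            tier = Tier.TIER3
        elif n_lower >= 1:
            tier = Tier.TIER2
        else:
            tier = Tier.TIER1
    else:  # MILK_ALT, MEAT_ALT: saturated fat never counts toward Tier 4
        if len(upper3) >= 2:
            tier = Tier.TIER4
        elif len(upper3) == 1:
            tier = Tier.TIER3
        elif satfat_upper:
            tier = Tier.TIER3  # saturated fat is the only upper exceedance
        elif n_lower == 3:
            tier = Tier.TIER3
        elif n_lower >= 1:
            tier = Tier.TIER2
        else:
            tier = Tier.TIER1

    return TierAssignment(tier=tier, exceeded_lower=lower, exceeded_upper=upper)


def apply_step2(
    assignment: TierAssignment,
    food: FoodRecord,
    rules: tuple[Step2Rule, ...] | list[Step2Rule] = (),
) -> TierAssignment:
    """Apply configured guidance adjustments in declared order; first match wins."""
    if assignment.tier is Tier.NOT_RECOMMENDED:
        return assignment
    for rule in rules:
        if rule.flag not in food.adjustment_flags:
            continue
        if assignment.tier.number != rule.from_tier:
            continue
        if not set(rule.requires_exceeded_lower) <= set(assignment.exceeded_lower):
            continue
        return assignment.model_copy(
            update={"tier": Tier(f"TIER{rule.to_tier}"), "step2_rule_applied": rule.name}
        )
    return assignment


def categorize_other(
    food: FoodRecord,
    category_map: dict[str, str],
    beverage_cutoff_kcal_per_100g: float = 40.0,
) -> TierAssignment:
    """Sort an other-group food into its (non-)recommended category.

    Water and unsaturated fats/oils are recommended "other" foods; beverages
    split into high calorie (>= 40 kcal/100 g) and low calorie (< 40 kcal/100 g).
    """
    if food.food_group is not FoodGroup.OTHER:
        raise ValueError(f"food {food.food_id!r} is not an OTHER-group food")
    if food.is_water:
        cat = OtherCategory.WATER
    else:
        mapped = category_map.get(food.subgroup)
        if mapped is None:
            logger.warning(
                "food %r: OTHER subgroup %r has no category mapping; UNCATEGORIZED",
                food.food_id,
                food.subgroup,
            )
            cat = OtherCategory.UNCATEGORIZED
        elif mapped == "BEVERAGE_SPLIT":
            if food.energy_kcal_per_100g >= beverage_cutoff_kcal_per_100g:
                cat = OtherCategory.HIGH_CAL_BEVERAGE
            else:
                cat = OtherCategory.LOW_CAL_BEVERAGE
        else:
            cat = OtherCategory(mapped)
    return TierAssignment(
        tier=Tier.NOT_RECOMMENDED,
        other_category=cat,
        recommended_other=cat in RECOMMENDED_OTHER,
    )


def classify(
    food: FoodRecord,
    thresholds: ThresholdSet | None = None,
    rules: tuple[Step2Rule, ...] | list[Step2Rule] = (),
    category_map: dict[str, str] | None = None,
    beverage_cutoff_kcal_per_100g: float = 40.0,
) -> TierAssignment:
    """Full classification: step 1 + step 2 for main-group foods, categories otherwise."""
    if food.food_group is FoodGroup.OTHER:
        return categorize_other(food, category_map or {}, beverage_cutoff_kcal_per_100g)
    step1 = classify_step1(food.profile, food.food_group, thresholds)
    return apply_step2(step1, food, rules)


def classify_foods(foods: list[FoodRecord], config) -> dict[str, TierAssignment]:
    """Classify a whole food table under a :class:`~hcst.config.PipelineConfig`."""
    return {
        f.food_id: classify(
            f,
            thresholds=config.thresholds,
            rules=config.step2_rules,
            category_map=config.other_category_map,
            beverage_cutoff_kcal_per_100g=config.beverage_high_cal_kcal_per_100g,
        )
        for f in foods
    }
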
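"""Per-respondent dietary metrics from one day of recall items.

Aggregates a respondent's recall into: total energy intake (EI), EWCFG
servings by food group and tier, energy by tier and other-food category,
percent of energy from Tier 4 plus non-recommended other foods, nutrient
density per 1000 kcal (and percent of energy for macronutrients), dietary
glycemic index and load, energy density of foods excluding all beverages,
and BMI.

Macronutrient energy shares use Atwater factors: 9 kcal/g fat, 4 kcal/g
carbohydrate and protein, 7 kcal/g alcohol; added sugars at 4 kcal/g.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .config import GIConfig
from .food_model_io import FoodGroup, FoodRecord, OtherCategory, RecallItem, Respondent, Tier
from .tier_classifier import TierAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "RespondentProfile",
    "servings_of",
    "energy_density",
    "glycemic_load",
    "dietary_gi",
    "resolve_gi",
    "bmi",
    "build_profile",
    "PCT_ENERGY_FACTORS",
]

#: kcal per gram for percent-of-energy conversion, by recall nutrient column.
PCT_ENERGY_FACTORS: dict[str, float] = {
    "total_fat_g": 9.0,
    "sat_fat_g": 9.0,
    "mufa_g": 9.0,
    "pufa_g": 9.0,
    "carb_g": 4.0,
    "added_sugars_g": 4.0,
    "protein_g": 4.0,
    "alcohol_g": 7.0,
}


class RespondentProfile(BaseModel):
    model_config = ConfigDict(frozen=True)

    respondent_id: str
    total_energy_kcal: float
    servings: dict[tuple[FoodGroup, Tier], float]
    energy_by_tier: dict[str, float]
    pct_energy_nonrecommended: float
    nutrient_density: dict[str, float]  # nutrient -> amount per 1000 kcal
    pct_energy: dict[str, float]  # macronutrient -> % of EI
    mean_gi: Optional[float]
    glycemic_load: float
    energy_density_kcal_per_g: Optional[float]
    bmi_kg_m2: Optional[float]
    valid: bool = True  # False when EI = 0 (densities undefined)

    def servings_in_tiers(self, group: FoodGroup, max_tier: int) -> float:
        return sum(
            v
            for (g, t), v in self.servings.items()
            if g == group and t is not Tier.NOT_RECOMMENDED and t.number <= max_tier
        )


def servings_of(item: RecallItem, food: FoodRecord) -> float:
    """EWCFG servings contributed by one consumed item (fractional, unrounded)."""
    return item.amount_g / food.grams_per_serving


def energy_density(items: list[RecallItem], foods: dict[str, FoodRecord]) -> Optional[float]:
    """kcal per gram over foods only, excluding all beverages.

    Returns ``None`` (undefined) when the recall contains no non-beverage item.
    """
    kcal = 0.0
    grams = 0.0
    for it in items:
        if not foods[it.food_id].is_beverage:
            kcal += it.energy_kcal
            grams += it.amount_g
    if grams == 0:
        logger.warning("energy density undefined: no non-beverage items")
        return None
    return kcal / grams


def resolve_gi(food: FoodRecord, gi_config: GIConfig) -> float:
    """Glycemic index for a food: food value, else subgroup median, else default."""
    if food.gi_value is not None:
        return food.gi_value
    if food.subgroup in gi_config.subgroup_medians:
        return gi_config.subgroup_medians[food.subgroup]
    logger.warning(
        "food %r: no GI value or subgroup median; using default %s",
        food.food_id,
        gi_config.default,
    )
    return gi_config.default


def glycemic_load(gi_value: float, carb_g: float) -> float:
    """GL = GI x grams of carbohydrate / 100."""
    return gi_value * carb_g / 100.0


def dietary_gi(
    items: list[RecallItem], foods: dict[str, FoodRecord], gi_config: GIConfig
) -> tuple[Optional[float], float]:
    """(carbohydrate-weighted dietary GI, total daily glycemic load).

    Dietary GI is undefined (``None``) when no item carries carbohydrate.
    """
    gi_carb = 0.0
    carb = 0.0
    for it in items:
        c = it.nutrient_amounts.get("carb_g", 0.0)
        if c <= 0:
            continue
        gi = resolve_gi(foods[it.food_id], gi_config)
        gi_carb += gi * c
        carb += c
    if carb == 0:
        return None, 0.0
    return gi_carb / carb, gi_carb / 100.0


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight (kg) divided by height (m) squared."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / height_m**2


def build_profile(
    respondent: Respondent,
    items: list[RecallItem],
    foods: dict[str, FoodRecord],
    assignments: dict[str, TierAssignment],
    gi_config: GIConfig | None = None,
) -> RespondentProfile:
    """Aggregate one respondent-day into a :class:`RespondentProfile`.

    Energy is conserved exactly: the energies tallied under Tiers 1-4 and
    every other-food category sum to EI.
    """
    gi_config = gi_config or GIConfig()
    ei = sum(it.energy_kcal for it in items)

    servings: dict[tuple[FoodGroup, Tier], float] = {}
    energy_by: dict[str, float] = {}
    nonrec_energy = 0.0
    nutrient_totals: dict[str, float] = {}

    for it in items:
        food = foods[it.food_id]
        asg = assignments[it.food_id]
        if asg.tier is Tier.NOT_RECOMMENDED:
            key = asg.other_category.value
        else:
            key = asg.tier.value
            sk = (food.food_group, asg.tier)
            servings[sk] = servings.get(sk, 0.0) + servings_of(it, food)
        energy_by[key] = energy_by.get(key, 0.0) + it.energy_kcal
        if asg.is_nonrecommended_energy:
            nonrec_energy += it.energy_kcal
        for nut, amt in it.nutrient_amounts.items():
            nutrient_totals[nut] = nutrient_totals.get(nut, 0.0) + amt

    valid = ei > 0
    if not valid and items:
        logger.warning("respondent %r: zero energy intake; densities undefined",
                       respondent.respondent_id)
    density = {k: v * 1000.0 / ei for k, v in nutrient_totals.items()} if valid else {}
    pct_energy = (
        {k: 100.0 * nutrient_totals.get(k, 0.0) * f / ei for k, f in PCT_ENERGY_FACTORS.items()}
        if valid
        else {}
    )
    pct_nonrec = 100.0 * nonrec_energy / ei if valid else 0.0

    mean_gi, gl = dietary_gi(items, foods, gi_config)
    ed = energy_density(items, foods) if items else None
    bmi_val = (
        bmi(respondent.weight_kg, respondent.height_m)
        if respondent.weight_kg is not None and respondent.height_m is not None
        else None
    )

    profile = RespondentProfile(
        respondent_id=respondent.respondent_id,
        total_energy_kcal=ei,
        servings=servings,
        energy_by_tier=energy_by,
        pct_energy_nonrecommended=pct_nonrec,
        nutrient_density=density,
        pct_energy=pct_energy,
        mean_gi=mean_gi,
        glycemic_load=gl,
        energy_density_kcal_per_g=ed,
        bmi_kg_m2=bmi_val,
        valid=valid,
    )
    # energy conservation is structural; guard against float drift
    assert math.isclose(sum(energy_by.values()), ei, abs_tol=0.1)
    return profile
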
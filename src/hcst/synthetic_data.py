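"""Synthetic food tables, respondents and 24-hour recalls.

Emulates the structure the pipeline assumes of a children/adolescent dietary
survey: a multi-subgroup food composition table whose per-RA nutrient values
span all four tiers, respondents aged 2-18 of both sexes with anthropometry,
activity level and lognormal survey weights plus bootstrap replicate-weight
columns, and one recall day per respondent with realistic item counts.

Three pieces of planted structure provide ground truth for recovery tests:

* **Tier spans** — every main-group subgroup receives foods constructed
  inside each tier's threshold window, then verified by the classifier.
* **Consumption archetypes** — compliers, intermediates and non-compliers
  draw their target share of energy from Tier 4 + non-recommended foods from
  well-separated distributions, so quartile membership is predictable;
  because Tier 1-2 foods are generated fibre-, protein- and micronutrient-
  rich while Tier 4 and non-recommended foods are energy-dense, sugary and
  high-GI, the complier/non-complier nutrient-density contrasts emerge
  mechanically.
* **Misreporting mixture** — a planted fraction of respondents report energy
  at a fixed factor below/above their estimated requirement; the rest sit
  inside the plausibility band with mild lognormal noise.

All randomness flows from one integer seed; identical seeds give
byte-identical tables.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import PipelineConfig, default_config
from .energy_plausibility import eer
from .food_model_io import (
    NUTRIENT_COLUMNS,
    FoodGroup,
    FoodRecord,
    NutrientProfilePerRA,
    PALCategory,
    RecallItem,
    Respondent,
    Sex,
)
from .tier_classifier import Tier, classify, classify_step1

__all__ = ["CohortSpec", "DietSpec", "generate_foods", "generate_cohort"]


class CohortSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_respondents: int = Field(default=2000, ge=0)
    age_min: float = 2.0
    age_max: float = 19.0
    prop_male: float = Field(default=0.5, ge=0, le=1)
    pal_probs: dict[PALCategory, float] = {
        PALCategory.SEDENTARY: 0.25,
        PALCategory.LOW_ACTIVE: 0.35,
        PALCategory.MODERATELY_ACTIVE: 0.25,
        PALCategory.HIGHLY_ACTIVE: 0.15,
    }
    missing_anthropometry_frac: float = Field(default=0.03, ge=0, le=1)
    survey_weight_sigma: float = 0.5
    survey_weight_scale: float = 1000.0
    n_replicates: int = Field(default=50, ge=0)

    @model_validator(mode="after")
    def _probs(self) -> "CohortSpec":
        if abs(sum(self.pal_probs.values()) - 1.0) > 1e-9:
            raise ValueError("PAL probabilities must sum to 1")
        return self


class DietSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    foods_per_subgroup_tier: int = Field(default=2, ge=1)
    items_per_day_mean: float = 13.0
    # archetype mixture: P(complier), P(intermediate), P(non-complier)
    archetype_probs: tuple[float, float, float] = (0.25, 0.50, 0.25)
    # target share of energy from Tier 4 + non-recommended foods, (mean, sd)
    nonrec_share_complier: tuple[float, float] = (0.07, 0.03)
    nonrec_share_intermediate: tuple[float, float] = (0.30, 0.06)
    nonrec_share_noncomplier: tuple[float, float] = (0.60, 0.06)
    # reported-EI-to-EER ratio centre per archetype (plausible reporters)
    ei_ratio_complier: float = 0.95
    ei_ratio_intermediate: float = 1.00
    ei_ratio_noncomplier: float = 1.05
    ei_ratio_sigma: float = 0.08
    # misreporting mixture
    under_frac: float = Field(default=0.10, ge=0, le=1)
    over_frac: float = Field(default=0.10, ge=0, le=1)
    under_factor: float = 0.6
    over_factor: float = 1.6

    @model_validator(mode="after")
    def _probs(self) -> "DietSpec":
        if abs(sum(self.archetype_probs) - 1.0) > 1e-9:
            raise ValueError("archetype probabilities must sum to 1")
        if self.under_frac + self.over_frac > 1:
            raise ValueError("misreporting fractions exceed 1")
        return self


# --- per-subgroup bases: (grams/RA, grams/serving, carb beyond sugars g/RA,
#     protein g/RA, fibre g/RA, added-sugar fraction of sugars, is_beverage)
_SUBGROUP_BASE: dict[str, tuple[float, float, float, float, float, float, bool]] = {
    "fruit": (140, 120, 12, 0.8, 2.2, 0.0, False),
    "fruit_juice": (250, 125, 2, 0.5, 0.3, 0.1, True),
    "vegetable_juice": (250, 125, 6, 1.5, 1.2, 0.0, True),
    "potatoes": (140, 125, 20, 2.5, 2.0, 0.0, False),
    "other_vegetables": (125, 125, 6, 2.0, 2.5, 0.0, False),
    "whole_grains": (75, 40, 22, 4.0, 3.5, 0.15, False),
    "non_whole_enriched_grains": (75, 40, 24, 3.5, 1.0, 0.2, False),
    "breakfast_cereals": (30, 30, 22, 2.5, 2.0, 0.5, False),
    "baked_goods_desserts": (55, 45, 28, 3.0, 1.0, 0.7, False),
    "pasta_rice_other_grains": (140, 75, 30, 4.5, 1.5, 0.05, False),
    "fluid_milk_fortified_soy": (250, 250, 12, 8.0, 0.0, 0.1, True),
    "cheese": (30, 50, 1, 7.0, 0.0, 0.0, False),
    "yogurt_fermented": (175, 175, 10, 6.0, 0.0, 0.4, False),
    "frozen_dairy_desserts": (125, 125, 18, 3.0, 0.2, 0.8, False),
    "other_milk_products": (125, 125, 8, 4.0, 0.0, 0.3, False),
    "beef_game_organ_meat": (90, 75, 0.5, 20.0, 0.0, 0.0, False),
    "poultry": (90, 75, 0.5, 21.0, 0.0, 0.0, False),
    "fish_shellfish": (90, 75, 0.5, 19.0, 0.0, 0.0, False),
    "processed_meats": (55, 75, 2, 10.0, 0.0, 0.1, False),
    "eggs": (50, 100, 0.6, 6.5, 0.0, 0.0, False),
    "legumes": (175, 175, 20, 9.0, 6.0, 0.0, False),
}

#: micronutrient targets per 1000 kcal at neutral quality
_MICRO_BASE: dict[str, float] = {
    "vit_a_re": 300.0,
    "vit_d_ug": 3.0,
    "thiamin_mg": 0.9,
    "riboflavin_mg": 1.1,
    "niacin_ne": 16.0,
    "vit_b6_mg": 0.8,
    "folate_ug": 95.0,
    "vit_b12_ug": 1.9,
    "vit_c_mg": 75.0,
    "calcium_mg": 550.0,
    "phosphorus_mg": 650.0,
    "potassium_mg": 1350.0,
    "magnesium_mg": 135.0,
    "iron_mg": 6.8,
    "zinc_mg": 5.0,
}

_TIER_QUALITY = {1: 1.45, 2: 1.1, 3: 0.85, 4: 0.55}
_TIER_ADDED_SUGAR = {1: 0.3, 2: 0.6, 3: 1.0, 4: 1.3}
_TIER_FIBRE = {1: 1.35, 2: 1.2, 3: 0.9, 4: 0.65}
_TIER_PROTEIN = {1: 1.25, 2: 1.1, 3: 0.95, 4: 0.8}


def _tier_profile(tier: int, group: FoodGroup, thr, rng: np.random.Generator) -> NutrientProfilePerRA:
    """Sample a per-RA fat/satfat/sugars/sodium profile inside a tier's window."""
    lf, ls, lna = thr.lower_fat_g, thr.lower_sugars_g, thr.lower_sodium_mg
    uf, us, una = thr.upper_fat_g, thr.upper_sugars_g, thr.upper_sodium_mg

    def below_lower():
        return (
            rng.uniform(0, lf * 0.93),
            rng.uniform(0, ls * 0.93),
            rng.uniform(0, lna * 0.93),
        )

    if tier == 1:
        fat, sug, sod = below_lower()
        satfat = rng.uniform(0, min(thr.upper_satfat_g * 0.9, fat))
    elif tier == 2:
        fat, sug, sod = below_lower()
        which = rng.choice(3, size=rng.integers(1, 3), replace=False)
        if 0 in which:
            fat = rng.uniform(lf * 1.06, uf * 0.95)
        if 1 in which:
            sug = rng.uniform(ls * 1.06, us * 0.95)
        if 2 in which:
            sod = rng.uniform(lna * 1.06, una * 0.95)
        satfat = rng.uniform(0, min(thr.upper_satfat_g * 0.9, fat))
    elif tier == 3:
        route = rng.integers(0, 3)
        if route == 0:  # all three lowers, no uppers
            fat = rng.uniform(lf * 1.06, uf * 0.95)
            sug = rng.uniform(ls * 1.06, us * 0.95)
            sod = rng.uniform(lna * 1.06, una * 0.95)
            satfat = rng.uniform(0, min(thr.upper_satfat_g * 0.9, fat))
        elif route == 1:  # saturated fat is the only upper exceedance
            satfat = rng.uniform(thr.upper_satfat_g * 1.1, thr.upper_satfat_g * 2.2)
            fat = rng.uniform(satfat, uf * 0.95)
            sug = rng.uniform(0, ls * 0.93)
            sod = rng.uniform(0, lna * 0.93)
        else:  # exactly one non-satfat upper
            fat, sug, sod = below_lower()
            pick = rng.integers(0, 3)
            if pick == 0:
                fat = rng.uniform(uf * 1.05, uf * 2.2)
            elif pick == 1:
                sug = rng.uniform(us * 1.05, us * 2.0)
            else:
                sod = rng.uniform(una * 1.05, una * 2.2)
            satfat = rng.uniform(0, min(thr.upper_satfat_g * 0.9, fat))
    else:  # tier 4: two or three uppers among fat/sugars/sodium (valid in all groups)
        fat, sug, sod = below_lower()
        which = rng.choice(3, size=rng.integers(2, 4), replace=False)
        if 0 in which:
            fat = rng.uniform(uf * 1.05, uf * 2.5)
        if 1 in which:
            sug = rng.uniform(us * 1.05, us * 2.2)
        if 2 in which:
            sod = rng.uniform(una * 1.05, una * 2.5)
        satfat = rng.uniform(0, min(thr.upper_satfat_g * 0.9, fat))

    return NutrientProfilePerRA(
        total_fat_g=round(fat, 3),
        sat_fat_g=round(min(satfat, fat), 3),
        sugars_g=round(sug, 3),
        sodium_mg=round(sod, 2),
    )


def _macro_energy(fat_g, carb_g, protein_g, alcohol_g=0.0) -> float:
    return 9.0 * fat_g + 4.0 * carb_g + 4.0 * protein_g + 7.0 * alcohol_g


def _food_universe(
    diet_spec: DietSpec, config: PipelineConfig, rng: np.random.Generator
) -> tuple[list[FoodRecord], dict[str, dict[str, float]], dict[str, int]]:
    """Build foods plus their per-100 g nutrient vectors and intended tiers.

    Returns (records, per-100g nutrients by food_id, intended tier number by
    food_id with 0 for other-group foods).
    """
    thr = config.thresholds
    foods: list[FoodRecord] = []
    per100: dict[str, dict[str, float]] = {}
    intended: dict[str, int] = {}

    def add_food(fid, group, subgroup, profile, grams_ra, grams_serv, carb_ra, prot_ra,
                 fibre_ra, added_ra, alcohol_ra, is_bev, is_water, quality, gi, flags=()):
        energy_ra = _macro_energy(profile.total_fat_g, carb_ra, prot_ra, alcohol_ra)
        scale = 100.0 / grams_ra
        nut = {c: 0.0 for c in NUTRIENT_COLUMNS}
        fat100 = profile.total_fat_g * scale
        sat100 = profile.sat_fat_g * scale
        nut["total_fat_g"] = fat100
        nut["sat_fat_g"] = sat100
        mufa = max(fat100 - sat100, 0.0) * 0.6
        nut["mufa_g"] = mufa
        nut["pufa_g"] = max(fat100 - sat100 - mufa, 0.0)
        nut["carb_g"] = carb_ra * scale
        nut["added_sugars_g"] = added_ra * scale
        nut["protein_g"] = prot_ra * scale
        nut["fibre_g"] = fibre_ra * scale
        nut["alcohol_g"] = alcohol_ra * scale
        nut["sodium_mg"] = profile.sodium_mg * scale
        energy100 = energy_ra * scale
        for micro, base in _MICRO_BASE.items():
            nut[micro] = base * quality * (energy100 / 1000.0) * rng.uniform(0.7, 1.3)
        rec = FoodRecord(
            food_id=fid,
            description=fid.replace("_", " "),
            food_group=group,
            subgroup=subgroup,
            profile=profile,
            energy_kcal_per_100g=round(energy100, 4),
            grams_per_RA=round(grams_ra, 2),
            grams_per_serving=round(grams_serv, 2),
            carb_g_per_100g=round(nut["carb_g"], 4),
            is_beverage=is_bev,
            is_water=is_water,
            adjustment_flags=frozenset(flags),
            gi_value=gi,
        )
        foods.append(rec)
        per100[fid] = nut
        return rec

    # ---- main-group foods: every subgroup spans all four tiers
    for group_name, subgroups in config.taxonomy.items():
        group = FoodGroup(group_name)
        if group is FoodGroup.OTHER:
            continue
        for subgroup in subgroups:
            base = _SUBGROUP_BASE[subgroup]
            g_ra, g_serv, carb_x, prot, fibre, add_frac, is_bev = base
            for tier in (1, 2, 3, 4):
                for k in range(diet_spec.foods_per_subgroup_tier):
                    profile = _tier_profile(tier, group, thr, rng)
                    got = classify_step1(profile, group, thr).tier.number
                    if got != tier:
                        raise RuntimeError(
                            f"tier construction failed for {subgroup}: wanted {tier}, got {got}"
                        )
                    carb_ra = profile.sugars_g + carb_x * rng.uniform(0.7, 1.3)
                    prot_ra = prot * _TIER_PROTEIN[tier] * rng.uniform(0.8, 1.2)
                    fibre_ra = min(
                        fibre * _TIER_FIBRE[tier] * rng.uniform(0.8, 1.2), carb_ra
                    )
                    added_ra = min(add_frac * _TIER_ADDED_SUGAR[tier], 0.95) * profile.sugars_g
                    gi_med = config.gi.subgroup_medians.get(subgroup, config.gi.default)
                    gi = None
                    if carb_ra > 1 and rng.random() < 0.85:
                        gi = float(np.clip(rng.normal(gi_med + 5.0 * (tier - 2.5), 4), 0, 130))
                    flags = ()
                    if subgroup == "whole_grains" and tier == 2:
                        # some whole grains owe their fat to naturally occurring oils
                        if rng.random() < 0.5 and "fat" in classify_step1(
                            profile, group, thr
                        ).exceeded_lower:
                            flags = ("whole_grain_natural_oils",)
                    fid = f"{subgroup}_t{tier}_{k}"
                    add_food(
                        fid, group, subgroup, profile, g_ra * rng.uniform(0.9, 1.1),
                        g_serv * rng.uniform(0.9, 1.1), carb_ra, prot_ra, fibre_ra,
                        added_ra, 0.0, is_bev, False, _TIER_QUALITY[tier], gi, flags,
                    )
                    intended[fid] = tier

    # ---- other-group foods and beverages
    def other(fid, subgroup, fat, satfat, sug, sod, g_ra, carb_x, prot, alcohol,
              is_bev, is_water, quality, gi=None, added_frac=0.0):
        profile = NutrientProfilePerRA(
            total_fat_g=fat, sat_fat_g=min(satfat, fat), sugars_g=sug, sodium_mg=sod
        )
        carb_ra = sug + carb_x
        add_food(
            fid, FoodGroup.OTHER, subgroup, profile, g_ra, g_ra, carb_ra, prot,
            0.0, added_frac * sug, alcohol, is_bev, is_water, quality, gi,
        )
        intended[fid] = 0

    other("water_0", "water", 0, 0, 0, 2, 250, 0, 0, 0, True, True, 0.0)
    for i in range(2):
        fat = rng.uniform(11, 14)
        other(f"unsat_oil_{i}", "unsaturated_fats_oils", fat, fat * 0.12, 0, 0,
              14, 0, 0, 0, False, False, 0.1)
    for i in range(2):
        fat = rng.uniform(10, 13)
        other(f"sat_fat_oil_{i}", "saturated_trans_fats_oils", fat, fat * 0.65, 0.3,
              rng.uniform(60, 110), 14, 0, 0.1, 0, False, False, 0.2)
    for i in range(4):
        other(f"hf_sugar_{i}", "high_fat_sugar_foods", rng.uniform(6, 18),
              rng.uniform(3, 6), rng.uniform(18, 35), rng.uniform(40, 180),
              rng.uniform(40, 70), rng.uniform(4, 12), rng.uniform(1, 3), 0,
              False, False, 0.4, gi=float(rng.normal(68, 4)), added_frac=0.85)
    for i in range(3):  # sugar-sweetened beverages: >= 40 kcal/100 g
        sug100 = rng.uniform(10.5, 13.5)
        g_ra = 250.0
        other(f"bev_high_{i}", "beverages", 0, 0, sug100 * g_ra / 100, rng.uniform(5, 40),
              g_ra, 0.3, 0, 0, True, False, 0.35, gi=float(rng.normal(65, 3)),
              added_frac=0.9)
    for i in range(2):  # diet drinks: < 40 kcal/100 g
        sug100 = rng.uniform(0.2, 1.8)
        g_ra = 250.0
        other(f"bev_low_{i}", "beverages", 0, 0, sug100 * g_ra / 100, rng.uniform(5, 40),
              g_ra, 0.2, 0, 0, True, False, 0.35, added_frac=0.9)
    for i in range(2):
        other(f"alcohol_{i}", "alcoholic_beverages", 0, 0, rng.uniform(0, 4),
              rng.uniform(5, 25), 350, rng.uniform(3, 10), 0.5, rng.uniform(11, 15),
              True, False, 0.2)
    other("meal_replacement_0", "meal_replacements", 5, 1.5, 12, 150, 60, 14, 10, 0,
          False, False, 0.8, added_frac=0.6)
    other("supplement_0", "supplements", 0.2, 0.05, 1.5, 5, 10, 1, 0.5, 0,
          False, False, 1.0)
    for i in range(2):
        other(f"uncategorized_{i}", "uncategorized", rng.uniform(0.5, 3),
              rng.uniform(0.1, 1), rng.uniform(1, 5), rng.uniform(300, 900),
              20, rng.uniform(3, 8), rng.uniform(0.5, 2), 0, False, False, 0.3)

    return foods, per100, intended


def generate_foods(
    diet_spec: DietSpec | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> list[FoodRecord]:
    """Deterministic food composition table spanning all tiers in every subgroup."""
    diet_spec = diet_spec or DietSpec()
    config = config or default_config()
    rng = np.random.default_rng([int(seed) % 2**31, 1])
    foods, _, intended = _food_universe(diet_spec, config, rng)
    # validate: intended tier is recoverable from the classifier
    assignments = {f.food_id: classify(
        f, thresholds=config.thresholds, rules=config.step2_rules,
        category_map=config.other_category_map,
        beverage_cutoff_kcal_per_100g=config.beverage_high_cal_kcal_per_100g,
    ) for f in foods}
    for f in foods:
        want = intended[f.food_id]
        asg = assignments[f.food_id]
        if want == 0:
            if asg.tier is not Tier.NOT_RECOMMENDED:
                raise RuntimeError(f"{f.food_id}: expected other-category food")
        elif asg.step2_rule_applied is None and asg.tier.number != want:
            raise RuntimeError(f"{f.food_id}: classified {asg.tier}, intended tier {want}")
    return foods


_ARCHETYPES = ("COMPLIER", "INTERMEDIATE", "NON_COMPLIER")


def _heights_weights(ages, sexes, rng):
    male = sexes == 0
    target = np.where(male, 1.76, 1.63)
    h = 0.87 + (ages - 2.0) * (target - 0.87) / 17.0 + rng.normal(0, 0.04, ages.size)
    h = np.clip(h, 0.8, 2.0)
    bmi = np.clip(rng.normal(15.5 + 0.25 * ages, 1.6), 12.0, None)
    w = bmi * h**2
    return np.round(h, 3), np.round(w, 2)


def generate_cohort(
    cohort_spec: CohortSpec | None = None,
    diet_spec: DietSpec | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> tuple[list[Respondent], list[RecallItem], "pd.DataFrame"]:
    """Generate (respondents, recalls, ground-truth table) for one survey day.

    The third element records each respondent's hidden archetype and planted
    misreporting class for recovery tests; it is not an input to the pipeline.
    """
    import pandas as pd

    cohort_spec = cohort_spec or CohortSpec()
    diet_spec = diet_spec or DietSpec()
    config = config or default_config()
    n = cohort_spec.n_respondents
    if n == 0:
        return [], [], pd.DataFrame(columns=["respondent_id", "archetype", "misreport"])

    food_rng = np.random.default_rng([int(seed) % 2**31, 1])
    foods, per100, _ = _food_universe(diet_spec, config, food_rng)
    assignments = {f.food_id: classify(
        f, thresholds=config.thresholds, rules=config.step2_rules,
        category_map=config.other_category_map,
        beverage_cutoff_kcal_per_100g=config.beverage_high_cal_kcal_per_100g,
    ) for f in foods}
    by_id = {f.food_id: f for f in foods}

    rec_pool = [f.food_id for f in foods
                if assignments[f.food_id].counts_toward_servings
                or assignments[f.food_id].recommended_other]
    rec_pool_food = [fid for fid in rec_pool if by_id[fid].energy_kcal_per_100g > 0]
    nonrec_pool = [f.food_id for f in foods
                   if assignments[f.food_id].is_nonrecommended_energy]
    nonrec_no_alcohol = [fid for fid in nonrec_pool
                         if by_id[fid].subgroup != "alcoholic_beverages"]

    rng = np.random.default_rng([int(seed) % 2**31, 2])
    ages = rng.uniform(cohort_spec.age_min, cohort_spec.age_max, n)
    sexes = (rng.random(n) >= cohort_spec.prop_male).astype(int)  # 0 = M, 1 = F
    heights, weights = _heights_weights(ages, sexes, rng)
    missing = rng.random(n) < cohort_spec.missing_anthropometry_frac
    pal_cats = list(cohort_spec.pal_probs)
    pal_p = np.array([cohort_spec.pal_probs[c] for c in pal_cats])
    pal_idx = rng.choice(len(pal_cats), size=n, p=pal_p)
    sw = np.exp(rng.normal(0, cohort_spec.survey_weight_sigma, n)) * cohort_spec.survey_weight_scale
    B = cohort_spec.n_replicates
    rep = np.empty((n, B))
    for b in range(B):
        counts = rng.multinomial(n, np.full(n, 1.0 / n))
        rep[:, b] = sw * counts

    arch_idx = rng.choice(3, size=n, p=np.asarray(diet_spec.archetype_probs))
    share_params = {
        0: diet_spec.nonrec_share_complier,
        1: diet_spec.nonrec_share_intermediate,
        2: diet_spec.nonrec_share_noncomplier,
    }
    ratio_centre = {
        0: diet_spec.ei_ratio_complier,
        1: diet_spec.ei_ratio_intermediate,
        2: diet_spec.ei_ratio_noncomplier,
    }
    mis_draw = rng.random(n)
    mis_class = np.where(
        mis_draw < diet_spec.under_frac, "UNDER",
        np.where(mis_draw < diet_spec.under_frac + diet_spec.over_frac, "OVER", "PLAUSIBLE"),
    )

    respondents: list[Respondent] = []
    items: list[RecallItem] = []
    truth_rows = []
    for i in range(n):
        rid = f"R{i:05d}"
        sex = Sex.M if sexes[i] == 0 else Sex.F
        pal = None if ages[i] < 6 else pal_cats[pal_idx[i]]
        resp = Respondent(
            respondent_id=rid,
            age_years=round(float(ages[i]), 2),
            sex=sex,
            weight_kg=None if missing[i] else float(weights[i]),
            height_m=None if missing[i] else float(heights[i]),
            pal=pal,
            survey_weight=round(float(sw[i]), 4),
            replicate_weights=tuple(np.round(rep[i], 4)),
        )
        respondents.append(resp)

        mean, sd = share_params[arch_idx[i]]
        s = float(np.clip(rng.normal(mean, sd), 0.005, 0.95))
        n_items = 1 + rng.poisson(max(diet_spec.items_per_day_mean - 1, 0))
        n_nonrec = int(np.clip(round(s * n_items), 1, n_items - 1))
        n_rec = n_items - n_nonrec
        pool_nr = nonrec_pool if ages[i] >= 14 else nonrec_no_alcohol
        chosen_rec = list(rng.choice(rec_pool_food, size=n_rec, replace=True))
        chosen_nr = list(rng.choice(pool_nr, size=n_nonrec, replace=True))

        portion = 0.6 + ages[i] / 14.0
        raw = []  # (food_id, amount_g, is_nonrec)
        for fid in chosen_rec:
            amt = by_id[fid].grams_per_serving * portion * float(rng.lognormal(0, 0.35))
            raw.append((fid, amt, False))
        for fid in chosen_nr:
            amt = by_id[fid].grams_per_serving * portion * float(rng.lognormal(0, 0.35))
            raw.append((fid, amt, True))

        def energy(fid, amt):
            return by_id[fid].energy_kcal_per_100g * amt / 100.0

        e_rec = sum(energy(fid, a) for fid, a, nr in raw if not nr)
        e_nr = sum(energy(fid, a) for fid, a, nr in raw if nr)
        if e_nr > 0 and e_rec > 0:
            factor = (s / (1 - s)) * e_rec / e_nr
            raw = [(fid, a * factor if nr else a, nr) for fid, a, nr in raw]

        total = sum(energy(fid, a) for fid, a, _ in raw)
        req = eer(resp, config.eer)
        ref = req if req is not None else 1000.0 + 100.0 * ages[i]
        if mis_class[i] == "UNDER":
            ratio = diet_spec.under_factor
        elif mis_class[i] == "OVER":
            ratio = diet_spec.over_factor
        else:
            ratio = ratio_centre[arch_idx[i]] * float(
                np.exp(rng.normal(0, diet_spec.ei_ratio_sigma))
            )
        scale = (ref * ratio) / total if total > 0 else 1.0
        for fid, amt, _ in raw:
            amt *= scale
            nut100 = per100[fid]
            items.append(
                RecallItem(
                    respondent_id=rid,
                    food_id=fid,
                    amount_g=round(amt, 4),
                    energy_kcal=round(energy(fid, amt), 6),
                    nutrient_amounts={
                        c: round(nut100[c] * amt / 100.0, 6) for c in NUTRIENT_COLUMNS
                    },
                )
            )
        truth_rows.append(
            {"respondent_id": rid, "archetype": _ARCHETYPES[arch_idx[i]],
             "misreport": mis_class[i], "nonrec_share_target": s}
        )

    return respondents, items, pd.DataFrame(truth_rows)
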
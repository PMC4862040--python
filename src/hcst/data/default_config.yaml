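# Default configuration for the HCST tier-system pipeline.
#
# The 21-subgroup taxonomy for the four main food groups is a reconstruction
# from the subgroups the surveillance literature names (potatoes, fruit juice,
# whole grains, fluid milk & fortified soy beverages, legumes, eggs,
# beef/game/organ meat, poultry, processed meats, ...); the authoritative list
# lives in Health Canada's technical documentation and can be swapped in here
# without touching code.

thresholds:
  lower_fat_g: 3
  lower_sugars_g: 6
  lower_sodium_mg: 140
  upper_fat_g: 10
  upper_sugars_g: 19
  upper_sodium_mg: 360
  upper_satfat_g: 2

beverage_high_cal_kcal_per_100g: 40

taxonomy:
  VEG_FRUIT:
    - fruit
    - fruit_juice
    - vegetable_juice
    - potatoes
    - other_vegetables
  GRAIN:
    - whole_grains
    - non_whole_enriched_grains
    - breakfast_cereals
    - baked_goods_desserts
    - pasta_rice_other_grains
  MILK_ALT:
    - fluid_milk_fortified_soy
    - cheese
    - yogurt_fermented
    - frozen_dairy_desserts
    - other_milk_products
  MEAT_ALT:
    - beef_game_organ_meat
    - poultry
    - fish_shellfish
    - processed_meats
    - eggs
    - legumes
  OTHER:
    - water
    - unsaturated_fats_oils
    - saturated_trans_fats_oils
    - high_fat_sugar_foods
    - beverages
    - alcoholic_beverages
    - meal_replacements
    - supplements
    - uncategorized

# How OTHER-group subgroups map to the non-recommended food categories.
# "BEVERAGE_SPLIT" applies the 40 kcal/100 g high/low-calorie cutoff.
other_category_map:
  water: WATER
  unsaturated_fats_oils: UNSAT_FAT_OIL
  saturated_trans_fats_oils: SAT_TRANS_FAT_OIL
  high_fat_sugar_foods: HIGH_FAT_SUGAR_FOOD
  beverages: BEVERAGE_SPLIT
  alcoholic_beverages: ALCOHOLIC_BEVERAGE
  meal_replacements: MEAL_REPLACEMENT
  supplements: SUPPLEMENT
  uncategorized: UNCATEGORIZED

# Step-2 adjustments applied after threshold classification, in declared order.
# Only the published whole-grain natural-oils adjustment ships enabled.
step2_rules:
  - name: whole_grain_natural_oils
    flag: whole_grain_natural_oils
    from_tier: 2
    to_tier: 1
    requires_exceeded_lower: [fat]

misreport_cutoffs:
  age_split_years: 12
  under_pct_lt12: 74
  over_pct_lt12: 135
  under_pct_ge12: 70
  over_pct_ge12: 142

# IOM factorial estimated-energy-requirement equations (DRI, 2005).
# EER = intercept + age_coef*age + PA*(weight_coef*weight_kg + height_coef*height_m)
#       + growth_kcal ; the young-child form is PAL-free:
# EER = 89*weight_kg - 100 + growth_kcal.
eer:
  young_child:
    age_min: 2
    age_max: 3
    weight_coef: 89
    intercept: -100
    growth_kcal: 20
  bands:
    - sex: M
      age_min: 3
      age_max: 9
      intercept: 88.5
      age_coef: -61.9
      weight_coef: 26.7
      height_coef: 903
      growth_kcal: 20
      pa:
        SEDENTARY: 1.00
        LOW_ACTIVE: 1.13
        MODERATELY_ACTIVE: 1.26
        HIGHLY_ACTIVE: 1.42
    - sex: M
      age_min: 9
      age_max: 19
      intercept: 88.5
      age_coef: -61.9
      weight_coef: 26.7
      height_coef: 903
      growth_kcal: 25
      pa:
        SEDENTARY: 1.00
        LOW_ACTIVE: 1.13
        MODERATELY_ACTIVE: 1.26
        HIGHLY_ACTIVE: 1.42
    - sex: F
      age_min: 3
      age_max: 9
      intercept: 135.3
      age_coef: -30.8
      weight_coef: 10.0
      height_coef: 934
      growth_kcal: 20
      pa:
        SEDENTARY: 1.00
        LOW_ACTIVE: 1.16
        MODERATELY_ACTIVE: 1.31
        HIGHLY_ACTIVE: 1.56
    - sex: F
      age_min: 9
      age_max: 19
      intercept: 135.3
      age_coef: -30.8
      weight_coef: 10.0
      height_coef: 934
      growth_kcal: 25
      pa:
        SEDENTARY: 1.00
        LOW_ACTIVE: 1.16
        MODERATELY_ACTIVE: 1.31
        HIGHLY_ACTIVE: 1.56

# Glycemic-index assignment: food-level value if present, else the subgroup
# median below, else the global default (glucose = 100 scale).
gi:
  default: 55
  subgroup_medians:
    fruit: 50
    fruit_juice: 48
    vegetable_juice: 43
    potatoes: 78
    other_vegetables: 40
    whole_grains: 51
    non_whole_enriched_grains: 71
    breakfast_cereals: 74
    baked_goods_desserts: 62
    pasta_rice_other_grains: 55
    fluid_milk_fortified_soy: 31
    cheese: 27
    yogurt_fermented: 33
    frozen_dairy_desserts: 51
    other_milk_products: 40
    beef_game_organ_meat: 0
    poultry: 0
    fish_shellfish: 0
    processed_meats: 28
    eggs: 0
    legumes: 32
    water: 0
    unsaturated_fats_oils: 0
    saturated_trans_fats_oils: 0
    high_fat_sugar_foods: 65
    beverages: 60
    alcoholic_beverages: 61
    meal_replacements: 48
    supplements: 50
    uncategorized: 55

brr:
  n_replicates: 50
  fay_factor: 0.0

quantiles:
  weighted: true
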
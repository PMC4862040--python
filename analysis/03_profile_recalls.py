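"""Aggregate each respondent's recall day into dietary metrics.

Servings by food group and tier, energy by tier/other-category, percent of
energy from Tier 4 + non-recommended foods, nutrient densities, GI/GL,
energy density and BMI.  Verifies energy conservation before writing
results/profiles.csv.
"""

import numpy as np
import pandas as pd

from hcst.config import default_config
from hcst.food_model_io import read_food_table, read_recalls, read_respondents
from hcst.pipeline import build_profiles, _profiles_frame
from hcst.tier_classifier import classify_foods

config = default_config()
foods = read_food_table("results/data/foods.csv", config.taxonomy)
respondents = read_respondents("results/data/respondents.csv")
items = read_recalls("results/data/recalls.csv")
assignments = classify_foods(foods, config)

profiles = build_profiles(respondents, items, foods, assignments, config)
conserved = sum(
    abs(sum(p.energy_by_tier.values()) - p.total_energy_kcal) <= 0.1 for p in profiles
)
assert conserved == len(profiles), "energy accounting must balance per respondent"

df = _profiles_frame(profiles)
df.to_csv("results/profiles.csv", index=False)

pct = np.array([p.pct_energy_nonrecommended for p in profiles])
print(f"{len(profiles)} respondents profiled; energy conserved for all of them")
print(f"percent energy from Tier 4 + non-recommended foods: "
      f"mean {pct.mean():.1f}%, IQR {np.percentile(pct, 25):.1f}-{np.percentile(pct, 75):.1f}%")
print("profiles written to results/profiles.csv")
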
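"""Stratify respondents into compliance quartiles within age strata.

Quartiles of percent energy from Tier 4 + non-recommended foods are computed
separately for children (< 12 y) and adolescents (>= 12 y) using survey
weights; Q1 members are compliers, Q4 non-compliers.  Checks how well the
generator's planted archetypes are recovered by the quartile extremes.
"""

import pandas as pd

from hcst.config import default_config
from hcst.compliance_stratification import stratify
from hcst.food_model_io import read_food_table, read_recalls, read_respondents
from hcst.pipeline import build_profiles
from hcst.tier_classifier import classify_foods

config = default_config()
foods = read_food_table("results/data/foods.csv", config.taxonomy)
respondents = read_respondents("results/data/respondents.csv")
items = read_recalls("results/data/recalls.csv")
assignments = classify_foods(foods, config)
profiles = build_profiles(respondents, items, foods, assignments, config)

results, cutpoints = stratify(profiles, respondents, weighted=config.quantiles.weighted)
df = pd.DataFrame([{
    "respondent_id": c.respondent_id,
    "pct_energy_nonrecommended": round(c.pct_energy_nonrecommended, 4),
    "quartile": c.quartile.value,
    "label": c.label.value,
    "stratum": c.stratum.value,
} for c in results])
df.to_csv("results/compliance.csv", index=False)

for stratum, (q25, q50, q75) in cutpoints.items():
    print(f"{stratum.value}: complier <= {q25:.2f}% energy; "
          f"intermediate {q25:.2f}-{q75:.2f}%; non-complier > {q75:.2f}%")

truth = pd.read_csv("results/data/truth.csv")
m = df.merge(truth, on="respondent_id")
q1 = m[m.quartile == "Q1"]; q4 = m[m.quartile == "Q4"]
print(f"Q1 members who are planted compliers: {(q1.archetype == 'COMPLIER').mean():.1%}")
print(f"Q4 members who are planted non-compliers: "
      f"{(q4.archetype == 'NON_COMPLIER').mean():.1%}")
print("stratification written to results/compliance.csv")
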
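"""Generate the synthetic survey inputs: food table, respondents, recalls.

Writes foods.csv, respondents.csv, recalls.csv (pipeline inputs) and
truth.csv (hidden archetype/misreporting ground truth, used only to check
recovery in later steps) under results/data/.
"""

import sys
from pathlib import Path

from hcst.config import default_config
from hcst.food_model_io import write_food_table, write_recalls, write_respondents
from hcst.synthetic_data import CohortSpec, DietSpec, generate_cohort, generate_foods

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

config = default_config()
diet = DietSpec()
foods = generate_foods(diet, SEED, config)
respondents, items, truth = generate_cohort(CohortSpec(), diet, SEED, config)

write_food_table(foods, OUT / "foods.csv")
write_respondents(respondents, OUT / "respondents.csv")
write_recalls(items, OUT / "recalls.csv")
truth.to_csv(OUT / "truth.csv", index=False)

print(f"seed {SEED}: {len(foods)} foods across "
      f"{len({f.subgroup for f in foods})} subgroups, "
      f"{len(respondents)} respondents (ages 2-18), {len(items)} recall items")
print(f"inputs written to {OUT}/")
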
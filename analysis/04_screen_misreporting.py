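"""Screen reported energy intake against IOM estimated energy requirements.

Classifies each respondent as under-reporter (< 74 % / < 70 % of EER for
children / adolescents), plausible, or over-reporter (> 135 % / > 142 %),
with respondents missing anthropometry or activity level flagged ineligible.
Compares the recovered mixture against the generator's planted fractions.
"""

import pandas as pd

from hcst.config import default_config
from hcst.food_model_io import read_recalls, read_respondents
from hcst.energy_plausibility import screen_respondent

config = default_config()
respondents = read_respondents("results/data/respondents.csv")
items = read_recalls("results/data/recalls.csv")

ei = {r.respondent_id: 0.0 for r in respondents}
for it in items:
    ei[it.respondent_id] += it.energy_kcal

rows = []
for r in respondents:
    status, req = screen_respondent(r, ei[r.respondent_id], config.eer,
                                    config.misreport_cutoffs)
    rows.append({
        "respondent_id": r.respondent_id,
        "eer_kcal": None if req is None else round(req, 2),
        "ei_kcal": round(ei[r.respondent_id], 2),
        "ratio_pct": None if req is None else round(100 * ei[r.respondent_id] / req, 2),
        "status": status.value,
    })
df = pd.DataFrame(rows)
df.to_csv("results/status.csv", index=False)

truth = pd.read_csv("results/data/truth.csv")
merged = df.merge(truth, on="respondent_id")
eligible = merged[merged.status != "INELIGIBLE"]
print(df.status.value_counts().to_string())
for cls in ("UNDER", "OVER"):
    planted = (eligible.misreport == cls).mean()
    found = (eligible.status == cls).mean()
    print(f"{cls.lower()}-reporting: planted {planted:.1%}, recovered {found:.1%}")
print("screen written to results/status.csv")
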
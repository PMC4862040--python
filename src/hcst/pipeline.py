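"""Stage orchestration: simulate -> classify -> profile -> screen -> comply -> summarize.

Each stage reads/writes plain CSV so any step can be re-run or swapped for
real survey extracts with the same layouts.  Every output carries a
provenance comment header (package version, seed, config hash); readers in
:mod:`hcst.food_model_io` skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compliance_stratification import AgeStratum, Quartile, stratify
from .config import PipelineConfig, default_config
from .energy_plausibility import MisreportStatus, screen_respondent
from .food_model_io import (
    DRI_BANDS,
    FoodGroup,
    OtherCategory,
    Respondent,
    Tier,
    dri_group_label,
    recommended_servings,
    write_food_table,
    write_recalls,
    write_respondents,
)
from .recall_metrics import RespondentProfile, build_profile
from .survey_stats import trend_test, weighted_mean_sem
from .synthetic_data import CohortSpec, DietSpec, generate_cohort, generate_foods
from .tier_classifier import classify_foods

logger = logging.getLogger(__name__)

__all__ = ["run_all", "build_profiles", "summary_reports"]

_BAND_LABELS = [b[0] for b in DRI_BANDS]


def _write_with_provenance(df: pd.DataFrame, path: Path, seed: int, config_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# hcst {__version__} seed={seed} config={config_hash}\n")
        df.to_csv(fh, index=False)


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:12]


def build_profiles(respondents, items, foods, assignments, config) -> list[RespondentProfile]:
    by_resp: dict[str, list] = {r.respondent_id: [] for r in respondents}
    for it in items:
        by_resp[it.respondent_id].append(it)
    food_map = {f.food_id: f for f in foods}
    return [
        build_profile(r, by_resp[r.respondent_id], food_map, assignments, config.gi)
        for r in respondents
    ]


def _profiles_frame(profiles: list[RespondentProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "respondent_id": p.respondent_id,
            "total_energy_kcal": p.total_energy_kcal,
            "pct_energy_nonrecommended": p.pct_energy_nonrecommended,
            "mean_gi": p.mean_gi,
            "glycemic_load": p.glycemic_load,
            "energy_density_kcal_per_g": p.energy_density_kcal_per_g,
            "bmi_kg_m2": p.bmi_kg_m2,
        }
        for g in (FoodGroup.VEG_FRUIT, FoodGroup.GRAIN, FoodGroup.MILK_ALT, FoodGroup.MEAT_ALT):
            row[f"servings_{g.value}_tiers_1_3"] = p.servings_in_tiers(g, 3)
            row[f"servings_{g.value}_tiers_1_4"] = p.servings_in_tiers(g, 4)
        for key in [t.value for t in Tier if t is not Tier.NOT_RECOMMENDED] + [
            c.value for c in OtherCategory
        ]:
            row[f"energy_{key}"] = p.energy_by_tier.get(key, 0.0)
        for nut, dens in sorted(p.nutrient_density.items()):
            row[f"nd_{nut}"] = dens
        for macro, pct in sorted(p.pct_energy.items()):
            row[f"pe_{macro}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)


def _cell(values, idx, respondents_by_id, rids) -> tuple[float, float | None]:
    vals = np.asarray(values, dtype=float)[idx]
    resp = [respondents_by_id[r] for r in np.asarray(rids)[idx]]
    w = np.array([r.survey_weight for r in resp])
    rep = np.array([r.replicate_weights for r in resp])
    if vals.size == 0 or w.sum() == 0:
        return np.nan, np.nan
    s = weighted_mean_sem(vals, w, rep if rep.size else None)
    return s.mean, s.sem


def summary_reports(
    respondents: list[Respondent],
    profiles: list[RespondentProfile],
    statuses: dict[str, MisreportStatus],
    compliance,
) -> dict[str, pd.DataFrame]:
    """Report tables shaped after the published layouts.

    * ``servings_by_tier`` — servings/day from Tiers 1-3 and 1-4 per food
      group vs the EWCFG recommendation, by DRI age-sex band.
    * ``energy_by_tier`` — kcal/day from Tiers 1-3, Tier 4, and each
      other-food category, plus the percent of energy from non-recommended
      foods, by DRI band.
    * ``complier_characteristics`` — age, sex, BMI and misreporting mix
      across compliance quartiles, per age stratum, with trend p-values.
    * ``nutrient_density`` — energy, nutrient densities, GI/GL and energy
      density across quartiles, per age stratum, with adjusted trend p-values.
    """
    rid = [p.respondent_id for p in profiles]
    by_id = {r.respondent_id: r for r in respondents}
    bands = np.array([dri_group_label(by_id[r].age_years, by_id[r].sex) for r in rid])
    pf = _profiles_frame(profiles)

    # --- servings by tier vs recommendation
    rows = []
    for g in (FoodGroup.VEG_FRUIT, FoodGroup.GRAIN, FoodGroup.MILK_ALT, FoodGroup.MEAT_ALT):
        for measure in ("tiers_1_3", "tiers_1_4"):
            row = {"food_group": g.value, "measure": measure}
            col = f"servings_{g.value}_{measure}"
            for band in _BAND_LABELS:
                mean, sem = _cell(pf[col], bands == band, by_id, rid)
                row[f"{band}_mean"], row[f"{band}_sem"] = round(mean, 4), round(sem, 4)
            rows.append(row)
        row = {"food_group": g.value, "measure": "ewcfg_recommendation"}
        for band in _BAND_LABELS:
            age_mid = {"2-3": 3, "4-8": 6, "9-13_M": 11, "9-13_F": 11,
                       "14-18_M": 16, "14-18_F": 16}[band]
            sex = "F" if band.endswith("_F") else "M"
            lo, hi = recommended_servings(age_mid, sex)[g]
            row[f"{band}_mean"] = lo if lo == hi else f"{lo}-{hi}"
            row[f"{band}_sem"] = ""
        rows.append(row)
    servings_report = pd.DataFrame(rows)

    # --- energy by tier / other category
    energy_rows = []
    pf["energy_tiers_1_3"] = pf["energy_TIER1"] + pf["energy_TIER2"] + pf["energy_TIER3"]
    nonrec_cols = [f"energy_{c.value}" for c in OtherCategory
                   if c not in (OtherCategory.WATER, OtherCategory.UNSAT_FAT_OIL)]
    pf["energy_nonrecommended_total"] = pf["energy_TIER4"] + pf[nonrec_cols].sum(axis=1)
    variables = (
        [("Tiers 1+2+3", "energy_tiers_1_3"), ("Tier 4", "energy_TIER4")]
        + [(c.value, f"energy_{c.value}") for c in OtherCategory]
        + [("Total Tier 4 + other (kcal/day)", "energy_nonrecommended_total"),
           ("Total (% of energy)", "pct_energy_nonrecommended")]
    )
    for label, col in variables:
        row = {"variable": label}
        for band in _BAND_LABELS:
            mean, sem = _cell(pf[col], bands == band, by_id, rid)
            row[f"{band}_mean"], row[f"{band}_sem"] = round(mean, 4), round(sem, 4)
        energy_rows.append(row)
    energy_report = pd.DataFrame(energy_rows)

    # --- per-stratum quartile tables
    qmap = {c.respondent_id: c for c in compliance}
    qidx = np.array([int(qmap[r].quartile.value[1]) for r in rid])
    stratum = np.array([qmap[r].stratum.value for r in rid])
    ages = np.array([by_id[r].age_years for r in rid])
    sex_is_f = np.array([by_id[r].sex.value == "F" for r in rid], dtype=float)
    mis = np.array([statuses[r].value for r in rid])
    weights = np.array([by_id[r].survey_weight for r in rid])

    def quartile_table(var_cols: list[tuple[str, pd.Series]], mask) -> pd.DataFrame:
        out = []
        for label, series in var_cols:
            vals = np.asarray(series, dtype=float)
            row = {"variable": label}
            for q in (1, 2, 3, 4):
                sel = mask & (qidx == q) & ~np.isnan(vals)
                mean, sem = _cell(vals, sel, by_id, rid)
                row[f"Q{q}_mean"], row[f"Q{q}_sem"] = round(mean, 4), round(sem, 4)
            ok = mask & ~np.isnan(vals)
            if len(np.unique(qidx[ok])) > 1:
                cov = pd.DataFrame(
                    {"age": ages[ok], "sex": sex_is_f[ok], "misreport": mis[ok]}
                )
                tr = trend_test(vals[ok], qidx[ok], cov, weights=weights[ok])
                row["p_trend"] = float(f"{tr.p_trend:.4g}")
            else:
                row["p_trend"] = np.nan
            out.append(row)
        return pd.DataFrame(out)

    char_tables = []
    dens_tables = []
    for strat in (AgeStratum.CHILD, AgeStratum.ADOLESCENT):
        mask = stratum == strat.value
        if not mask.any():
            continue
        chars = [
            ("Age (years)", ages),
            ("Female (0/1)", sex_is_f),
            ("BMI (kg/m2)", pf["bmi_kg_m2"]),
            ("Under-reporter (0/1)", (mis == "UNDER").astype(float)),
            ("Plausible reporter (0/1)", (mis == "PLAUSIBLE").astype(float)),
            ("Over-reporter (0/1)", (mis == "OVER").astype(float)),
        ]
        t = quartile_table(chars, mask)
        t.insert(0, "stratum", strat.value)
        char_tables.append(t)

        dens = [("Energy (kcal/day)", pf["total_energy_kcal"])]
        for macro, label in [
            ("pe_total_fat_g", "Fat (%E)"), ("pe_sat_fat_g", "Saturated fat (%E)"),
            ("pe_mufa_g", "MUFA (%E)"), ("pe_pufa_g", "PUFA (%E)"),
            ("pe_carb_g", "Carbohydrate (%E)"), ("pe_added_sugars_g", "Added sugar (%E)"),
            ("pe_protein_g", "Protein (%E)"), ("pe_alcohol_g", "Alcohol (%E)"),
        ]:
            dens.append((label, pf[macro]))
        dens.append(("Fibre (g/1000 kcal)", pf["nd_fibre_g"]))
        for nut in ["vit_a_re", "vit_d_ug", "thiamin_mg", "riboflavin_mg", "niacin_ne",
                    "vit_b6_mg", "folate_ug", "vit_b12_ug", "vit_c_mg", "calcium_mg",
                    "phosphorus_mg", "potassium_mg", "sodium_mg", "magnesium_mg",
                    "iron_mg", "zinc_mg"]:
            dens.append((f"{nut} (/1000 kcal)", pf[f"nd_{nut}"]))
        dens += [("Glycemic index", pf["mean_gi"]), ("Glycemic load", pf["glycemic_load"]),
                 ("Energy density (kcal/g)", pf["energy_density_kcal_per_g"])]
        t = quartile_table(dens, mask)
        t.insert(0, "stratum", strat.value)
        dens_tables.append(t)

    return {
        "servings_by_tier": servings_report,
        "energy_by_tier": energy_report,
        "complier_characteristics": pd.concat(char_tables, ignore_index=True),
        "nutrient_density": pd.concat(dens_tables, ignore_index=True),
    }


def run_all(
    config: PipelineConfig | None = None,
    out_dir: str | Path = "results",
    seed: int = 0,
    cohort_spec: CohortSpec | None = None,
    diet_spec: DietSpec | None = None,
) -> dict[str, Path]:
    """Run the full pipeline on a synthetic cohort and write all outputs.

    Deterministic under (seed, config): rerunning writes byte-identical files.
    """
    config = config or default_config()
    cohort_spec = cohort_spec or CohortSpec()
    diet_spec = diet_spec or DietSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    paths: dict[str, Path] = {}

    foods = generate_foods(diet_spec, seed, config)
    respondents, items, truth = generate_cohort(cohort_spec, diet_spec, seed, config)
    logger.info("simulate: %d foods, %d respondents, %d recall items",
                len(foods), len(respondents), len(items))
    write_food_table(foods, out / "foods.csv")
    write_respondents(respondents, out / "respondents.csv")
    write_recalls(items, out / "recalls.csv")
    truth.to_csv(out / "truth.csv", index=False)
    paths.update({k: out / f"{k}.csv" for k in ("foods", "respondents", "recalls", "truth")})

    assignments = classify_foods(foods, config)
    tier_rows = [
        {
            "food_id": fid,
            "tier": a.tier.value,
            "other_category": "" if a.other_category is None else a.other_category.value,
            "recommended_other": a.recommended_other,
            "exceeded_lower": ";".join(sorted(a.exceeded_lower)),
            "exceeded_upper": ";".join(sorted(a.exceeded_upper)),
            "step2_rule_applied": a.step2_rule_applied or "",
        }
        for fid, a in assignments.items()
    ]
    _write_with_provenance(pd.DataFrame(tier_rows), out / "tiers.csv", seed, chash)
    paths["tiers"] = out / "tiers.csv"
    tier_counts = pd.Series([r["tier"] for r in tier_rows]).value_counts().to_dict()
    logger.info("classify: %s", tier_counts)

    profiles = build_profiles(respondents, items, foods, assignments, config)
    _write_with_provenance(_profiles_frame(profiles), out / "profiles.csv", seed, chash)
    paths["profiles"] = out / "profiles.csv"

    ei = {p.respondent_id: p.total_energy_kcal for p in profiles}
    statuses: dict[str, MisreportStatus] = {}
    status_rows = []
    for r in respondents:
        status, req = screen_respondent(r, ei[r.respondent_id], config.eer,
                                        config.misreport_cutoffs)
        statuses[r.respondent_id] = status
        status_rows.append({
            "respondent_id": r.respondent_id,
            "eer_kcal": "" if req is None else round(req, 2),
            "ei_kcal": round(ei[r.respondent_id], 2),
            "ratio_pct": "" if req is None else round(100 * ei[r.respondent_id] / req, 2),
            "status": status.value,
        })
    _write_with_provenance(pd.DataFrame(status_rows), out / "status.csv", seed, chash)
    paths["status"] = out / "status.csv"
    n_inel = sum(1 for s in statuses.values() if s is MisreportStatus.INELIGIBLE)
    logger.info("screen: %d respondents, %d ineligible", len(respondents), n_inel)

    compliance, cutpoints = stratify(profiles, respondents,
                                     weighted=config.quantiles.weighted)
    comp_rows = [{
        "respondent_id": c.respondent_id,
        "pct_energy_nonrecommended": round(c.pct_energy_nonrecommended, 4),
        "quartile": c.quartile.value,
        "label": c.label.value,
        "stratum": c.stratum.value,
    } for c in compliance]
    _write_with_provenance(pd.DataFrame(comp_rows), out / "compliance.csv", seed, chash)
    cut_rows = [{"stratum": s.value, "q25": round(c[0], 4), "q50": round(c[1], 4),
                 "q75": round(c[2], 4)} for s, c in cutpoints.items()]
    _write_with_provenance(pd.DataFrame(cut_rows), out / "cutpoints.csv", seed, chash)
    paths["compliance"] = out / "compliance.csv"
    paths["cutpoints"] = out / "cutpoints.csv"
    logger.info("comply: cutpoints %s", {s.value: c for s, c in cutpoints.items()})

    reports = summary_reports(respondents, profiles, statuses, compliance)
    for name, df in reports.items():
        path = out / f"report_{name}.csv"
        _write_with_provenance(df, path, seed, chash)
        paths[name] = path
    logger.info("summarize: wrote %d report tables", len(reports))
    return paths
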
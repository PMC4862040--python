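"""Domain types for foods, respondents and 24-hour-recall items, plus flat-file IO.

The tier system operates on nutrient amounts *per reference amount* (RA), the
regulated quantity of a food usually eaten in one sitting.  Serving accounting
uses grams per EWCFG (Eating Well with Canada's Food Guide) serving, which is a
different quantity.  Both are carried on :class:`FoodRecord`.

All tables are plain CSV/TSV (delimiter sniffed between comma and tab, UTF-8).
Lines starting with ``#`` are treated as provenance comments and skipped.
"""

from __future__ import annotations

import csv
import enum
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "FoodGroup",
    "Sex",
    "PALCategory",
    "Tier",
    "OtherCategory",
    "NutrientProfilePerRA",
    "ThresholdSet",
    "FoodRecord",
    "Respondent",
    "RecallItem",
    "NUTRIENT_COLUMNS",
    "read_food_table",
    "write_food_table",
    "read_respondents",
    "write_respondents",
    "read_recalls",
    "write_recalls",
    "recommended_servings",
    "dri_group_label",
    "DRI_BANDS",
]


class FoodGroup(str, enum.Enum):
    VEG_FRUIT = "VEG_FRUIT"
    GRAIN = "GRAIN"
    MILK_ALT = "MILK_ALT"
    MEAT_ALT = "MEAT_ALT"
    OTHER = "OTHER"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class PALCategory(str, enum.Enum):
    SEDENTARY = "SEDENTARY"
    LOW_ACTIVE = "LOW_ACTIVE"
    MODERATELY_ACTIVE = "MODERATELY_ACTIVE"
    HIGHLY_ACTIVE = "HIGHLY_ACTIVE"


class Tier(str, enum.Enum):
    """Ordinal healthfulness class; TIER1 healthiest, TIER4 not in line with guidance.

    ``NOT_RECOMMENDED`` marks "other" foods and beverages outside the four main
    food groups (they carry an :class:`OtherCategory` instead of a tier number).
    """

    TIER1 = "TIER1"
    TIER2 = "TIER2"
    TIER3 = "TIER3"
    TIER4 = "TIER4"
    NOT_RECOMMENDED = "NOT_RECOMMENDED"

    @property
    def number(self) -> int:
        if self is Tier.NOT_RECOMMENDED:
            raise ValueError("NOT_RECOMMENDED has no tier number")
        return int(self.value[-1])


class OtherCategory(str, enum.Enum):
    HIGH_FAT_SUGAR_FOOD = "HIGH_FAT_SUGAR_FOOD"
    SAT_TRANS_FAT_OIL = "SAT_TRANS_FAT_OIL"
    UNSAT_FAT_OIL = "UNSAT_FAT_OIL"
    HIGH_CAL_BEVERAGE = "HIGH_CAL_BEVERAGE"
    LOW_CAL_BEVERAGE = "LOW_CAL_BEVERAGE"
    MEAL_REPLACEMENT = "MEAL_REPLACEMENT"
    SUPPLEMENT = "SUPPLEMENT"
    ALCOHOLIC_BEVERAGE = "ALCOHOLIC_BEVERAGE"
    UNCATEGORIZED = "UNCATEGORIZED"
    WATER = "WATER"


#: "Other" categories that are nonetheless recommended in the food guide
#: (water and healthy vegetable oils); their energy is excluded from the
#: percent-energy-from-non-recommended-foods numerator.
RECOMMENDED_OTHER = frozenset({OtherCategory.WATER, OtherCategory.UNSAT_FAT_OIL})


class NutrientProfilePerRA(BaseModel):
    """Total fat, saturated fat, sugars and sodium per reference amount."""

    model_config = ConfigDict(frozen=True)

    total_fat_g: float = Field(ge=0)
    sat_fat_g: float = Field(ge=0)
    sugars_g: float = Field(ge=0)
    sodium_mg: float = Field(ge=0)

    @model_validator(mode="after")
    def _satfat_within_fat(self) -> "NutrientProfilePerRA":
        if self.sat_fat_g > self.total_fat_g:
            raise ValueError(
                f"sat_fat_g ({self.sat_fat_g}) exceeds total_fat_g ({self.total_fat_g})"
            )
        return self


class ThresholdSet(BaseModel):
    """Lower and upper per-RA thresholds for fat, sugars, sodium (+ upper sat fat).

    Defaults are the published surveillance-tool constants: lower 3 g fat /
    6 g sugars / 140 mg sodium, upper 10 g fat / 19 g sugars / 360 mg sodium /
    2 g saturated fat, all per reference amount.  "Exceed" is strict: a value
    exactly at a threshold does not exceed it.
    """

    model_config = ConfigDict(frozen=True)

    lower_fat_g: float = 3.0
    lower_sugars_g: float = 6.0
    lower_sodium_mg: float = 140.0
    upper_fat_g: float = 10.0
    upper_sugars_g: float = 19.0
    upper_sodium_mg: float = 360.0
    upper_satfat_g: float = 2.0

    @model_validator(mode="after")
    def _ordered(self) -> "ThresholdSet":
        for v in self.model_dump().values():
            if v <= 0:
                raise ValueError("all thresholds must be > 0")
        pairs = [
            ("fat", self.lower_fat_g, self.upper_fat_g),
            ("sugars", self.lower_sugars_g, self.upper_sugars_g),
            ("sodium", self.lower_sodium_mg, self.upper_sodium_mg),
        ]
        for name, lo, hi in pairs:
            if hi <= lo:
                raise ValueError(f"upper {name} threshold must exceed lower")
        return self


class FoodRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    food_id: str
    description: str = ""
    food_group: FoodGroup
    subgroup: str
    profile: NutrientProfilePerRA
    energy_kcal_per_100g: float = Field(ge=0)
    grams_per_RA: float = Field(gt=0)
    grams_per_serving: float = Field(gt=0)
    carb_g_per_100g: float = Field(ge=0, default=0.0)
    is_beverage: bool = False
    is_water: bool = False
    adjustment_flags: frozenset[str] = frozenset()
    gi_value: Optional[float] = None

    @field_validator("gi_value")
    @classmethod
    def _gi_range(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (0 <= v <= 150):
            raise ValueError(f"gi_value {v} outside [0, 150]")
        return v


class Respondent(BaseModel):
    model_config = ConfigDict(frozen=True)

    respondent_id: str
    age_years: float = Field(ge=2)
    sex: Sex
    weight_kg: Optional[float] = None
    height_m: Optional[float] = None
    pal: Optional[PALCategory] = None
    survey_weight: float = Field(ge=0)
    replicate_weights: tuple[float, ...] = ()

    @field_validator("age_years")
    @classmethod
    def _age_band(cls, v: float) -> float:
        if not (2 <= v < 19):
            raise ValueError(f"age_years {v} outside [2, 19)")
        return v

    @field_validator("weight_kg", "height_m")
    @classmethod
    def _positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("anthropometry must be positive")
        return v

    @field_validator("replicate_weights")
    @classmethod
    def _nonneg(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(w < 0 for w in v):
            raise ValueError("replicate weights must be nonnegative")
        return v

    @property
    def eer_eligible(self) -> bool:
        """Whether the IOM energy-requirement equation can be evaluated.

        Physical activity level is only required from age 6 up (it was not
        collected for younger children; the young-child / sedentary equation
        form covers them).
        """
        if self.weight_kg is None or self.height_m is None:
            return False
        if self.age_years >= 6 and self.pal is None:
            return False
        return True


#: Canonical recall nutrient columns (item-level amounts, native units).
NUTRIENT_COLUMNS: tuple[str, ...] = (
    "total_fat_g",
    "sat_fat_g",
    "mufa_g",
    "pufa_g",
    "carb_g",
    "added_sugars_g",
    "protein_g",
    "fibre_g",
    "alcohol_g",
    "sodium_mg",
    "vit_a_re",
    "vit_d_ug",
    "thiamin_mg",
    "riboflavin_mg",
    "niacin_ne",
    "vit_b6_mg",
    "folate_ug",
    "vit_b12_ug",
    "vit_c_mg",
    "calcium_mg",
    "phosphorus_mg",
    "potassium_mg",
    "magnesium_mg",
    "iron_mg",
    "zinc_mg",
)


class RecallItem(BaseModel):
    model_config = ConfigDict(frozen=True)

    respondent_id: str
    food_id: str
    amount_g: float = Field(gt=0)
    energy_kcal: float = Field(ge=0)
    nutrient_amounts: dict[str, float]

    @field_validator("nutrient_amounts")
    @classmethod
    def _nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for k, amt in v.items():
            if amt < 0:
                raise ValueError(f"nutrient {k} is negative")
        return v


# ---------------------------------------------------------------------------
# EWCFG recommended servings (food guide, 2007) by DRI age-sex band
# ---------------------------------------------------------------------------

#: DRI bands as half-open age intervals; sex ``None`` means both sexes share a row.
DRI_BANDS: tuple[tuple[str, float, float, Optional[Sex]], ...] = (
    ("2-3", 2.0, 4.0, None),
    ("4-8", 4.0, 9.0, None),
    ("9-13_M", 9.0, 14.0, Sex.M),
    ("9-13_F", 9.0, 14.0, Sex.F),
    ("14-18_M", 14.0, 19.0, Sex.M),
    ("14-18_F", 14.0, 19.0, Sex.F),
)

_EWCFG_SERVINGS: dict[str, dict[FoodGroup, tuple[float, float]]] = {
    "2-3": {
        FoodGroup.VEG_FRUIT: (4, 4),
        FoodGroup.GRAIN: (3, 3),
        FoodGroup.MILK_ALT: (2, 2),
        FoodGroup.MEAT_ALT: (1, 1),
    },
    "4-8": {
        FoodGroup.VEG_FRUIT: (5, 5),
        FoodGroup.GRAIN: (4, 4),
        FoodGroup.MILK_ALT: (2, 2),
        FoodGroup.MEAT_ALT: (1, 1),
    },
    "9-13_M": {
        FoodGroup.VEG_FRUIT: (6, 6),
        FoodGroup.GRAIN: (6, 6),
        FoodGroup.MILK_ALT: (3, 4),
        FoodGroup.MEAT_ALT: (1, 2),
    },
    "9-13_F": {
        FoodGroup.VEG_FRUIT: (6, 6),
        FoodGroup.GRAIN: (6, 6),
        FoodGroup.MILK_ALT: (3, 4),
        FoodGroup.MEAT_ALT: (1, 2),
    },
    "14-18_M": {
        FoodGroup.VEG_FRUIT: (8, 8),
        FoodGroup.GRAIN: (7, 7),
        FoodGroup.MILK_ALT: (3, 4),
        FoodGroup.MEAT_ALT: (3, 3),
    },
    "14-18_F": {
        FoodGroup.VEG_FRUIT: (7, 7),
        FoodGroup.GRAIN: (6, 6),
        FoodGroup.MILK_ALT: (3, 4),
        FoodGroup.MEAT_ALT: (2, 2),
    },
}


def dri_group_label(age_years: float, sex: Sex) -> str:
    """Map an (age, sex) pair to its DRI reporting band label."""
    if not (2 <= age_years < 19):
        raise ValueError(f"age {age_years} outside [2, 19)")
    for label, lo, hi, band_sex in DRI_BANDS:
        if lo <= age_years < hi and (band_sex is None or band_sex == sex):
            return label
    raise AssertionError("DRI bands must partition [2, 19) x sex")


def recommended_servings(age_years: float, sex: Sex) -> dict[FoodGroup, tuple[float, float]]:
    """EWCFG recommended daily servings (min, max) per food group for an (age, sex)."""
    return dict(_EWCFG_SERVINGS[dri_group_label(age_years, Sex(sex))])


# ---------------------------------------------------------------------------
# Flat-file IO
# ---------------------------------------------------------------------------

FOOD_COLUMNS = [
    "food_id",
    "description",
    "food_group",
    "subgroup",
    "total_fat_g_per_ra",
    "sat_fat_g_per_ra",
    "sugars_g_per_ra",
    "sodium_mg_per_ra",
    "energy_kcal_per_100g",
    "grams_per_ra",
    "grams_per_serving",
    "carb_g_per_100g",
    "is_beverage",
    "is_water",
    "adjustment_flags",
    "gi_value",
]

RESPONDENT_COLUMNS = [
    "respondent_id",
    "age_years",
    "sex",
    "weight_kg",
    "height_m",
    "pal",
    "survey_weight",
]

RECALL_COLUMNS = ["respondent_id", "food_id", "amount_g", "energy_kcal", *NUTRIENT_COLUMNS]


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            try:
                return csv.Sniffer().sniff(line, delimiters=",\t").delimiter
            except csv.Error:
                return ","
    return ","


def _read_table(path: str | Path, mandatory: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in mandatory]
    if extra:
        logger.warning("%s: ignoring unknown column(s): %s", path, ", ".join(extra))
    return df


def _opt_float(value: str) -> Optional[float]:
    value = value.strip()
    return float(value) if value else None


def _bool(value: str) -> bool:
    return value.strip().lower() in {"1", "true", "yes"}


def read_food_table(path: str | Path, taxonomy: dict[str, list[str]]) -> list[FoodRecord]:
    """Read and validate the food composition table.

    ``taxonomy`` maps food-group name to its configured list of subgroups;
    any (group, subgroup) pair outside the taxonomy is a hard error so the
    rule engine never sees an unclassifiable food.
    """
    df = _read_table(path, FOOD_COLUMNS)
    records: list[FoodRecord] = []
    for _, row in df.iterrows():
        fid = row["food_id"]
        group = row["food_group"]
        if group not in taxonomy or row["subgroup"] not in taxonomy[group]:
            raise ValueError(
                f"food {fid!r}: subgroup {row['subgroup']!r} not in configured "
                f"taxonomy for group {group!r}"
            )
        try:
            rec = FoodRecord(
                food_id=fid,
                description=row["description"],
                food_group=FoodGroup(group),
                subgroup=row["subgroup"],
                profile=NutrientProfilePerRA(
                    total_fat_g=float(row["total_fat_g_per_ra"]),
                    sat_fat_g=float(row["sat_fat_g_per_ra"]),
                    sugars_g=float(row["sugars_g_per_ra"]),
                    sodium_mg=float(row["sodium_mg_per_ra"]),
                ),
                energy_kcal_per_100g=float(row["energy_kcal_per_100g"]),
                grams_per_RA=float(row["grams_per_ra"]),
                grams_per_serving=float(row["grams_per_serving"]),
                carb_g_per_100g=float(row["carb_g_per_100g"]),
                is_beverage=_bool(row["is_beverage"]),
                is_water=_bool(row["is_water"]),
                adjustment_flags=frozenset(
                    f for f in row["adjustment_flags"].split(";") if f.strip()
                ),
                gi_value=_opt_float(row["gi_value"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"food {fid!r}: {exc}") from exc
        records.append(rec)
    return records


def write_food_table(records: list[FoodRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "food_id": r.food_id,
                "description": r.description,
                "food_group": r.food_group.value,
                "subgroup": r.subgroup,
                "total_fat_g_per_ra": r.profile.total_fat_g,
                "sat_fat_g_per_ra": r.profile.sat_fat_g,
                "sugars_g_per_ra": r.profile.sugars_g,
                "sodium_mg_per_ra": r.profile.sodium_mg,
                "energy_kcal_per_100g": r.energy_kcal_per_100g,
                "grams_per_ra": r.grams_per_RA,
                "grams_per_serving": r.grams_per_serving,
                "carb_g_per_100g": r.carb_g_per_100g,
                "is_beverage": r.is_beverage,
                "is_water": r.is_water,
                "adjustment_flags": ";".join(sorted(r.adjustment_flags)),
                "gi_value": "" if r.gi_value is None else r.gi_value,
            }
        )
    pd.DataFrame(rows, columns=FOOD_COLUMNS).to_csv(path, index=False)


def read_respondents(path: str | Path) -> list[Respondent]:
    """Read the respondent table.

    Respondents with missing weight, height or (age >= 6) activity level are
    retained but are ineligible for the energy-requirement screen — mirroring
    surveillance practice of excluding them only from misreporting analyses.
    Replicate-weight columns are any columns named ``repw_<i>``, taken in
    numeric order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in RESPONDENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    rep_cols = sorted(
        (c for c in df.columns if c.startswith("repw_")), key=lambda c: int(c.split("_")[1])
    )
    if df["respondent_id"].duplicated().any():
        dupes = df.loc[df["respondent_id"].duplicated(), "respondent_id"].tolist()
        raise ValueError(f"{path}: duplicate respondent_id(s): {dupes[:5]}")
    out: list[Respondent] = []
    for _, row in df.iterrows():
        pal = row["pal"].strip()
        try:
            out.append(
                Respondent(
                    respondent_id=row["respondent_id"],
                    age_years=float(row["age_years"]),
                    sex=Sex(row["sex"]),
                    weight_kg=_opt_float(row["weight_kg"]),
                    height_m=_opt_float(row["height_m"]),
                    pal=PALCategory(pal) if pal else None,
                    survey_weight=float(row["survey_weight"]),
                    replicate_weights=tuple(float(row[c]) for c in rep_cols),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"respondent {row['respondent_id']!r}: {exc}") from exc
    return out


def write_respondents(respondents: list[Respondent], path: str | Path) -> None:
    n_rep = max((len(r.replicate_weights) for r in respondents), default=0)
    rep_cols = [f"repw_{i}" for i in range(n_rep)]
    rows = []
    for r in respondents:
        row = {
            "respondent_id": r.respondent_id,
            "age_years": r.age_years,
            "sex": r.sex.value,
            "weight_kg": "" if r.weight_kg is None else r.weight_kg,
            "height_m": "" if r.height_m is None else r.height_m,
            "pal": "" if r.pal is None else r.pal.value,
            "survey_weight": r.survey_weight,
        }
        row.update({c: w for c, w in zip(rep_cols, r.replicate_weights)})
        rows.append(row)
    pd.DataFrame(rows, columns=RESPONDENT_COLUMNS + rep_cols).to_csv(path, index=False)


def read_recalls(path: str | Path) -> list[RecallItem]:
    df = _read_table(path, RECALL_COLUMNS)
    out: list[RecallItem] = []
    for idx, row in df.iterrows():
        try:
            out.append(
                RecallItem(
                    respondent_id=row["respondent_id"],
                    food_id=row["food_id"],
                    amount_g=float(row["amount_g"]),
                    energy_kcal=float(row["energy_kcal"]),
                    nutrient_amounts={c: float(row[c]) for c in NUTRIENT_COLUMNS},
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"recall row {idx} ({row['respondent_id']!r}): {exc}") from exc
    return out


def write_recalls(items: list[RecallItem], path: str | Path) -> None:
    rows = []
    for it in items:
        row = {
            "respondent_id": it.respondent_id,
            "food_id": it.food_id,
            "amount_g": it.amount_g,
            "energy_kcal": it.energy_kcal,
        }
        row.update({c: it.nutrient_amounts.get(c, 0.0) for c in NUTRIENT_COLUMNS})
        rows.append(row)
    pd.DataFrame(rows, columns=RECALL_COLUMNS).to_csv(path, index=False)
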
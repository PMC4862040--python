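"""Pipeline configuration: validated load of the structured config file.

The package ships a default configuration (``hcst/data/default_config.yaml``)
holding every rule constant of the tier system — threshold set, beverage
calorie cutoff, other-food category map, step-2 adjustment rules, EWCFG
taxonomy, IOM energy-requirement coefficients, misreporting cutoffs, GI
lookup and survey-statistics settings.  Unknown keys are rejected so a typo
cannot silently disable a rule.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .food_model_io import PALCategory, Sex, ThresholdSet

__all__ = [
    "Step2Rule",
    "EERBand",
    "YoungChildEER",
    "EERParameters",
    "MisreportCutoffs",
    "GIConfig",
    "BRRConfig",
    "QuantileConfig",
    "PipelineConfig",
    "load_config",
    "default_config",
]


class Step2Rule(BaseModel):
    """A declarative post-threshold adjustment: predicate on flags and current tier."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    flag: str
    from_tier: int = Field(ge=1, le=4)
    to_tier: int = Field(ge=1, le=4)
    requires_exceeded_lower: tuple[str, ...] = ()


class EERBand(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    sex: Sex
    age_min: float
    age_max: float
    intercept: float
    age_coef: float
    weight_coef: float
    height_coef: float
    growth_kcal: float
    pa: dict[PALCategory, float]

    @model_validator(mode="after")
    def _sedentary_unit(self) -> "EERBand":
        if self.pa.get(PALCategory.SEDENTARY) != 1.0:
            raise ValueError("sedentary PA multiplier must be 1.0")
        if set(self.pa) != set(PALCategory):
            raise ValueError("PA table must cover all four activity categories")
        return self


class YoungChildEER(BaseModel):
    """PAL-free equation form for the youngest band: EER = coef*weight + intercept + growth."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    age_min: float
    age_max: float
    weight_coef: float
    intercept: float
    growth_kcal: float


class EERParameters(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    young_child: YoungChildEER
    bands: tuple[EERBand, ...]

    @model_validator(mode="after")
    def _coverage(self) -> "EERParameters":
        for sex in Sex:
            covered: list[tuple[float, float]] = [
                (self.young_child.age_min, self.young_child.age_max)
            ]
            covered += [(b.age_min, b.age_max) for b in self.bands if b.sex == sex]
            covered.sort()
            lo = 2.0
            for a, b in covered:
                if a > lo:
                    raise ValueError(f"EER bands leave ages [{lo}, {a}) uncovered for {sex}")
                lo = max(lo, b)
            if lo < 19.0:
                raise ValueError(f"EER bands leave ages [{lo}, 19) uncovered for {sex}")
        return self

    def band_for(self, sex: Sex, age_years: float) -> EERBand | YoungChildEER:
        yc = self.young_child
        if yc.age_min <= age_years < yc.age_max:
            return yc
        for band in self.bands:
            if band.sex == sex and band.age_min <= age_years < band.age_max:
                return band
        raise KeyError(f"no EER band configured for sex={sex} age={age_years}")


class MisreportCutoffs(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    age_split_years: float = 12.0
    under_pct_lt12: float = 74.0
    over_pct_lt12: float = 135.0
    under_pct_ge12: float = 70.0
    over_pct_ge12: float = 142.0

    @model_validator(mode="after")
    def _ordered(self) -> "MisreportCutoffs":
        for under, over in (
            (self.under_pct_lt12, self.over_pct_lt12),
            (self.under_pct_ge12, self.over_pct_ge12),
        ):
            if not (under < 100 < over):
                raise ValueError("misreport cutoffs must bracket 100 % of EER")
        return self


class GIConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    default: float = 55.0
    subgroup_medians: dict[str, float] = {}


class BRRConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    n_replicates: int = 50
    fay_factor: float = Field(default=0.0, ge=0.0, lt=1.0)


class QuantileConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    weighted: bool = True


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    thresholds: ThresholdSet = ThresholdSet()
    beverage_high_cal_kcal_per_100g: float = 40.0
    taxonomy: dict[str, list[str]]
    other_category_map: dict[str, str]
    step2_rules: tuple[Step2Rule, ...] = ()
    misreport_cutoffs: MisreportCutoffs = MisreportCutoffs()
    eer: EERParameters
    gi: GIConfig = GIConfig()
    brr: BRRConfig = BRRConfig()
    quantiles: QuantileConfig = QuantileConfig()

    @model_validator(mode="after")
    def _other_map_consistent(self) -> "PipelineConfig":
        other = set(self.taxonomy.get("OTHER", []))
        unmapped = other - set(self.other_category_map)
        if unmapped:
            raise ValueError(f"OTHER subgroups without a category mapping: {sorted(unmapped)}")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)


def default_config() -> PipelineConfig:
    """The configuration shipped with the package (published rule constants)."""
    ref = resources.files("hcst.data").joinpath("default_config.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return PipelineConfig.model_validate(raw)
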
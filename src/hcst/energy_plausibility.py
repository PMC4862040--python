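"""Energy-misreporting screen: IOM estimated energy requirement and EI/EER cutoffs.

Each respondent's reported energy intake (EI) is compared against their
estimated energy requirement (EER) from the IOM factorial equations (age,
sex, weight, height, physical-activity level).  The ratio 100*EI/EER is then
screened against age-banded cutoffs: under-reporter below 74 % (< 12 years)
or 70 % (>= 12 years) of EER, over-reporter above 135 % / 142 %.  The
inequalities are strict, so a ratio exactly at a cutoff is plausible.
Respondents missing any equation input are ineligible and receive no number.
"""

from __future__ import annotations

import enum
from typing import Optional

from .config import EERBand, EERParameters, MisreportCutoffs, YoungChildEER
from .food_model_io import PALCategory, Respondent

__all__ = ["MisreportStatus", "eer", "misreport_status", "screen_respondent"]


class MisreportStatus(str, enum.Enum):
    UNDER = "UNDER"
    PLAUSIBLE = "PLAUSIBLE"
    OVER = "OVER"
    INELIGIBLE = "INELIGIBLE"


def eer(respondent: Respondent, params: EERParameters) -> Optional[float]:
    """Estimated energy requirement in kcal/day, or ``None`` if ineligible.

    Children below the young-child age bound use the PAL-free equation form;
    from there until age 6 (for whom activity was not collected) a missing
    PAL defaults to sedentary.
    """
    if respondent.weight_kg is None or respondent.height_m is None:
        return None
    band = params.band_for(respondent.sex, respondent.age_years)
    if isinstance(band, YoungChildEER):
        return band.weight_coef * respondent.weight_kg + band.intercept + band.growth_kcal
    assert isinstance(band, EERBand)
    pal = respondent.pal
    if pal is None:
        if respondent.age_years >= 6:
            return None
        pal = PALCategory.SEDENTARY
    pa = band.pa[pal]
    return (
        band.intercept
        + band.age_coef * respondent.age_years
        + pa * (band.weight_coef * respondent.weight_kg + band.height_coef * respondent.height_m)
        + band.growth_kcal
    )


def misreport_status(
    ei_kcal: float,
    eer_kcal: float,
    age_years: float,
    cutoffs: MisreportCutoffs | None = None,
) -> MisreportStatus:
    """Classify an EI/EER ratio against the age-banded plausibility cutoffs."""
    if eer_kcal <= 0:
        raise ValueError("EER must be positive")
    if ei_kcal < 0:
        raise ValueError("EI must be nonnegative")
    cutoffs = cutoffs or MisreportCutoffs()
    ratio = 100.0 * ei_kcal / eer_kcal
    if age_years < cutoffs.age_split_years:
        under, over = cutoffs.under_pct_lt12, cutoffs.over_pct_lt12
    else:
        under, over = cutoffs.under_pct_ge12, cutoffs.over_pct_ge12
    if ratio < under:
        return MisreportStatus.UNDER
    if ratio > over:
        return MisreportStatus.OVER
    return MisreportStatus.PLAUSIBLE


def screen_respondent(
    respondent: Respondent,
    ei_kcal: float,
    params: EERParameters,
    cutoffs: MisreportCutoffs | None = None,
) -> tuple[MisreportStatus, Optional[float]]:
    """(status, EER) for one respondent; INELIGIBLE carries no EER."""
    if not respondent.eer_eligible:
        return MisreportStatus.INELIGIBLE, None
    req = eer(respondent, params)
    if req is None:
        return MisreportStatus.INELIGIBLE, None
    return misreport_status(ei_kcal, req, respondent.age_years, cutoffs), req
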
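"""Compliance strata: quartiles of percent energy from Tier 4 + non-recommended foods.

Respondents are ranked, within the child (< 12 years) and adolescent
(>= 12 years) strata, on the percent of their energy intake coming from
Tier 4 foods plus "other" foods and beverages not recommended in the food
guide.  Quartile 1 members are "compliers", quartiles 2-3 "intermediates",
quartile 4 "non-compliers".
"""

from __future__ import annotations

import enum

import numpy as np
from pydantic import BaseModel, ConfigDict

from .food_model_io import Respondent
from .recall_metrics import RespondentProfile

__all__ = [
    "Quartile",
    "ComplianceLabel",
    "AgeStratum",
    "ComplianceResult",
    "weighted_quantile",
    "quartile_cutpoints",
    "assign_quartile",
    "stratify",
]


class Quartile(str, enum.Enum):
    Q1 = "Q1"
    Q2 = "Q2"
    Q3 = "Q3"
    Q4 = "Q4"


class ComplianceLabel(str, enum.Enum):
    COMPLIER = "COMPLIER"
    INTERMEDIATE = "INTERMEDIATE"
    NON_COMPLIER = "NON_COMPLIER"


class AgeStratum(str, enum.Enum):
    CHILD = "CHILD"  # age < 12
    ADOLESCENT = "ADOLESCENT"  # age >= 12


_LABEL_BY_QUARTILE = {
    Quartile.Q1: ComplianceLabel.COMPLIER,
    Quartile.Q2: ComplianceLabel.INTERMEDIATE,
    Quartile.Q3: ComplianceLabel.INTERMEDIATE,
    Quartile.Q4: ComplianceLabel.NON_COMPLIER,
}


class ComplianceResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    respondent_id: str
    pct_energy_nonrecommended: float
    quartile: Quartile
    label: ComplianceLabel
    stratum: AgeStratum


def weighted_quantile(values, weights, q) -> np.ndarray:
    """Weight-replication-consistent quantiles with linear interpolation.

    A record of weight *w* behaves exactly like *w* unit-weight copies: the
    quantile at probability ``q`` is read at continuous rank
    ``h = (W - 1) q + 1`` on the weighted order statistics (``W`` the total
    weight), interpolating linearly across the unit of weight spanning ``h``.
    With equal unit weights this is the ordinary linear-interpolation sample
    quantile, and integer weights reproduce the expanded-sample quantile
    exactly.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if values.shape != weights.shape or values.ndim != 1:
        raise ValueError("values and weights must be equal-length 1-D arrays")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    keep = weights > 0
    values, weights = values[keep], weights[keep]
    if values.size == 0:
        raise ValueError("total weight must be positive")
    order = np.argsort(values, kind="stable")
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    total = cum[-1]

    def value_at_rank(r: float) -> float:
        # value of the weighted order statistic at continuous rank r in (0, W]
        idx = np.searchsorted(cum, r, side="left")
        return values[min(idx, values.size - 1)]

    out = np.empty(q.shape)
    for i, qq in enumerate(q):
        if not 0 <= qq <= 1:
            raise ValueError("quantile probabilities must lie in [0, 1]")
        h = (total - 1.0) * qq + 1.0
        lo = np.floor(h)
        frac = h - lo
        v_lo = value_at_rank(max(lo, 1.0))
        if frac == 0:
            out[i] = v_lo
        else:
            out[i] = v_lo + frac * (value_at_rank(lo + 1.0) - v_lo)
    return out


def quartile_cutpoints(values, weights=None) -> tuple[float, float, float]:
    """(q25, q50, q75) of the compliance metric; survey-weighted by default."""
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("at least 4 respondents are required for quartiles")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("total weight must be positive")
    q25, q50, q75 = weighted_quantile(values, weights, [0.25, 0.5, 0.75])
    return float(q25), float(q50), float(q75)


def assign_quartile(value: float, cutpoints: tuple[float, float, float]) -> Quartile:
    """Ties at a cutpoint go to the lower quartile."""
    q25, q50, q75 = cutpoints
    if value <= q25:
        return Quartile.Q1
    if value <= q50:
        return Quartile.Q2
    if value <= q75:
        return Quartile.Q3
    return Quartile.Q4


def stratify(
    profiles: list[RespondentProfile],
    respondents: list[Respondent],
    weighted: bool = True,
    age_split_years: float = 12.0,
) -> tuple[list[ComplianceResult], dict[AgeStratum, tuple[float, float, float]]]:
    """Quartile-stratify respondents within the child and adolescent strata.

    Returns the per-respondent results (input order preserved) and the
    cutpoint table per stratum.  Cutpoints use survey weights unless
    ``weighted`` is false.
    """
    resp_by_id = {r.respondent_id: r for r in respondents}
    strata: dict[AgeStratum, list[RespondentProfile]] = {s: [] for s in AgeStratum}
    for p in profiles:
        r = resp_by_id[p.respondent_id]
        stratum = AgeStratum.CHILD if r.age_years < age_split_years else AgeStratum.ADOLESCENT
        strata[stratum].append(p)

    cutpoints: dict[AgeStratum, tuple[float, float, float]] = {}
    for stratum, members in strata.items():
        if not members:
            continue
        vals = [p.pct_energy_nonrecommended for p in members]
        wts = (
            [resp_by_id[p.respondent_id].survey_weight for p in members] if weighted else None
        )
        cutpoints[stratum] = quartile_cutpoints(vals, wts)

    results: list[ComplianceResult] = []
    for p in profiles:
        r = resp_by_id[p.respondent_id]
        stratum = AgeStratum.CHILD if r.age_years < age_split_years else AgeStratum.ADOLESCENT
        q = assign_quartile(p.pct_energy_nonrecommended, cutpoints[stratum])
        results.append(
            ComplianceResult(
                respondent_id=p.respondent_id,
                pct_energy_nonrecommended=p.pct_energy_nonrecommended,
                quartile=q,
                label=_LABEL_BY_QUARTILE[q],
                stratum=stratum,
            )
        )
    return results, cutpoints
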
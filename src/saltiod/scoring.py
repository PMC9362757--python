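"""Percent-of-guidelines-met scoring and aggregation.

The central statistic: a country's recorded standard amount (midpoint
or single value, mg iodine/kg salt) divided by the WHO 2014 suggested
amount at that country's salt intake, times 100.  100% means the
standard matches the guideline exactly; 200% means it requires double
the suggested amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .errors import DomainError, ValidationError
from .guidelines import DEFAULT_PARAMS, GuidelineParams, WhoMode, who_iodine_amount
from .standards import CompoundCategory, Scope

__all__ = ["ScoreCategory", "ScoreResult", "ScoreSummary", "percent_guidelines_met", "aggregate_scores"]


class ScoreCategory(str, Enum):
    BELOW = "below"
    MEETS = "meets"
    ABOVE = "above"


@dataclass(frozen=True)
class ScoreResult:
    """Per-country score against the 2014 guidelines."""

    country: str
    salt_intake_g_day: float
    who_amount_mg_kg: float
    standard_midpoint_mg_kg: float
    percent_met: float
    category: ScoreCategory
    scope: Scope | None = None
    compound_category: CompoundCategory | None = None


def percent_guidelines_met(
    midpoint_mg_kg: float,
    salt_intake_g_day: float,
    params: GuidelineParams = DEFAULT_PARAMS,
    mode: WhoMode = "continuous",
    *,
    country: str = "",
    scope: Scope | None = None,
    compound_category: CompoundCategory | None = None,
    meets_tolerance: float = 0.0,
) -> ScoreResult:
    """Score one standard against the WHO suggested amount.

    ``percent_met = 100 × midpoint / who_amount(salt_intake)``.  The
    category is ``below`` (< 100%), ``meets`` (= 100%, compared exactly
    after computation unless ``meets_tolerance`` > 0), or ``above``
    (> 100%).
    """
    if not midpoint_mg_kg > 0:
        raise DomainError(f"midpoint must be positive, got {midpoint_mg_kg}")
    if not salt_intake_g_day > 0:
        raise DomainError(f"salt intake must be positive, got {salt_intake_g_day}")
    who = who_iodine_amount(salt_intake_g_day, params, mode)
    # divide first, then scale: a midpoint equal to the WHO amount must
    # give exactly 100.0
    percent = 100.0 * (midpoint_mg_kg / who)
    if abs(percent - 100.0) <= meets_tolerance:
        category = ScoreCategory.MEETS
    elif percent < 100.0:
        category = ScoreCategory.BELOW
    else:
        category = ScoreCategory.ABOVE
    return ScoreResult(
        country=country,
        salt_intake_g_day=salt_intake_g_day,
        who_amount_mg_kg=who,
        standard_midpoint_mg_kg=midpoint_mg_kg,
        percent_met=percent,
        category=category,
        scope=scope,
        compound_category=compound_category,
    )


@dataclass
class ScoreSummary:
    """Aggregate view over a set of country scores."""

    by_category: pd.DataFrame  # category, n, pct
    min_percent: float
    min_country: str
    max_percent: float
    max_country: str
    by_scope: pd.DataFrame  # scope × category counts
    by_compound: pd.DataFrame  # compound category counts and pct
    n: int


def scores_to_frame(scores: list[ScoreResult]) -> pd.DataFrame:
    """Tabulate scores, one row per country, sorted by country code."""
    rows = [
        {
            "country": s.country,
            "salt_intake_g_day": s.salt_intake_g_day,
            "who_amount_mg_kg": s.who_amount_mg_kg,
            "midpoint_mg_kg": s.standard_midpoint_mg_kg,
            "percent_met": s.percent_met,
            "category": s.category.value,
            "scope": s.scope.value if s.scope else "",
            "compound_category": s.compound_category.value if s.compound_category else "",
        }
        for s in scores
    ]
    return pd.DataFrame(rows).sort_values("country", kind="stable").reset_index(drop=True)


def aggregate_scores(scores: list[ScoreResult]) -> ScoreSummary:
    """Counts and percentages per category, extremes, and cross-tabs.

    The scope cross-tab contrasts standards covering both household and
    processed-food salt with those covering only one stream; the
    compound table counts the three-way recommended-compound
    classification.  Results are invariant to input order.
    """
    if not scores:
        raise ValidationError("cannot aggregate an empty score list")
    df = scores_to_frame(scores)
    n = len(df)

    cats = [c.value for c in ScoreCategory]
    counts = df["category"].value_counts().reindex(cats, fill_value=0)
    by_category = pd.DataFrame(
        {"category": cats, "n": counts.values, "pct": 100.0 * counts.values / n}
    )

    imin = df["percent_met"].idxmin()
    imax = df["percent_met"].idxmax()

    scope_merged = df["scope"].map(
        lambda s: "both" if s == Scope.BOTH.value else "single_stream"
    )
    by_scope = (
        pd.crosstab(scope_merged, df["category"])
        .reindex(columns=cats, fill_value=0)
        .rename_axis(index="scope", columns=None)
        .reset_index()
    )

    comp_counts = (
        df.loc[df["compound_category"] != "", "compound_category"]
        .value_counts()
        .reindex([c.value for c in CompoundCategory], fill_value=0)
    )
    comp_total = comp_counts.sum()
    by_compound = pd.DataFrame(
        {
            "compound_category": comp_counts.index,
            "n": comp_counts.values,
            "pct": 100.0 * comp_counts.values / comp_total if comp_total else 0.0,
        }
    )

    return ScoreSummary(
        by_category=by_category,
        min_percent=float(df.loc[imin, "percent_met"]),
        min_country=str(df.loc[imin, "country"]),
        max_percent=float(df.loc[imax, "percent_met"]),
        max_country=str(df.loc[imax, "country"]),
        by_scope=by_scope,
        by_compound=by_compound,
        n=n,
    )
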
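"""Linking guideline scores to population iodine status.

Median urinary iodine concentration (mUIC, μg/L) is the standard
population indicator of recent iodine intake: below 100 μg/L intake is
insufficient, 100–299 μg/L adequate, 300 μg/L and above excessive.

A country's score can only be expected to predict its mUIC when iodized
salt actually reaches households, so an eligibility filter is applied
before correlating: at least 70% of households must consume salt
iodized to any level, the coverage survey must precede the mUIC
assessment by 1–5 years, and the survey must have been run more than a
year after the salt standard was issued.  A relaxed alternative keeps
every country with an mUIC assessment in school-age children taken
after the standard was issued.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Sequence

import pandas as pd
from scipy import stats

from .errors import (
    DomainError,
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)
from .scoring import ScoreResult
from .standards import SaltStandard

__all__ = [
    "MuicClass",
    "Population",
    "CoverageRecord",
    "StatusRecord",
    "EligibilityCriterion",
    "EligibilityResult",
    "CorrelationResult",
    "classify_muic",
    "is_eligible",
    "correlate",
    "DEFAULT_POPULATION_PRIORITY",
]


class MuicClass(str, Enum):
    INSUFFICIENT = "insufficient"
    ADEQUATE = "adequate"
    EXCESSIVE = "excessive"


class Population(str, Enum):
    SCHOOL_AGE_CHILDREN = "school_age_children"
    WOMEN_REPRODUCTIVE_AGE = "women_reproductive_age"
    GENERAL = "general"


#: When a country has mUIC surveys in several population groups, the
#: first group in this order is used.
DEFAULT_POPULATION_PRIORITY: tuple[Population, ...] = (
    Population.SCHOOL_AGE_CHILDREN,
    Population.WOMEN_REPRODUCTIVE_AGE,
    Population.GENERAL,
)


@dataclass(frozen=True)
class CoverageRecord:
    """Household iodized-salt coverage survey (any iodization level)."""

    country: str
    pct_households_any_iodized: float
    survey_start_year: int
    survey_end_year: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "country", self.country.upper())
        if not 0 <= self.pct_households_any_iodized <= 100:
            raise ValidationError(
                f"coverage must be 0–100%, got {self.pct_households_any_iodized}"
            )
        if self.survey_start_year > self.survey_end_year:
            raise ValidationError("survey start year after end year")

    def reference_year(self, rule: Literal["end", "start", "midpoint"] = "end") -> int:
        if rule == "end":
            return self.survey_end_year
        if rule == "start":
            return self.survey_start_year
        return (self.survey_start_year + self.survey_end_year) // 2


@dataclass(frozen=True)
class StatusRecord:
    """One population mUIC assessment."""

    country: str
    muic_ug_L: float
    assessment_year: int
    population: Population = Population.GENERAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "country", self.country.upper())
        object.__setattr__(self, "population", Population(self.population))
        if self.muic_ug_L < 0:
            raise ValidationError(f"mUIC cannot be negative, got {self.muic_ug_L}")


class EligibilityCriterion(str, Enum):
    COVERAGE_BELOW_70 = "coverage_below_70"
    WINDOW_VIOLATION = "window_violation"
    PRE_STANDARD_SURVEY = "pre_standard_survey"
    MISSING_DATA = "missing_data"


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    failed_criteria: tuple[EligibilityCriterion, ...] = ()

    def __post_init__(self) -> None:
        if self.eligible != (not self.failed_criteria):
            raise ValidationError("eligible must mean no failed criteria")


def classify_muic(muic_ug_L: float) -> MuicClass:
    """Classify a population mUIC: <100 insufficient, 100–299 adequate,
    ≥300 excessive (μg/L)."""
    if muic_ug_L is None or (isinstance(muic_ug_L, float) and math.isnan(muic_ug_L)):
        raise DomainError("mUIC is missing")
    if muic_ug_L < 0:
        raise DomainError(f"mUIC cannot be negative, got {muic_ug_L}")
    if muic_ug_L < 100:
        return MuicClass.INSUFFICIENT
    if muic_ug_L < 300:
        return MuicClass.ADEQUATE
    return MuicClass.EXCESSIVE


def is_eligible(
    standard: SaltStandard,
    coverage: CoverageRecord,
    status: StatusRecord,
    *,
    coverage_threshold: float = 70.0,
    window_years: tuple[int, int] = (1, 5),
    min_post_standard_gap_years: int = 1,
    reference_year_rule: Literal["end", "start", "midpoint"] = "end",
) -> EligibilityResult:
    """Apply the status-linkage eligibility filter to one country.

    Eligible iff coverage ≥ 70% of households, the mUIC assessment
    falls 1–5 years (inclusive) after the coverage survey's reference
    year (the survey end year by default), and the coverage survey was
    run strictly more than a year after the standard was issued.  All
    criteria are evaluated; failures are enumerated, not
    short-circuited.
    """
    if not (standard.country == coverage.country == status.country):
        raise ValidationError(
            f"country mismatch: {standard.country}, {coverage.country}, "
            f"{status.country}"
        )
    failed: list[EligibilityCriterion] = []
    missing = any(
        v is None or (isinstance(v, float) and math.isnan(v))
        for v in (
            coverage.pct_households_any_iodized,
            status.muic_ug_L,
            float(status.assessment_year),
            float(standard.issue_year),
        )
    )
    if missing:
        failed.append(EligibilityCriterion.MISSING_DATA)
        return EligibilityResult(False, tuple(failed))

    ref = coverage.reference_year(reference_year_rule)
    if coverage.pct_households_any_iodized < coverage_threshold:
        failed.append(EligibilityCriterion.COVERAGE_BELOW_70)
    gap = status.assessment_year - ref
    if not window_years[0] <= gap <= window_years[1]:
        failed.append(EligibilityCriterion.WINDOW_VIOLATION)
    if not (ref - standard.issue_year) > min_post_standard_gap_years:
        failed.append(EligibilityCriterion.PRE_STANDARD_SURVEY)
    return EligibilityResult(not failed, tuple(failed))


@dataclass
class CorrelationResult:
    """Pearson correlation between percent-of-guidelines-met and mUIC."""

    r: float
    p: float
    n: int
    table: pd.DataFrame  # country, percent_met, muic_ug_L, muic_class, population

    def summary(self) -> dict:
        return {"r": self.r, "p": self.p, "n": self.n}


LinkageFilter = Literal["strict_eligibility", "post_legislation_sac"]


def _pick_status(
    statuses: Sequence[StatusRecord],
    priority: Sequence[Population],
) -> StatusRecord | None:
    for pop in priority:
        matches = [s for s in statuses if s.population is pop]
        if matches:
            # latest assessment wins; ties broken on mUIC for determinism
            return max(matches, key=lambda s: (s.assessment_year, s.muic_ug_L))
    return None


def join_status(
    scores: Sequence[ScoreResult],
    statuses: Sequence[StatusRecord],
    *,
    filter: LinkageFilter = "post_legislation_sac",
    coverages: Sequence[CoverageRecord] | None = None,
    standards: Sequence[SaltStandard] | None = None,
    population_priority: Sequence[Population] = DEFAULT_POPULATION_PRIORITY,
    coverage_threshold: float = 70.0,
    window_years: tuple[int, int] = (1, 5),
    min_post_standard_gap_years: int = 1,
    reference_year_rule: Literal["end", "start", "midpoint"] = "end",
) -> pd.DataFrame:
    """Join scores to mUIC records under an eligibility filter.

    Returns one row per country that passes the filter, with columns
    country, percent_met, muic_ug_L, muic_class, population.
    """
    by_country_status: dict[str, list[StatusRecord]] = {}
    for s in statuses:
        by_country_status.setdefault(s.country, []).append(s)
    std_by_country = {s.country: s for s in standards} if standards else {}
    cov_by_country: dict[str, list[CoverageRecord]] = {}
    for c in coverages or ():
        cov_by_country.setdefault(c.country, []).append(c)

    rows = []
    for score in sorted(scores, key=lambda s: s.country):
        country = score.country
        cands = by_country_status.get(country, [])
        if not cands:
            continue
        std = std_by_country.get(country)
        if filter == "strict_eligibility":
            if std is None:
                raise ValidationError(
                    "strict_eligibility filter requires standards for every scored "
                    f"country; missing {country}"
                )
            chosen: StatusRecord | None = None
            # statuses in priority order; within a status, any coverage
            # survey satisfying the criteria qualifies the country
            for pop in population_priority:
                for status in sorted(
                    (s for s in cands if s.population is pop),
                    key=lambda s: (-s.assessment_year, -s.muic_ug_L),
                ):
                    for cov in sorted(
                        cov_by_country.get(country, []),
                        key=lambda c: -c.survey_end_year,
                    ):
                        res = is_eligible(
                            std,
                            cov,
                            status,
                            coverage_threshold=coverage_threshold,
                            window_years=window_years,
                            min_post_standard_gap_years=min_post_standard_gap_years,
                            reference_year_rule=reference_year_rule,
                        )
                        if res.eligible:
                            chosen = status
                            break
                    if chosen:
                        break
                if chosen:
                    break
            if chosen is None:
                continue
            status = chosen
        elif filter == "post_legislation_sac":
            sac = [
                s
                for s in cands
                if s.population is Population.SCHOOL_AGE_CHILDREN
                and (std is None or s.assessment_year > std.issue_year)
            ]
            if not sac:
                continue
            status = max(sac, key=lambda s: (s.assessment_year, s.muic_ug_L))
        else:
            raise ValidationError(f"unknown linkage filter {filter!r}")
        rows.append(
            {
                "country": country,
                "percent_met": score.percent_met,
                "muic_ug_L": status.muic_ug_L,
                "muic_class": classify_muic(status.muic_ug_L).value,
                "population": status.population.value,
            }
        )
    return pd.DataFrame(
        rows, columns=["country", "percent_met", "muic_ug_L", "muic_class", "population"]
    )


def correlate(
    scores: Sequence[ScoreResult],
    statuses: Sequence[StatusRecord],
    *,
    filter: LinkageFilter = "post_legislation_sac",
    coverages: Sequence[CoverageRecord] | None = None,
    standards: Sequence[SaltStandard] | None = None,
    **join_options,
) -> CorrelationResult:
    """Pearson correlation of percent-of-guidelines-met against mUIC.

    The two-sided p-value comes from the t transform
    ``t = r sqrt((n − 2) / (1 − r²))`` with n − 2 degrees of freedom.
    Requires at least 3 joined pairs and non-degenerate variance in
    both variables.
    """
    table = join_status(
        scores,
        statuses,
        filter=filter,
        coverages=coverages,
        standards=standards,
        **join_options,
    )
    n = len(table)
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 country pairs to correlate, got {n}"
        )
    x = table["percent_met"].to_numpy(dtype=float)
    y = table["muic_ug_L"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: zero variance in percent_met or mUIC"
        )
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n, table=table)
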
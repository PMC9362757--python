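"""Synthetic country tables with known ground truth.

Emulates the structure of the global fortification-database extracts
the pipeline consumes — one salt standard, one salt-intake estimate,
one household coverage survey and one mUIC assessment per country —
with a physiological forward model tying them together so that every
pipeline stage can be validated against generator bookkeeping:

1. Draw a salt intake ``s`` (g/day, truncated normal on [3, 14]) and a
   guideline multiplier ``m`` (uniform, default on [0.68, 3.50] to span
   the 68%–350% range observed across real national standards).
2. Set the standard's midpoint to ``m × who_amount(s)`` and synthesize
   a range, minimum or single-value clause around it.
3. Compute the iodine actually consumed: concentration at household
   ``c = midpoint × compliance × (1 − loss_fraction)`` mg/kg, daily
   intake ``I = s × c + baseline_diet_iodine`` μg/day.
4. Map intake to urinary concentration: ``mUIC = excreted_fraction × I
   / urine_volume_L`` μg/L, with multiplicative lognormal noise.

With default parameters, ``compliance = 1`` and ``m = 1`` the model
gives mUIC = 0.90 × (10 × 19.5 × 0.7) / 1.0 = 122.85 μg/L at a 10 g/day
intake — adequate, consistent with salt iodization at exactly the
guideline level delivering adequate iodine status.

Survey and standard years are drawn so that a configurable fraction of
countries passes the strict eligibility filter; the rest violate
exactly one criterion each, chosen at random.  A ground-truth table
(never read by the pipeline) records the multiplier, designed
eligibility and score category per country.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .guidelines import (
    DEFAULT_PARAMS,
    POTASSIUM_IODATE,
    POTASSIUM_IODIDE,
    GuidelineParams,
    WhoMode,
    who_iodine_amount,
)

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate"]

STANDARDS_COLUMNS = [
    "country", "issue_year", "iodine_form", "iodine_low", "iodine_high",
    "iodine_value", "basis", "basis_compound", "compounds", "scope",
]
INTAKE_COLUMNS = ["country", "salt_intake_g_day"]
COVERAGE_COLUMNS = [
    "country", "pct_households_any_iodized", "survey_start_year", "survey_end_year",
]
STATUS_COLUMNS = ["country", "muic_ug_L", "assessment_year", "population"]
TRUTH_COLUMNS = [
    "country", "multiplier", "salt_intake_g_day", "midpoint_mg_kg",
    "percent_met_true", "category_true", "compound_category_true", "scope_true",
    "muic_noiseless_ug_L", "eligible_design",
]

_NONRECOMMENDED = ("calcium_iodate", "sodium_iodide", "sodium_iodate")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    The defaults mirror the structure of the real country tables:
    salt intakes centred near 10 g/day within the 3–14 g/day guideline
    span, standard midpoints between 68% and 350% of the suggested
    amount, compound mixes dominated by the recommended iodate/iodide
    pair, and mostly both-stream legislation scope.
    """

    n_countries: int = 110
    seed: int = 0
    # salt intake distribution, g/day (normal truncated to bounds)
    salt_intake_mean: float = 10.0
    salt_intake_sd: float = 2.5
    salt_intake_bounds: tuple[float, float] = (3.0, 14.0)
    # multiplier m = standard midpoint / WHO amount
    multiplier_low: float = 0.68
    multiplier_high: float = 3.50
    range_halfwidth_frac: float = 0.25
    # probabilities for the iodine-clause form: range, single, minimum
    form_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    # probabilities for compound classes: all_recommended, mixed, none
    compound_probs: tuple[float, float, float] = (0.74, 0.25, 0.01)
    # probability the legislation covers both salt streams
    scope_both_prob: float = 96 / 110
    # forward model
    compliance: float = 1.0
    loss_fraction: float = 0.30
    baseline_diet_iodine_ug: float = 0.0
    excreted_fraction: float = 0.90
    urine_volume_L: float = 1.0
    noise_sigma: float = 0.15
    # year scheme
    eligible_fraction: float = 0.8
    issue_year_range: tuple[int, int] = (1990, 2005)
    # population group probabilities: SAC, WRA, general
    population_probs: tuple[float, float, float] = (0.8, 0.15, 0.05)
    who_mode: WhoMode = "continuous"
    params: GuidelineParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        if self.n_countries < 0:
            raise ConfigError("n_countries must be non-negative")
        if not 0 <= self.compliance <= 1:
            raise ConfigError("compliance must lie in [0, 1]")
        if not 0 < self.excreted_fraction <= 1:
            raise ConfigError("excreted_fraction must lie in (0, 1]")
        if not self.urine_volume_L > 0:
            raise ConfigError("urine_volume_L must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")
        if not self.multiplier_low <= self.multiplier_high:
            raise ConfigError("multiplier_low must not exceed multiplier_high")
        if not 0 < self.multiplier_low:
            raise ConfigError("multipliers must be positive")
        if not 0 <= self.range_halfwidth_frac < 1:
            raise ConfigError("range_halfwidth_frac must lie in [0, 1)")
        if not 0 <= self.eligible_fraction <= 1:
            raise ConfigError("eligible_fraction must lie in [0, 1]")
        lo, hi = self.salt_intake_bounds
        if not 0 < lo < hi:
            raise ConfigError("salt intake bounds must satisfy 0 < low < high")
        for probs, name in (
            (self.form_probs, "form_probs"),
            (self.compound_probs, "compound_probs"),
            (self.population_probs, "population_probs"),
        ):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be non-negative and sum to 1")


@dataclass
class SyntheticBundle:
    """Generated tables plus the ground truth the pipeline never sees."""

    standards: pd.DataFrame
    intake: pd.DataFrame
    coverage: pd.DataFrame
    status: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the five tables as CSVs; same config+seed ⇒ identical bytes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("standards", "intake", "coverage", "status", "truth"):
            p = out / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths


def _country_code(i: int) -> str:
    """Deterministic synthetic ISO3-style codes: AAA, AAB, ..."""
    letters = []
    for _ in range(3):
        letters.append(chr(ord("A") + i % 26))
        i //= 26
    return "".join(reversed(letters))


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    # rejection sampling; bounds are a few SDs wide so this terminates fast
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))  # pathological config fallback


def _draw_compounds(rng: np.random.Generator, probs) -> tuple[str, str]:
    """Return (semicolon-joined compound list, designed category)."""
    cat = rng.choice(["all_recommended", "mixed", "none_recommended"], p=list(probs))
    rec = [POTASSIUM_IODATE, POTASSIUM_IODIDE]
    if cat == "all_recommended":
        pick = rng.integers(0, 3)
        chosen = rec if pick == 2 else [rec[pick]]
    elif cat == "mixed":
        chosen = [rec[rng.integers(0, 2)], _NONRECOMMENDED[rng.integers(0, 3)]]
    else:
        chosen = [_NONRECOMMENDED[rng.integers(0, 3)]]
    return ";".join(chosen), cat


def _draw_years(rng: np.random.Generator, cfg: SyntheticConfig, eligible: bool):
    """Issue/survey/assessment years plus coverage pct honouring the design.

    Eligible countries satisfy every strict criterion; ineligible ones
    violate exactly one, drawn at random.
    """
    y0, y1 = cfg.issue_year_range
    issue = int(rng.integers(y0, y1 + 1))
    post_gap = int(rng.integers(2, 9))  # survey > 1 y after the standard
    end = issue + post_gap
    start = end - int(rng.integers(0, 2))
    muic_year = end + int(rng.integers(1, 6))  # in [1, 5]
    pct = float(rng.uniform(70.0, 99.5))
    if not eligible:
        violation = rng.choice(["coverage", "window", "pre_standard"])
        if violation == "coverage":
            pct = float(rng.uniform(20.0, 69.5))
        elif violation == "window":
            gap = int(rng.choice([0, 6, 7, 8]))
            muic_year = end + gap
        else:  # survey too soon after (or before) the standard
            end = issue + int(rng.integers(0, 2))  # gap of 0 or 1, not > 1
            start = end
            muic_year = end + int(rng.integers(1, 6))
    return issue, start, end, muic_year, pct


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the four pipeline tables plus ground truth.

    Deterministic: the same config (including seed) always yields
    byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    std_rows, intake_rows, cov_rows, status_rows, truth_rows = [], [], [], [], []
    populations = [p for p in
                   ("school_age_children", "women_reproductive_age", "general")]
    lo_b, hi_b = config.salt_intake_bounds

    for i in range(config.n_countries):
        country = _country_code(i)
        s = _truncated_normal(
            rng, config.salt_intake_mean, config.salt_intake_sd, lo_b, hi_b
        )
        m = float(rng.uniform(config.multiplier_low, config.multiplier_high))
        who = who_iodine_amount(s, config.params, config.who_mode)
        midpoint = m * who

        form = str(rng.choice(["range", "single", "minimum"], p=list(config.form_probs)))
        h = config.range_halfwidth_frac
        low = high = value = ""
        if form == "range" and h > 0:
            low, high = midpoint * (1 - h), midpoint * (1 + h)
        elif form == "range":  # degenerate halfwidth: fall back to a single value
            form = "single"
            value = midpoint
        elif form == "minimum":
            low = midpoint
        else:
            value = midpoint
        compounds, comp_cat = _draw_compounds(rng, config.compound_probs)
        scope = (
            "both"
            if rng.random() < config.scope_both_prob
            else str(rng.choice(["household_only", "processed_only"]))
        )

        eligible = bool(rng.random() < config.eligible_fraction)
        issue, start, end, muic_year, pct = _draw_years(rng, config, eligible)

        conc_household = midpoint * config.compliance * (1 - config.loss_fraction)
        intake_ug = s * conc_household + config.baseline_diet_iodine_ug
        muic_clean = config.excreted_fraction * intake_ug / config.urine_volume_L
        noise = (
            float(rng.lognormal(0.0, config.noise_sigma))
            if config.noise_sigma > 0
            else 1.0
        )
        muic = muic_clean * noise
        population = str(rng.choice(populations, p=list(config.population_probs)))

        std_rows.append(
            dict(
                country=country, issue_year=issue, iodine_form=form,
                iodine_low=low, iodine_high=high, iodine_value=value,
                basis="iodine", basis_compound="", compounds=compounds, scope=scope,
            )
        )
        intake_rows.append(dict(country=country, salt_intake_g_day=s))
        cov_rows.append(
            dict(
                country=country, pct_households_any_iodized=pct,
                survey_start_year=start, survey_end_year=end,
            )
        )
        status_rows.append(
            dict(
                country=country, muic_ug_L=muic, assessment_year=muic_year,
                population=population,
            )
        )
        truth_rows.append(
            dict(
                country=country, multiplier=m, salt_intake_g_day=s,
                midpoint_mg_kg=midpoint, percent_met_true=100.0 * m,
                category_true=("below" if m < 1 else "meets" if m == 1 else "above"),
                compound_category_true=comp_cat, scope_true=scope,
                muic_noiseless_ug_L=muic_clean, eligible_design=eligible,
            )
        )

    return SyntheticBundle(
        standards=pd.DataFrame(std_rows, columns=STANDARDS_COLUMNS),
        intake=pd.DataFrame(intake_rows, columns=INTAKE_COLUMNS),
        coverage=pd.DataFrame(cov_rows, columns=COVERAGE_COLUMNS),
        status=pd.DataFrame(status_rows, columns=STATUS_COLUMNS),
        truth=pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS),
        config=config,
    )
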
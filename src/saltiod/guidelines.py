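"""WHO 2014 salt-fortification guideline model.

The 2014 WHO guidelines suggest an average amount of iodine to add to
food-grade salt as a function of estimated daily salt intake.  The
suggested concentrations follow a simple mass-balance model: a
population should receive the adult recommended nutrient intake (RNI)
of 150 μg iodine/day from salt after accounting for iodine losses
between production and the household (taken as 30%).  For a salt intake
of ``s`` g/day the amount to add is therefore::

    amount(s) = round_half_up( RNI × (1 + loss_fraction) / s )   [mg/kg]

which, with the default parameters, reproduces every cell of the
published 12-row lookup table for intakes of 3–14 g/day (65, 49, 39,
33, 28, 24, 22, 20, 18, 16, 15, 14 mg/kg).

Two evaluation modes are exposed:

``table``
    Round the intake half-up to the nearest integer on the 3–14 g/day
    grid (clamping to the grid edges) and return the published integer
    amount.  This is the mode that matches the printed guideline table.
``continuous``
    Evaluate the generating formula directly, without rounding.  This
    is the default for scoring because national salt-intake estimates
    are real-valued.

The guidelines also name the two recommended fortification compounds,
potassium iodate (KIO3) and potassium iodide (KI); the recommended set
lives on :class:`GuidelineParams` and drives compound classification in
:mod:`saltiod.standards`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
import yaml

from .errors import ConfigError, DomainError

__all__ = [
    "POTASSIUM_IODATE",
    "POTASSIUM_IODIDE",
    "GuidelineParams",
    "GuidelineTable",
    "IntakeOutOfRangeWarning",
    "round_half_up",
    "who_table",
    "who_iodine_amount",
]

#: Canonical identifiers of the two WHO-recommended iodine compounds.
POTASSIUM_IODATE = "potassium_iodate"
POTASSIUM_IODIDE = "potassium_iodide"

WhoMode = Literal["table", "continuous"]


class IntakeOutOfRangeWarning(UserWarning):
    """Salt intake falls outside the 3–14 g/day guideline grid."""


def round_half_up(x: float) -> int:
    """Round ``x`` to the nearest integer with ties going up.

    The guideline table rounds 19.5 → 20 and 32.5 → 33, so Python's
    built-in banker's rounding is not usable here.  Decimal arithmetic
    on the shortest repr avoids binary-float tie artefacts.
    """
    return int(Decimal(repr(x)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GuidelineParams:
    """Constants of the WHO 2014 salt-fortification model.

    Parameters
    ----------
    rni_ug_per_day:
        Recommended nutrient intake for iodine, μg/day.  Default 150
        (mean adult RNI).
    loss_fraction:
        Proportion of added iodine lost between production and the
        household, dimensionless.  Default 0.30.
    bioavailability:
        Proportion of ingested iodine absorbed.  Recorded for
        completeness (the guidelines cite 92%) but the published table
        is reproduced by the RNI-plus-losses formula alone, so this
        constant enters no computation in this package.
    intake_grid_g_per_day:
        The integer salt-intake grid of the published table, g/day.
    recommended_compounds:
        Canonical identifiers of the WHO-recommended fortification
        compounds.
    """

    rni_ug_per_day: float = 150.0
    loss_fraction: float = 0.30
    bioavailability: float = 0.92
    intake_grid_g_per_day: tuple[int, ...] = tuple(range(3, 15))
    recommended_compounds: frozenset[str] = frozenset(
        {POTASSIUM_IODATE, POTASSIUM_IODIDE}
    )

    def __post_init__(self) -> None:
        if not self.rni_ug_per_day > 0:
            raise ConfigError("rni_ug_per_day must be positive")
        if not 0 < self.loss_fraction < 1:
            raise ConfigError("loss_fraction must lie in (0, 1)")
        if not 0 < self.bioavailability <= 1:
            raise ConfigError("bioavailability must lie in (0, 1]")
        grid = self.intake_grid_g_per_day
        if len(grid) < 1 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigError("intake grid must be strictly increasing")
        if not self.recommended_compounds:
            raise ConfigError("recommended_compounds must be non-empty")

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "GuidelineParams":
        """Build params from a plain mapping (e.g. parsed YAML/JSON)."""
        kwargs: dict = dict(data)
        if "intake_grid_g_per_day" in kwargs:
            kwargs["intake_grid_g_per_day"] = tuple(
                int(v) for v in kwargs["intake_grid_g_per_day"]  # type: ignore[union-attr]
            )
        if "recommended_compounds" in kwargs:
            kwargs["recommended_compounds"] = frozenset(
                str(v) for v in kwargs["recommended_compounds"]  # type: ignore[union-attr]
            )
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "GuidelineParams":
        """Load parameter overrides from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: expected a mapping of parameter overrides")
        return cls.from_mapping(data)


#: Module-wide default parameter set.
DEFAULT_PARAMS = GuidelineParams()


@dataclass(frozen=True)
class GuidelineTable:
    """The 12-entry salt-intake → iodine-amount lookup table (mg/kg)."""

    entries: Mapping[int, int]

    def __post_init__(self) -> None:
        amounts = list(self.entries.values())
        if any(b >= a for a, b in zip(amounts, amounts[1:])):
            raise ConfigError("guideline amounts must strictly decrease with intake")

    def amount(self, salt_intake_g_day: int) -> int:
        """Return the tabulated amount for an integer grid intake."""
        try:
            return self.entries[int(salt_intake_g_day)]
        except KeyError:
            raise DomainError(
                f"salt intake {salt_intake_g_day} g/d is not on the guideline grid"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        """Table as a DataFrame with columns salt_intake_g_day, iodine_mg_kg."""
        return pd.DataFrame(
            {
                "salt_intake_g_day": list(self.entries),
                "iodine_mg_kg": list(self.entries.values()),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def who_table(params: GuidelineParams = DEFAULT_PARAMS) -> GuidelineTable:
    """Generate the guideline lookup table from the RNI-plus-losses formula.

    With default parameters this reproduces the published table exactly.
    """
    entries = {
        s: round_half_up(params.rni_ug_per_day * (1 + params.loss_fraction) / s)
        for s in params.intake_grid_g_per_day
    }
    return GuidelineTable(entries)


def who_iodine_amount(
    salt_intake_g_day: float,
    params: GuidelineParams = DEFAULT_PARAMS,
    mode: WhoMode = "continuous",
) -> float:
    """Suggested iodine amount to add to salt, mg iodine per kg salt.

    Parameters
    ----------
    salt_intake_g_day:
        Estimated daily salt intake, g/day.  Must be positive.  Intakes
        outside the guideline grid span raise
        :class:`IntakeOutOfRangeWarning` (the value is still returned;
        in table mode the intake is clamped to the grid edge).
    params:
        Guideline model constants.
    mode:
        ``"table"`` for the integer lookup table (intake rounded
        half-up to the nearest grid point), ``"continuous"`` for the
        unrounded generating formula.
    """
    if not salt_intake_g_day > 0:
        raise DomainError(f"salt intake must be positive, got {salt_intake_g_day}")
    grid = params.intake_grid_g_per_day
    lo, hi = grid[0], grid[-1]
    if not lo <= salt_intake_g_day <= hi:
        warnings.warn(
            f"salt intake {salt_intake_g_day} g/d is outside the guideline "
            f"grid [{lo}, {hi}] g/d",
            IntakeOutOfRangeWarning,
            stacklevel=2,
        )
    if mode == "continuous":
        return params.rni_ug_per_day * (1 + params.loss_fraction) / salt_intake_g_day
    if mode == "table":
        nearest = min(max(round_half_up(salt_intake_g_day), lo), hi)
        return float(who_table(params).amount(nearest))
    raise ConfigError(f"unknown mode {mode!r}; expected 'table' or 'continuous'")
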
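"""National salt-standard data model and normalization.

A country's salt standard specifies the iodine content of iodized salt
as a range, a minimum, or a single value, on either an elemental-iodine
or a compound-mass basis, together with the allowed fortification
compounds and the scope of the legislation (household salt, processed
food salt, or both).  This module normalizes raw standards to a single
recorded amount — the midpoint of a range, or the single/minimum
amount — in mg iodine per kg salt, mirroring how global fortification
databases standardize them to ppm, and classifies the allowed compounds
against the WHO-recommended set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from enum import Enum

from .errors import ConversionError, ValidationError
from .guidelines import (
    DEFAULT_PARAMS,
    POTASSIUM_IODATE,
    POTASSIUM_IODIDE,
    GuidelineParams,
)

__all__ = [
    "SpecForm",
    "Basis",
    "Scope",
    "CompoundCategory",
    "IodineSpec",
    "SaltStandard",
    "IODINE_MASS_FRACTION",
    "to_iodine_basis",
    "extract_midpoint",
    "canonicalize_compound",
    "classify_compounds",
]

logger = logging.getLogger(__name__)


class SpecForm(str, Enum):
    RANGE = "range"
    MINIMUM = "minimum"
    SINGLE = "single"


class Basis(str, Enum):
    IODINE = "iodine"
    COMPOUND = "compound"


class Scope(str, Enum):
    """Which salt streams the iodization legislation covers."""

    BOTH = "both"
    HOUSEHOLD_ONLY = "household_only"
    PROCESSED_ONLY = "processed_only"


class CompoundCategory(str, Enum):
    """Three-way partition of a standard's allowed compounds."""

    ALL_RECOMMENDED = "all_recommended"
    MIXED = "mixed"
    NONE_RECOMMENDED = "none_recommended"


# Iodine mass fractions from atomic masses K 39.098, I 126.904, O 16.000,
# Na 22.990, Ca 40.078.
_I = 126.904
IODINE_MASS_FRACTION: dict[str, float] = {
    POTASSIUM_IODATE: _I / (39.098 + _I + 3 * 16.000),  # KIO3, 0.5930
    POTASSIUM_IODIDE: _I / (39.098 + _I),  # KI, 0.7644
    "sodium_iodate": _I / (22.990 + _I + 3 * 16.000),  # NaIO3
    "sodium_iodide": _I / (22.990 + _I),  # NaI
    "calcium_iodate": 2 * _I / (40.078 + 2 * (_I + 3 * 16.000)),  # Ca(IO3)2
}

_SYNONYMS: dict[str, str] = {
    "kio3": POTASSIUM_IODATE,
    "iodate": POTASSIUM_IODATE,
    "potassium iodate": POTASSIUM_IODATE,
    "ki": POTASSIUM_IODIDE,
    "iodide": POTASSIUM_IODIDE,
    "potassium iodide": POTASSIUM_IODIDE,
    "naio3": "sodium_iodate",
    "sodium iodate": "sodium_iodate",
    "nai": "sodium_iodide",
    "sodium iodide": "sodium_iodide",
    "caio32": "calcium_iodate",
    "ca(io3)2": "calcium_iodate",
    "calcium iodate": "calcium_iodate",
}


@dataclass(frozen=True)
class IodineSpec:
    """Iodine content clause of a salt standard, mg/kg salt.

    ``form`` selects which amount fields are meaningful: a range uses
    ``low``/``high``, a minimum uses ``low``, a single value uses
    ``value``.  ``basis`` records whether the amounts are elemental
    iodine or mass of the fortification compound named by
    ``basis_compound``.
    """

    form: SpecForm
    low: float | None = None
    high: float | None = None
    value: float | None = None
    basis: Basis = Basis.IODINE
    basis_compound: str | None = None

    def __post_init__(self) -> None:
        form = SpecForm(self.form)
        object.__setattr__(self, "form", form)
        object.__setattr__(self, "basis", Basis(self.basis))
        if form is SpecForm.RANGE:
            if self.low is None or self.high is None:
                raise ValidationError("range spec requires low and high")
            if not (0 < self.low < self.high):
                raise ValidationError(
                    f"range spec requires 0 < low < high, got {self.low}–{self.high}"
                )
        elif form is SpecForm.MINIMUM:
            if self.low is None or not self.low > 0:
                raise ValidationError("minimum spec requires one positive amount")
        else:  # SINGLE
            if self.value is None or not self.value > 0:
                raise ValidationError("single spec requires one positive amount")
        if self.basis is Basis.COMPOUND:
            if self.basis_compound is None:
                raise ValidationError("compound basis requires basis_compound")
            if self.basis_compound not in IODINE_MASS_FRACTION:
                raise ConversionError(
                    f"no iodine mass fraction known for compound "
                    f"{self.basis_compound!r}"
                )

    def amounts(self) -> tuple[float, ...]:
        if self.form is SpecForm.RANGE:
            return (self.low, self.high)  # type: ignore[return-value]
        if self.form is SpecForm.MINIMUM:
            return (self.low,)  # type: ignore[return-value]
        return (self.value,)  # type: ignore[return-value]


@dataclass(frozen=True)
class SaltStandard:
    """One country's salt-iodization standard."""

    country: str
    issue_year: int
    spec: IodineSpec
    compounds: tuple[str, ...]
    scope: Scope = Scope.BOTH

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Za-z]{3}", self.country):
            raise ValidationError(f"country must be an ISO3 code, got {self.country!r}")
        object.__setattr__(self, "country", self.country.upper())
        object.__setattr__(self, "scope", Scope(self.scope))
        object.__setattr__(self, "compounds", tuple(self.compounds))
        if not 1900 <= int(self.issue_year) <= 2100:
            raise ValidationError(f"implausible issue year {self.issue_year}")
        if not self.compounds:
            raise ValidationError("compounds must be non-empty")


def canonicalize_compound(name: str) -> str:
    """Map a free-text compound name to a canonical identifier.

    Matching is case- and punctuation-insensitive ("KIO3", "iodate" and
    "Potassium Iodate" all map to ``potassium_iodate``).  Unknown names
    are preserved as slugged opaque identifiers — treated downstream as
    non-recommended — with a logged warning.
    """
    if not name or not name.strip():
        raise ValidationError("compound name must be a non-empty string")
    squeezed = re.sub(r"[^a-z0-9()]+", " ", name.strip().lower()).strip()
    if squeezed in _SYNONYMS:
        return _SYNONYMS[squeezed]
    compact = re.sub(r"[^a-z0-9]+", "", squeezed)
    if compact in _SYNONYMS:
        return _SYNONYMS[compact]
    slug = re.sub(r"\s+", "_", squeezed)
    if slug not in IODINE_MASS_FRACTION:
        logger.warning(
            "unknown iodine compound %r kept as opaque non-recommended id %r",
            name,
            slug,
        )
    return slug


def to_iodine_basis(spec: IodineSpec) -> IodineSpec:
    """Convert a compound-mass spec to elemental iodine, mg/kg.

    Amounts are multiplied by the compound's iodine mass fraction
    (0.5930 for potassium iodate, 0.7644 for potassium iodide).
    Iodine-basis specs are returned unchanged, making the operation
    idempotent.
    """
    if spec.basis is Basis.IODINE:
        return spec
    frac = IODINE_MASS_FRACTION.get(spec.basis_compound or "")
    if frac is None:
        raise ConversionError(
            f"no iodine mass fraction known for compound {spec.basis_compound!r}"
        )

    def conv(x: float | None) -> float | None:
        return None if x is None else x * frac

    return replace(
        spec,
        low=conv(spec.low),
        high=conv(spec.high),
        value=conv(spec.value),
        basis=Basis.IODINE,
        basis_compound=None,
    )


def extract_midpoint(spec: IodineSpec) -> float:
    """Single recorded iodine amount for a standard, mg/kg.

    Range → midpoint ``(low + high) / 2``; single → the stated value;
    minimum → the stated minimum, treated as the single recorded amount.
    The spec must already be on the elemental-iodine basis.
    """
    if spec.basis is not Basis.IODINE:
        raise ValidationError("extract_midpoint requires an iodine-basis spec")
    if spec.form is SpecForm.RANGE:
        return (spec.low + spec.high) / 2  # type: ignore[operator]
    if spec.form is SpecForm.MINIMUM:
        return float(spec.low)  # type: ignore[arg-type]
    return float(spec.value)  # type: ignore[arg-type]


def classify_compounds(
    compounds: list[str] | tuple[str, ...],
    params: GuidelineParams = DEFAULT_PARAMS,
) -> CompoundCategory:
    """Classify a standard's allowed compounds against the WHO set.

    All allowed compounds recommended → ``all_recommended``; none
    recommended → ``none_recommended``; otherwise ``mixed``.  The
    result is invariant to list order and duplicates.
    """
    if not compounds:
        raise ValidationError("compound list must be non-empty")
    members = set(compounds)
    recommended = members & params.recommended_compounds
    if recommended == members:
        return CompoundCategory.ALL_RECOMMENDED
    if not recommended:
        return CompoundCategory.NONE_RECOMMENDED
    return CompoundCategory.MIXED
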
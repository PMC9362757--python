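"""Exception hierarchy.

Everything derives from :class:`SaltiodError` so callers (and the CLI,
which maps validation failures to exit code 2) can catch package errors
without catching unrelated bugs.
"""


class SaltiodError(Exception):
    """Base class for all package errors."""


class DomainError(SaltiodError, ValueError):
    """An input value is outside the mathematical domain of an operation."""


class ValidationError(SaltiodError, ValueError):
    """A record or configuration violates a structural invariant."""


class ConversionError(SaltiodError, ValueError):
    """A compound-basis amount cannot be converted to elemental iodine."""


class ConfigError(SaltiodError, ValueError):
    """A configuration object is internally inconsistent."""


class InsufficientDataError(SaltiodError, ValueError):
    """Too few observations to compute the requested statistic."""


class UndefinedCorrelationError(SaltiodError, ValueError):
    """Correlation requested on a vector with zero variance."""
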
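"""Exception hierarchy.

All library errors derive from :class:`TumorGrowthError` so callers (and the
CLI) can catch one base class; the ValueError mixins keep duck-typed callers
working.
"""


class TumorGrowthError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(TumorGrowthError, ValueError):
    """A growth-law or treatment parameter violates its constraints."""


class DomainError(TumorGrowthError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InsufficientDataError(TumorGrowthError, ValueError):
    """Too few observations for the requested fit or forecast."""


class FitError(TumorGrowthError, RuntimeError):
    """The optimizer failed to converge; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ConfigurationError(TumorGrowthError, ValueError):
    """Inconsistent run configuration (e.g. missing untreated reference)."""


class DataValidationError(TumorGrowthError, ValueError):
    """Malformed input table; ``row`` is the 1-based data-row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row
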
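"""Exception hierarchy.

Every malformed input raises exactly one of these typed errors, so callers
(and the CLI exit-code mapping) can distinguish schema problems, value-level
validation failures and configuration mistakes.
"""


class NichepopError(Exception):
    """Base class for all package errors."""


class SchemaError(NichepopError):
    """A required column is missing or cannot be resolved through the schema map."""


class ValidationError(NichepopError):
    """Row-level invariant violation (bounds, duplicates, inconsistent sums)."""


class DegeneratePlotError(ValidationError):
    """A plot whose observations cannot support relative components (all-zero counts)."""


class UndefinedBreadthError(ValidationError):
    """Niche breadth requested for an all-zero importance-value row."""


class EmptySelectionError(ValidationError):
    """A query (e.g. census year) selected no records."""


class InsufficientHistoryError(ValidationError):
    """Trend analysis requested with fewer than two survey years."""


class ParameterError(NichepopError):
    """Invalid simulation or analysis parameter."""


class CollinearityError(NichepopError):
    """Explanatory matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "explanatory matrix is rank deficient; linearly dependent column(s): "
            + ", ".join(map(str, self.columns))
        )


class ConfigurationError(NichepopError):
    """Pipeline configuration is incomplete or inconsistent."""
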
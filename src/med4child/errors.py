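"""Exception hierarchy for the med4child package."""


class Med4ChildError(Exception):
    """Base class for all package errors."""


class ConfigurationError(Med4ChildError):
    """Invalid registry, mapping, or run configuration."""


class SchemaError(Med4ChildError):
    """Input table does not match the expected schema."""

    def __init__(self, message: str, missing_columns: list[str] | None = None):
        super().__init__(message)
        self.missing_columns = missing_columns or []


class MissingAnswerError(Med4ChildError):
    """An answer required for scoring is missing.

    Raised instead of silently scoring 0 so the missing-data policy
    (complete-case exclusion vs. score-zero) can act on it.
    """


class IncompleteRecordError(Med4ChildError):
    """A record cannot be scored under the complete-case policy."""


class DomainError(Med4ChildError, ValueError):
    """A value lies outside its scientifically valid domain."""


class UndefinedKappaError(Med4ChildError):
    """Cohen's kappa is undefined (expected agreement is exactly 1)."""


class InsufficientDataError(Med4ChildError):
    """Too few observations for the requested statistic."""


class RankDeficiencyError(Med4ChildError):
    """Regression design matrix is rank deficient (collinear covariates)."""
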
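"""Exception hierarchy shared across the pipeline stages."""


class HemobayesError(Exception):
    """Base class for all package errors."""


class ValidationError(HemobayesError):
    """Input table or configuration failed validation.

    Carries a ``report`` attribute: a list of human-readable strings, one
    per offending record or field.
    """

    def __init__(self, message: str, report: list[str] | None = None):
        super().__init__(message)
        self.report = report or []


class InsufficientDataError(HemobayesError):
    """Too few observations for the requested operation."""


class DomainError(HemobayesError):
    """A value lies outside the mathematical domain of an operation."""


class FitError(HemobayesError):
    """MCMC fitting failed or the data are degenerate for the family."""


class NotConvergedError(FitError):
    """A downstream stage refused a fit whose diagnostics failed."""


class SelectionError(HemobayesError):
    """Model selection impossible (fewer than two converged candidates)."""


class ConfigError(HemobayesError):
    """Inconsistent simulation or pipeline configuration."""
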
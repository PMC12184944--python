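"""Exception hierarchy shared across the package.

Every error raised by normcard derives from :class:`NormcardError`, so
callers (notably the CLI and the web service) can catch one base class and
translate it into an exit code or HTTP status.
"""


class NormcardError(Exception):
    """Base class for all normcard errors."""


class FormatError(NormcardError):
    """A document or table could not be parsed; the message names the offending path."""


class ModelValidationError(NormcardError):
    """A model violates schema invariants.

    Carries the full list of violations, not only the first one found.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "model validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class DomainError(NormcardError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class RangeError(NormcardError):
    """A predictor value lies outside the range a spline term is defined on."""


class QueryError(NormcardError):
    """A query is structurally wrong: missing predictor, unknown name, bad mode."""


class LinkOverflowError(DomainError):
    """A linear predictor is so large that the inverse link would overflow."""
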
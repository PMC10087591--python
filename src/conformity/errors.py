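"""Typed exceptions shared across the package.

Each maps to a distinct nonzero exit code in the command-line interface
(see :mod:`conformity.cli`).
"""


class ConformityError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ConformityError, ValueError):
    """A parameter or input value is outside its mathematical domain."""


class DegenerateInputError(DomainError):
    """An input hits a point where the model is undefined (e.g. a
    unanimity endpoint under anti-conformity, where the logistic map
    has no finite limit worth silently returning)."""


class ConfigError(ConformityError):
    """A configuration file is missing, malformed, or out of range."""


class InsufficientDataError(ConformityError):
    """Too few usable observations to estimate the requested model."""


class EstimationError(ConformityError):
    """Estimation is impossible or the optimizer failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
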
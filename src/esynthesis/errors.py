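"""Exception hierarchy shared across the package."""


class EsynthesisError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EsynthesisError):
    """Input file or configuration cannot be parsed into the expected shape."""


class ValidationError(EsynthesisError):
    """Parsed input violates a data-model invariant (e.g. events > n)."""


class DomainError(EsynthesisError):
    """A quantity left its mathematical domain (e.g. a rate outside [0, 1])."""


class InsufficientDataError(EsynthesisError):
    """Too few dose groups or data points for the requested operation."""


class FitError(EsynthesisError):
    """Nonlinear least squares failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(EsynthesisError):
    """Invalid run or network configuration."""
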
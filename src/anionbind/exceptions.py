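"""Exception hierarchy shared across the package."""


class AnionBindError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AnionBindError, ValueError):
    """An input violates a physical or mathematical domain constraint."""


class ConfigurationError(AnionBindError, ValueError):
    """Inconsistent model/parameter configuration (not a data problem)."""


class NumericalError(AnionBindError, RuntimeError):
    """A solver failed to converge; carries diagnostics where available."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class FitError(AnionBindError, RuntimeError):
    """All optimisation starts failed; per-start diagnostics attached."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class SchemaError(AnionBindError, ValueError):
    """A CSV file violates its schema; lists every violation found."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "schema validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )
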
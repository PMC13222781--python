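"""Exception hierarchy shared across the package."""


class PanelScrutinyError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PanelScrutinyError, ValueError):
    """A model parameter is outside its admissible domain."""


class SpecificationError(PanelScrutinyError, ValueError):
    """A model specification is internally inconsistent (e.g. implied
    correlations exceed 1, or a unique variance would be negative)."""


class SchemaError(PanelScrutinyError, ValueError):
    """Data labels/shape do not match what an operation requires."""


class DegenerateInputError(PanelScrutinyError, ZeroDivisionError):
    """A closed form hits a vanishing denominator (|r| = 1 and similar)."""


class ConvergenceError(PanelScrutinyError, RuntimeError):
    """An iterative fit failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(PanelScrutinyError, ValueError):
    """A pipeline configuration is invalid or self-contradictory."""
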
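"""Exception hierarchy shared across the pipeline stages."""


class PolartraitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PolartraitError, ValueError):
    """A numeric argument violates its stated domain (e.g. nonpositive abundance)."""


class DesignError(PolartraitError, ValueError):
    """An experimental design cannot support the requested analysis."""


class InsufficientDataError(PolartraitError, ValueError):
    """Too few usable observations to estimate anything."""


class InvalidDataError(PolartraitError, ValueError):
    """Observations exist but are unusable (non-finite logs, all-negative rates...)."""


class EmptySeriesError(InsufficientDataError):
    """A series became empty after blank correction / filtering."""


class FitError(PolartraitError, RuntimeError):
    """Nonlinear fit failed to converge after all starting points."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnidentifiableFitError(FitError):
    """The data carry no information on one or more parameters (e.g. flat rates)."""


class BootstrapUnstableError(PolartraitError, RuntimeError):
    """More than half of the bootstrap resamples failed to fit."""


class NoEnrichmentError(InvalidDataError):
    """Tracer source is not enriched above the baseline pool."""


class NormalizationError(InvalidDataError):
    """No positive growth rate available to normalize against."""


class LabelingError(PolartraitError, ValueError):
    """A sequence lacks the habitat/source label required by the scan."""


class ConfigurationError(PolartraitError, ValueError):
    """Pipeline or filter configuration is inconsistent."""


class EmptyAlignmentError(PolartraitError, ValueError):
    """Trimming removed every alignment column."""


class ClassificationError(PolartraitError, ValueError):
    """Residue sets do not form a classifiable convergence pattern."""
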
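"""Exception hierarchy shared across the pipeline.

CLI exit codes: ConfigError -> 2, DataError (and subclasses) -> 3,
ConvergenceError -> 4.
"""


class OxprofError(Exception):
    """Base class for all package errors."""


class ConfigError(OxprofError):
    """Invalid configuration (bad SDs, fractions outside [0, 1], ...)."""


class DataError(OxprofError):
    """Invalid or insufficient input data."""


class FormatError(DataError):
    """Malformed file content (channel mismatch, negative intensities)."""


class GeometryError(DataError):
    """Degenerate or out-of-bounds ROI geometry."""


class CapacityError(DataError):
    """Requested cell geometry cannot be placed without overlap."""


class EmptyCytoplasmError(DataError):
    """Every pixel of a neuron mask was excluded as nucleus/neuromelanin."""


class DegenerateDesignError(DataError):
    """Regression design with zero spread in the covariate."""


class DegenerateFitError(DataError):
    """Perfectly collinear fit; zero-width intervals are refused."""


class ConvergenceError(OxprofError):
    """MCMC run failed its acceptance diagnostics (R-hat / ESS)."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
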
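"""Exception types shared across the package."""


class NicheMechError(Exception):
    """Base class for all package-specific errors."""


class ConvergenceError(NicheMechError):
    """A nonlinear solve did not converge; carries the final residuals."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class NumericalValidityError(NicheMechError):
    """A computed field violates a physical validity requirement."""


class CalibrationError(NicheMechError):
    """Not enough (or degenerate) data to calibrate a cutoff."""


class UndefinedRatioError(NicheMechError):
    """A requested intensity ratio is undefined for this cell."""


class ConfigError(NicheMechError):
    """Invalid pipeline configuration (raised before any stage runs)."""


class StageError(NicheMechError):
    """A pipeline stage failed during execution."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
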
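"""Exception hierarchy for the pipeline.

Each failure mode that the command-line layer maps to a distinct exit code
gets its own class; everything inherits from :class:`IdhcalError` so callers
can catch the package's errors wholesale.
"""


class IdhcalError(Exception):
    """Base class for all idhcal errors."""


class ConfigurationError(IdhcalError, ValueError):
    """Invalid simulation or pipeline configuration."""


class LabelFormatError(IdhcalError, ValueError):
    """A label volume contains values outside the {0, 1, 2} convention."""


class EmptyTumorError(IdhcalError, ValueError):
    """A volume or count record contains no tumor voxels (labels 1 or 2)."""


class ShapeMismatchError(IdhcalError, ValueError):
    """Per-fold label maps of one subject disagree on grid shape."""


class LeakageError(IdhcalError, ValueError):
    """Calibration and evaluation cohorts share subject ids."""


class ConvergenceError(IdhcalError, RuntimeError):
    """MCMC failed its convergence diagnostics within the configured budget.

    Carries the offending diagnostics in :attr:`diagnostics`.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnfitCalibratorError(IdhcalError, RuntimeError):
    """A calibrator was used for prediction before (or despite) a failed fit."""
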
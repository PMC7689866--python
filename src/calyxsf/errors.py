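"""Exception hierarchy.

All library errors derive from :class:`CalyxSFError` so pipeline code can
catch one base class; most also derive from ``ValueError`` because they signal
invalid inputs.
"""


class CalyxSFError(Exception):
    """Base class for all calyxsf errors."""


class ParameterError(CalyxSFError, ValueError):
    """Invalid parameter values (negative counts, nonpositive exponents...)."""


class ProtocolError(CalyxSFError, ValueError):
    """Invalid stimulation protocol (empty intensity list, unsorted levels)."""


class GenerationError(CalyxSFError, RuntimeError):
    """Synthetic-volume generation failed (e.g. requested caps overlap)."""


class ConfigurationError(CalyxSFError, ValueError):
    """Analysis configuration incompatible with the data (e.g. sampling rate
    too low to resolve the smoothing window)."""


class NoiseEstimationError(CalyxSFError, RuntimeError):
    """No event-free baseline available to estimate noise."""


class InsufficientDataError(CalyxSFError, ValueError):
    """Too few observations for the requested statistic."""


class ThresholdError(CalyxSFError, ValueError):
    """Automatic thresholding impossible (e.g. constant-intensity volume)."""


class EmptySomaError(CalyxSFError, RuntimeError):
    """Soma segmentation produced no voxels."""


class StageError(CalyxSFError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
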
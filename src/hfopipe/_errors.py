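"""Exception types shared across the pipeline."""


class HfoPipeError(Exception):
    """Base class for all hfopipe-specific errors."""


class FormatError(HfoPipeError):
    """A recording or table file could not be parsed."""


class AliasingError(HfoPipeError, ValueError):
    """A requested oscillation frequency is at or above the Nyquist limit."""


class PlacementError(HfoPipeError, RuntimeError):
    """Synthetic events could not be placed without violating spacing rules."""


class DegenerateBaselineError(HfoPipeError, ValueError):
    """Peak thresholds are undefined because the baseline SD is zero."""


class DegenerateEpochError(HfoPipeError, ValueError):
    """A normalization constant for an epoch is zero."""


class DegenerateCohortError(HfoPipeError, ValueError):
    """A cohort-level normalization constant is zero."""


class TrainingDivergedError(HfoPipeError, RuntimeError):
    """Network training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")
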
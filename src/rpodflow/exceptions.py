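"""Exception hierarchy.

All rpodflow errors derive from :class:`RpodflowError` so callers can catch
the package's failures with one clause; validation-type errors also derive
from ``ValueError`` to behave naturally in generic code.
"""


class RpodflowError(Exception):
    """Base class for all rpodflow errors."""


class ValidationError(RpodflowError, ValueError):
    """Invalid argument or configuration (bad spec, out-of-range mode count...)."""


class FormatError(RpodflowError, ValueError):
    """On-disk data does not conform to the declared dialect."""


class DataError(RpodflowError, ValueError):
    """Numerically invalid data (non-finite values at valid grid points)."""


class InsufficientDataError(RpodflowError, ValueError):
    """Too few snapshots for the requested operation."""


class PipelineError(RpodflowError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage
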
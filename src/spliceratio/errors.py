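"""Exception types shared across the package."""


class SpliceRatioError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SpliceRatioError, ValueError):
    """A numeric argument violates a precondition (negative ratio, non-positive affinity, ...)."""


class DataValidationError(SpliceRatioError, ValueError):
    """An input table failed validation; the message names file/line/column where known."""


class WindowRejected(SpliceRatioError, ValueError):
    """A 3' splice-site window could not be extracted for an event.

    Carries a machine-readable ``reason`` (``"non_canonical"``,
    ``"out_of_bounds"``, ``"missing_contig"``).
    """

    def __init__(self, event_id: str, reason: str, detail: str = ""):
        self.event_id = event_id
        self.reason = reason
        msg = f"event {event_id}: window rejected ({reason})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class StageError(SpliceRatioError, RuntimeError):
    """A pipeline stage failed; names the stage and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
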
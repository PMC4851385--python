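"""Exception hierarchy shared across the package."""


class FibroquantError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(FibroquantError, ValueError):
    """A synthetic-data or hazard specification violates its invariants."""


class CalibrationError(FibroquantError, RuntimeError):
    """A moment-matching or color-calibration problem has no valid solution."""


class NoTissueError(FibroquantError, ValueError):
    """No tile passed the tissue-fraction floor; the section is effectively empty."""


class StageError(FibroquantError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
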
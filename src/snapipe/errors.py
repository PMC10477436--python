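"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`SnapipeError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` to behave naturally in generic code.
"""


class SnapipeError(Exception):
    """Base class for all snapipe errors."""


class InvalidLabelError(SnapipeError, ValueError):
    """An unknown group / nerve / condition label was supplied."""


class ConfigError(SnapipeError, ValueError):
    """A generator or pipeline configuration violates its invariants."""


class ArgumentError(SnapipeError, ValueError):
    """An operation received an out-of-contract argument."""


class DesignError(SnapipeError, ValueError):
    """A digital filter could not be designed or is unstable."""


class AlignmentError(SnapipeError, ValueError):
    """Two signals that must share sampling rate or grid do not."""


class FormatError(SnapipeError, ValueError):
    """A file on disk is missing required fields or cannot be parsed."""


class InsufficientDataError(SnapipeError, ValueError):
    """Too few trials / samples for the requested statistical operation."""


class StageError(SnapipeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
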
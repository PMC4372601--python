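"""Exception hierarchy for the pipeline.

Everything raised on bad input derives from :class:`MirsigError`, so callers
(and the CLI) can catch one type. ``FormatError`` is reserved for files whose
layout is wrong; ``ValidationError`` for values that parse but violate a
contract.
"""


class MirsigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirsigError):
    """A file does not have the expected columns/layout."""


class ValidationError(MirsigError):
    """A parsed value violates a domain contract."""


class InsufficientBlanksError(ValidationError):
    """Fewer than three blank spots survive trimming."""


class EmptyProfileError(MirsigError):
    """No probe on an array was called present."""


class DegenerateProfileError(MirsigError):
    """The median of background-corrected signals is not positive."""


class AbsentSpotError(MirsigError):
    """Background subtraction was requested for a spot not called present."""


class UndefinedCorrelationError(MirsigError):
    """Rank correlation requested against a constant vector."""


class PipelineError(MirsigError):
    """A pipeline stage failed; the message names the stage."""
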
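"""Exception hierarchy used across the pipeline.

All domain errors derive from :class:`HippodecodeError` so callers can catch
one base class; validation problems additionally derive from ``ValueError``
to behave well in generic numeric code.
"""


class HippodecodeError(Exception):
    """Base class for all errors raised by hippodecode."""


class InvalidParameterError(HippodecodeError, ValueError):
    """A parameter violates its documented precondition."""


class ShapeError(HippodecodeError, ValueError):
    """Array shapes or lengths are inconsistent."""


class InsufficientDataError(HippodecodeError, ValueError):
    """Not enough samples to carry out the requested fit or framing."""


class DegenerateInputError(HippodecodeError, ValueError):
    """Input is constant or otherwise carries no usable signal."""


class FormatError(HippodecodeError, ValueError):
    """A file on disk does not match the expected layout."""


class EmptyResultError(HippodecodeError, ValueError):
    """The operation would produce no output (e.g. no complete windows)."""
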
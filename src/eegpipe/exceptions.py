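"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`EegPipeError` so callers can catch the
package's failures without masking programming errors, while the concrete
classes also subclass the matching builtin (``ValueError``, ``KeyError``,
``OSError``) for idiomatic handling.
"""


class EegPipeError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(EegPipeError, ValueError):
    """A parameter object or input violates a documented precondition."""


class DegenerateInputError(ValidationError):
    """Input is degenerate for the requested statistic (e.g. constant signal)."""


class NoMatchError(EegPipeError, ArithmeticError):
    """A template found zero matches, making log of a zero frequency undefined."""

    def __init__(self, template_index: int, dimension: int):
        self.template_index = template_index
        self.dimension = dimension
        super().__init__(
            f"template {template_index} at embedding dimension {dimension} has "
            "zero matches under the exclude-self convention; the tolerance r is "
            "too small for this signal"
        )


class ChannelError(EegPipeError, KeyError):
    """A requested channel is absent from a recording or file."""

    def __init__(self, missing, available):
        self.missing = list(missing)
        self.available = list(available)
        super().__init__(
            f"missing channel(s) {self.missing}; available: {self.available}"
        )

    def __str__(self) -> str:  # KeyError repr-quotes its payload otherwise
        return self.args[0]


class FormatError(EegPipeError, OSError):
    """A file could not be parsed as any supported recording format."""


class EmptyOutputError(EegPipeError, ValueError):
    """An operation would produce no output (e.g. recording shorter than one window)."""
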
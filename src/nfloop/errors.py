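"""Exception hierarchy for the neurofeedback pipeline.

Every stage raises a named subclass of :class:`NfloopError` so callers (and
the CLI) can report structured, stage-attributable failures.
"""


class NfloopError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(NfloopError):
    """Invalid configuration (montage, filter spec, schedule, constants)."""


class ParseError(NfloopError):
    """Malformed input file; carries a human-readable location."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SignalError(NfloopError):
    """Invalid signal content (non-positive intensities, masked baseline...)."""


class TooShortToFilterError(SignalError):
    """Series shorter than the FIR tap count."""


class ChannelUnusableError(SignalError):
    """A montage group has no usable channel after artifact rejection."""


class BlockInvalidError(NfloopError):
    """Block cannot be analysed (fully masked baseline, too few samples)."""


class DegenerateMapError(NfloopError):
    """Feedback map cannot be fit (zero spread, too few surviving samples)."""


class InsufficientDataError(NfloopError):
    """Not enough observations for a statistic."""
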
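"""Exception hierarchy for the ecgcrypt pipeline.

Every stage raises a subclass of :class:`EcgCryptError` so callers (and the
CLI) can distinguish validation problems from genuine runtime failures.
"""


class EcgCryptError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(EcgCryptError, ValueError):
    """A configuration object violates its invariants."""


class InputError(EcgCryptError, ValueError):
    """An input signal or sequence violates a precondition."""


class FormatError(EcgCryptError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class EmptyInputError(EcgCryptError, ValueError):
    """A file or sequence was empty where data is required."""


class KeyNotFoundError(EcgCryptError, KeyError):
    """A requested label is absent from a signal container."""


class DegenerateRangeError(EcgCryptError, ValueError):
    """Min–max normalization of a constant sequence is undefined."""


class DivergenceError(EcgCryptError, RuntimeError):
    """Gradient refinement diverged; try a smaller learning rate."""


class NoIMFError(EcgCryptError, ValueError):
    """Decomposition produced no intrinsic mode functions."""


class TooShortError(EcgCryptError, ValueError):
    """The signal is too short for the requested operation."""
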
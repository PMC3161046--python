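"""Exception hierarchy used across the package."""


class SomAtlasError(Exception):
    """Base class for all errors raised by somatlas."""


class FormatError(SomAtlasError):
    """A file does not conform to the expected layout (header, field counts)."""


class ParseError(SomAtlasError):
    """A cell or row could not be parsed; the message names the location."""


class ValidationError(SomAtlasError):
    """Inputs violate a documented precondition or invariant."""


class StateError(SomAtlasError):
    """An operation was applied to data in the wrong scale/state."""
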
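"""Exception hierarchy shared across the package."""


class EPUError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(EPUError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(EPUError, ValueError):
    """Input data violates a documented invariant."""
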
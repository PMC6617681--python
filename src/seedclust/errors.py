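"""Exception types shared across the pipeline."""


class SeedclustError(Exception):
    """Base class for all package errors."""


class ValidationError(SeedclustError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(SeedclustError, ValueError):
    """A file could not be parsed; message carries the location."""
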
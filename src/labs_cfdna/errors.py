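"""Exception types shared across the package."""


class LabsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LabsError, ValueError):
    """A function argument is outside its documented domain."""


class ValidationError(LabsError, ValueError):
    """Input data violates a structural invariant (counts, coordinates, schema)."""


class ParseError(LabsError, ValueError):
    """A file could not be parsed; the message names the offending line."""
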
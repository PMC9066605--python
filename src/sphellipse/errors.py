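"""Exception types shared across the package."""


class SphellipseError(ValueError):
    """Base class for all sphellipse errors."""


class InvalidGeometryError(SphellipseError):
    """Raised for degenerate geometric input (zero vectors, parallel axes...)."""


class DomainError(SphellipseError):
    """Raised when a numeric argument lies outside its admissible domain."""


class ParseError(SphellipseError):
    """Raised when a JSON/CSV particle description is malformed."""
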
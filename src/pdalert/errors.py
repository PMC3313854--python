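"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data violate a documented contract (range, format, order)."""


class SchemaMismatchError(ValidationError):
    """Raised when two objects do not share the same attribute schema."""
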
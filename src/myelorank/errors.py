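"""Exception types shared across the package."""


class MyelorankError(Exception):
    """Base class for all package errors."""


class FormatError(MyelorankError):
    """Input file does not conform to the expected layout."""


class ValidationError(MyelorankError):
    """Input values violate a documented invariant."""
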
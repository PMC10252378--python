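"""Exception types shared across the package."""


class DriveStressError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(DriveStressError):
    """An operation received an empty signal, matrix, or window set."""


class InvalidSpecError(DriveStressError):
    """A filter or network specification cannot be realized for the given input."""


class SchemaError(DriveStressError):
    """A configuration or input file violates its schema."""
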
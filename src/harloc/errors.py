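"""Exception hierarchy shared by every harloc module."""


class HarlocError(Exception):
    """Base class for all package errors."""


class ValidationError(HarlocError):
    """An argument or domain object violates its invariants."""


class SchemaError(HarlocError):
    """A file's structure (columns, keys) does not match what was requested."""


class FormatError(HarlocError):
    """A file could not be parsed at all; the message carries a location."""


class DegenerateInputError(HarlocError):
    """Input is too degenerate for the operation (constant series, zero variance)."""
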
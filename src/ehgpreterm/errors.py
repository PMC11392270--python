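"""Exception hierarchy shared across the package."""


class EHGError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EHGError):
    """A record header or signal file could not be parsed."""


class UnsupportedRecordError(EHGError):
    """A record does not expose the three required EHG channels."""


class IntegrityError(EHGError):
    """A table violates an integrity constraint (duplicates, NaN, ...)."""


class ParameterError(EHGError, ValueError):
    """An operation was called with invalid parameters."""


class UndefinedValueError(EHGError):
    """A feature value is mathematically undefined for this input."""


class StratificationError(EHGError):
    """A class is too small to satisfy the requested stratified split."""
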
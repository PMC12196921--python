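"""Exception types shared across the package."""


class StarchMorphError(Exception):
    """Base class for all package errors."""


class InvalidGranuleError(StarchMorphError, ValueError):
    """A contour, hilum or measurement violates a geometric invariant."""


class InsufficientDataError(StarchMorphError, ValueError):
    """Too few observations for the requested statistic."""


class SchemaError(StarchMorphError, ValueError):
    """A granule table does not match the expected column mapping."""
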
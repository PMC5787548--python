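"""Exception hierarchy for normorph."""


class NormorphError(Exception):
    """Base class for all package errors."""


class ParseError(NormorphError):
    """A table or config file could not be parsed; the message names the location."""


class ValidationError(NormorphError):
    """Input data violates an invariant (duplicate visits, bad category, ...)."""


class SchemaVersionError(NormorphError):
    """A persisted normative database has an incompatible schema version."""


class IntegrityError(NormorphError):
    """A persisted normative database is truncated or corrupt."""


class InsufficientDataError(NormorphError):
    """Too few data points for the requested operation (key is skipped upstream)."""


class InsufficientControlsError(NormorphError):
    """Fewer matched controls than the configured floor; no silent fallback."""
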
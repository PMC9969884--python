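"""Exception hierarchy shared across the pipeline."""


class TcrPersistError(Exception):
    """Base class for all package errors."""


class FormatError(TcrPersistError):
    """An input file does not conform to the expected dialect."""


class ValidationError(TcrPersistError):
    """In-memory data violates an invariant (missing fields, bad ranges)."""


class ConfigError(TcrPersistError):
    """A configuration object is internally inconsistent."""


class UsageError(TcrPersistError):
    """An operation was called outside its contract (e.g. cross-pair persistence)."""
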
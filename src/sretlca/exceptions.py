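"""Exception hierarchy shared across the package."""


class SretlcaError(Exception):
    """Base class for all package errors."""


class ConfigError(SretlcaError):
    """A configuration value violates its contract (names the offending field)."""


class DataError(SretlcaError):
    """Input data violate a structural precondition (duplicates, range, ids)."""


class PipelineError(SretlcaError):
    """A pipeline stage failed; message carries the stage name."""
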
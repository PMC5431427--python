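"""Exception hierarchy shared across the pipeline stages."""


class OrganNetError(Exception):
    """Base class for all package errors."""


class ConfigError(OrganNetError, ValueError):
    """Invalid configuration value; message names the offending field."""


class ValidationError(OrganNetError, ValueError):
    """Malformed or inconsistent input data."""


class DegenerateInputError(OrganNetError, ValueError):
    """Input is structurally valid but degenerate for the requested statistic
    (e.g. an all-zero library, a single replicate per group, zero variance)."""


class BlockSizeError(OrganNetError, ValueError):
    """Gene count exceeds the single-block limit; blockwise decomposition is
    deliberately unsupported."""
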
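"""Exception types shared across the pipeline.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class ScvafError(Exception):
    """Base class for all package errors."""


class ConfigError(ScvafError):
    """Invalid or inconsistent configuration."""


class DataError(ScvafError):
    """Malformed, missing or inconsistent input data."""
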
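"""Exception hierarchy.

``CislncError`` is the base for everything this package raises on bad input
or bad configuration, so callers (and the CLI) can distinguish data problems
from programming errors.
"""


class CislncError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CislncError):
    """Invalid configuration (simulation or pipeline)."""


class DataError(CislncError):
    """Malformed, inconsistent, or missing input data."""


class PipelineError(CislncError):
    """A pipeline stage failed; the message names the stage and cause."""
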
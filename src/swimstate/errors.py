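"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration problems -> 2,
data/schema problems -> 3, degenerate analysis input -> 4.
"""


class SwimStateError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SwimStateError, ValueError):
    """An argument violates an operation's preconditions."""


class ConfigError(SwimStateError, ValueError):
    """A configuration value or document is invalid."""


class SchemaError(SwimStateError):
    """A session container is missing datasets or has an unsupported version."""


class FormatError(SwimStateError):
    """A table or log is internally inconsistent."""


class DegenerateInputError(SwimStateError):
    """Input is technically valid but statistically degenerate (e.g. constant)."""
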
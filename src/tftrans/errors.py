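"""Exception hierarchy for the tftrans pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, data errors
(FormatError / ValidationError / AlignmentError) -> 3, anything else -> 1.
"""


class TFTransError(Exception):
    """Base class for all tftrans errors."""


class ConfigError(TFTransError):
    """Invalid configuration value or combination."""


class FormatError(TFTransError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(TFTransError):
    """A well-formed file violates a domain invariant (range, uniqueness...)."""


class AlignmentError(TFTransError):
    """Two tables cannot be aligned on a common sample set."""
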
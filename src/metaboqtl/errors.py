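"""Exception hierarchy used across the pipeline.

Exit-code mapping for the CLI: ConfigError -> 2, DataError -> 3,
ConvergenceError -> 4.
"""


class MetaboQTLError(Exception):
    """Base class for all package errors."""


class ConfigError(MetaboQTLError):
    """Invalid configuration value (bad threshold, MAF range, h2 ...)."""


class DataError(MetaboQTLError):
    """Invalid or degenerate input data (singular design, empty table ...)."""


class ConvergenceError(MetaboQTLError):
    """An iterative fit failed to converge.

    Carries the last iterate so callers can inspect where it stalled.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
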
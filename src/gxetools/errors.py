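"""Exception hierarchy.

Validation problems (bad config, malformed input files) are distinguished
from runtime failures so the CLI can map them to distinct exit codes.
"""


class GxeToolsError(Exception):
    """Base class for all package errors."""


class ConfigError(GxeToolsError):
    """Invalid configuration or simulation parameters."""


class FormatError(GxeToolsError):
    """Malformed or inconsistent input file."""


class ValidationError(GxeToolsError):
    """Input data violates an invariant (negative FPKM, q outside [0,1], ...)."""
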
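"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config errors → 2, data errors → 3).
"""


class VisfeedbackError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(VisfeedbackError, ValueError):
    """Invalid configuration (schema violations, impossible parameter values)."""


class DataError(VisfeedbackError, ValueError):
    """Invalid or inconsistent data (malformed tables, shape mismatches, degenerate inputs)."""
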
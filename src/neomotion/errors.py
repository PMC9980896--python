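"""Exception hierarchy.

All package errors derive from :class:`NeomotionError` so callers (and the CLI,
which maps validation errors to exit code 2 and statistical degeneracies to 3)
can distinguish them from programming errors.
"""


class NeomotionError(Exception):
    """Base class for all neomotion errors."""


class ValidationError(NeomotionError, ValueError):
    """Malformed or inconsistent input data."""


class InvalidConfigError(NeomotionError, ValueError):
    """A configuration value outside its allowed domain."""


class EmptySelectionError(NeomotionError, ValueError):
    """An operation selected zero frames/scans where at least one is required."""


class DegenerateDataError(NeomotionError, ValueError):
    """Input is statistically degenerate (zero variance, constant series, ...)."""
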
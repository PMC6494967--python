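"""Exception hierarchy shared across the pipeline.

All package errors derive from :class:`NetpharmError` so callers can catch
one base class at the CLI boundary.
"""


class NetpharmError(Exception):
    """Base class for all errors raised by netpharm."""


class ConfigurationError(NetpharmError):
    """A parameter or column mapping is invalid (caller-side mistake)."""


class InputDataError(NetpharmError):
    """The input data violate a contract (duplicate ids, empty seeds, ...)."""


class FormatError(InputDataError):
    """A file does not conform to the expected text dialect."""


class ConvergenceError(NetpharmError):
    """Power iteration failed to reach the requested tolerance."""


class DegenerateNullError(NetpharmError):
    """The permutation null has zero spread; a Z-score is undefined."""
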
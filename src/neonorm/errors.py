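"""Exception hierarchy.

All errors raised on purpose by the package derive from :class:`NeonormError`
so callers can catch pipeline failures without masking genuine bugs.
"""


class NeonormError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeonormError):
    """An invalid configuration value; the message names the offending field."""


class InputError(NeonormError):
    """Inconsistent or malformed inputs (mismatched subjects, bad joins, ...)."""


class NumericalError(NeonormError):
    """A linear-algebra failure that survived the jitter escalation."""


class DegenerateDataError(NeonormError):
    """Zero-variance data where variation is required (constant predictor, ...)."""
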
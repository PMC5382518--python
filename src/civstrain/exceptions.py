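"""Exception hierarchy.

All failures raised by this package derive from :class:`CivstrainError` so
callers can distinguish pipeline failures from programming errors.
"""


class CivstrainError(Exception):
    """Base class for all package errors."""


class ParameterError(CivstrainError, ValueError):
    """A parameter violates its documented invariants."""


class DataError(CivstrainError, ValueError):
    """Input data is malformed or insufficient for the requested operation."""


class ExtractionError(CivstrainError, RuntimeError):
    """Tag-grid extraction failed (e.g. no harmonic peak above the noise floor)."""
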
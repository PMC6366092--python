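"""Exception hierarchy.

All package errors derive from :class:`AdmapError` so callers (and the CLI)
can distinguish domain failures from programming errors.
"""


class AdmapError(Exception):
    """Base class for all errors raised by admap."""


class InvalidSeparationError(AdmapError, ValueError):
    """Sequence separation k < 1 requested (a residue has no pair with itself)."""


class EmptyInputError(AdmapError, ValueError):
    """An operation that needs at least one input item received none."""


class DegenerateTraceError(AdmapError, ValueError):
    """A Cα trace with fewer than two residues cannot yield pair statistics."""


class NoStatisticsError(AdmapError, ValueError):
    """No residue pair of the query sequence has a significant table entry."""


class InvalidIntervalError(AdmapError, ValueError):
    """A 1-based inclusive interval is empty, reversed, or out of range."""


class SequenceError(AdmapError, ValueError):
    """A sequence contains letters outside the 20 standard codes (plus X)."""


class CalibrationError(AdmapError, ValueError):
    """Disorder-probability calibration received no admissible protein."""


class UndefinedMetricError(AdmapError, ZeroDivisionError):
    """An accuracy metric was requested on counts that leave it undefined."""


class ParseError(AdmapError, ValueError):
    """A file could not be parsed; the message carries location information."""


class ValidationError(AdmapError, ValueError):
    """Structured input violated a schema or an annotation invariant."""


class ConfigError(AdmapError, ValueError):
    """A configuration file contained unknown keys or invalid values."""
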
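"""Exception hierarchy for antwalks.

All package errors derive from :class:`AntwalksError` so callers can catch
one base class; the subclasses distinguish malformed files, inconsistent
data, undersized samples and bad parameters, which the pipeline maps to
distinct exit codes.
"""


class AntwalksError(Exception):
    """Base class for all antwalks errors."""


class FormatError(AntwalksError):
    """Input file does not match the expected format (missing columns, empty file)."""


class DataError(AntwalksError):
    """File parsed but content violates a data invariant (frame gaps, zero body axis)."""


class InsufficientDataError(DataError):
    """Too few observations to compute the requested quantity."""


class UndefinedMetricError(DataError):
    """Metric undefined for this input (e.g. zero path length)."""


class ParameterError(AntwalksError):
    """Invalid parameter value or combination."""
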
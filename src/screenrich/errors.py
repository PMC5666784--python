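"""Exception hierarchy for screenrich.

All package errors derive from :class:`ScreenrichError` so callers can catch
one base class; the CLI maps each subtype to a stage-tagged message and a
nonzero exit status.
"""


class ScreenrichError(Exception):
    """Base class for all screenrich errors."""


class ParameterError(ScreenrichError, ValueError):
    """An argument or configuration value is out of its admissible range."""


class MetadataError(ScreenrichError, ValueError):
    """Required screen metadata (e.g. score direction) is missing or invalid."""


class ValidationError(ScreenrichError, ValueError):
    """An input file failed validation; the message names the offending row."""


class UndefinedMetricError(ScreenrichError, ValueError):
    """A metric is requested on an input where it is mathematically undefined
    (e.g. ROC AUC on a single-class ranking)."""


class ComparisonError(ScreenrichError, ValueError):
    """Two reports cannot be compared (mismatched provenance or key sets)."""
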
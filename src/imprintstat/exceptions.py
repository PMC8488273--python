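"""Exception hierarchy for imprintstat.

Every error raised on purpose by the package derives from
:class:`ImprintstatError`, so callers can catch one type at the
pipeline boundary and keep analysing the remaining measures.
"""


class ImprintstatError(Exception):
    """Base class for all imprintstat errors."""


class SchemaError(ImprintstatError):
    """An input table is missing a required column or has the wrong layout."""


class ParseError(ImprintstatError):
    """A cell could not be parsed (carries the offending row number)."""


class ValidationError(ImprintstatError):
    """A loaded record violates a domain invariant."""


class DuplicateMeasurementError(ValidationError):
    """More than one row for the same (chick, region, hemisphere, measure)."""


class InsufficientDataError(ImprintstatError):
    """Too few observations for the requested statistic."""


class CalibrationError(ImprintstatError):
    """A gel standard curve cannot be fitted or is degenerate."""


class UndefinedScoreError(ImprintstatError):
    """Preference score undefined because total test approach is zero."""


class UnidentifiableModelError(ImprintstatError):
    """Regression cannot be fitted (e.g. all preference scores identical)."""
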
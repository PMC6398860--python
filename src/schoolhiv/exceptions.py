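"""Shared exception types."""


class SchoolHIVError(Exception):
    """Base class for package errors."""


class InvalidParameterError(SchoolHIVError, ValueError):
    """A parameter violates its documented domain."""


class MalformedHistoryError(SchoolHIVError, ValueError):
    """An HIV test history violates ordering invariants."""


class CollinearityError(SchoolHIVError, ValueError):
    """Design matrix is rank deficient; message names offending columns."""


class SeparationError(SchoolHIVError, ValueError):
    """A covariate perfectly predicts the outcome; message names the column."""


class UndefinedRatioError(SchoolHIVError, ZeroDivisionError):
    """Risk ratio undefined (zero events in the reference stratum)."""


class UndefinedBoundError(SchoolHIVError, ZeroDivisionError):
    """Selection bound undefined (zero variance of the control index)."""


class UnidentifiedModelError(SchoolHIVError, ValueError):
    """Requested coefficient is not identified on the given data."""
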
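"""Exception types shared across the package."""


class HotspotNacError(Exception):
    """Base class for package errors."""


class ValidationError(HotspotNacError, ValueError):
    """A configuration or input value violates a documented constraint.

    The message always names the offending field.
    """


class CohortIOError(HotspotNacError, IOError):
    """A cohort file could not be parsed; the message carries file (and,
    where the underlying parser reports one, line) information."""


class InsufficientPointsError(HotspotNacError, ValueError):
    """Too few points to estimate a similarity transform (need >= 3)."""


class NotFittedError(HotspotNacError, RuntimeError):
    """Prediction requested from a model that has not been fitted."""
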
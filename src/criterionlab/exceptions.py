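"""Package-specific error types.

All inherit from :class:`ValueError` so callers can catch broadly.
"""


class CriterionLabError(ValueError):
    """Base class for all criterionlab errors."""


class DegenerateModelError(CriterionLabError):
    """The generative model collapses (e.g. mu = 0 in a detection model, or
    equal category SDs in the embedded-category model) so the requested
    quantity is undefined."""


class BoundaryRateError(CriterionLabError):
    """A hit or false-alarm rate of exactly 0 or 1 reached the z-transform
    without finite-sample correction."""


class NoInteriorBoundaryError(CriterionLabError):
    """The prior is so extreme that one response is always optimal and no
    interior decision boundary exists for the embedded-category task."""


class NonIdentifiableFitError(CriterionLabError):
    """The trial data cannot constrain the fit (e.g. every response is
    identical)."""


class InsufficientDataError(CriterionLabError):
    """A condition is missing one of the truth classes needed to estimate
    hit and false-alarm rates."""
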
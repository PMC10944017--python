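"""Exception hierarchy shared across the pipeline stages."""


class C4DroughtError(Exception):
    """Base class for all package-specific errors."""


class StationarityError(C4DroughtError):
    """AR coefficients imply a non-stationary process (root inside unit circle)."""


class DegenerateSeriesError(C4DroughtError):
    """Series has zero residual variance after detrending."""


class InsufficientDataError(C4DroughtError):
    """Too few observations for the requested operation."""


class CollinearityError(C4DroughtError):
    """Regressor matrix is singular."""


class InvalidWeightsError(C4DroughtError):
    """Leaf weight triplet violates hydrated > dry."""


class InvalidHeightError(C4DroughtError):
    """Non-positive tiller height."""


class DegenerateCurveError(C4DroughtError):
    """A-Ci curve is flat or otherwise unfittable."""


class InvalidReferenceError(C4DroughtError):
    """Reference assimilation rate is zero or non-positive where positivity is required."""


class SchemaError(C4DroughtError):
    """Input file is missing mandatory columns or contains malformed rows."""
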
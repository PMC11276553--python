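"""Exception hierarchy shared by all cccm modules."""


class CCMError(Exception):
    """Base class for all errors raised by this package."""


class SeriesLengthError(CCMError, ValueError):
    """A time series is too short for the requested embedding or model."""


class DegenerateSeriesError(CCMError, ValueError):
    """An operation received a constant (zero-variance) or otherwise
    degenerate series for which the result is undefined."""


class NotEnoughNeighborsError(CCMError, ValueError):
    """A nearest-neighbor query does not have enough admissible candidates.

    Attributes
    ----------
    earliest_admissible : int or None
        Earliest query time (sample index) at which the search would have
        enough candidates, when that is well defined.
    """

    def __init__(self, message: str, earliest_admissible: int | None = None):
        super().__init__(message)
        self.earliest_admissible = earliest_admissible


class SingularFitError(CCMError, ValueError):
    """A least-squares design matrix is rank deficient."""
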
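"""Delay embedding (shadow-manifold construction) for scalar time series.

The state of a dynamical system observed through a single scalar variable
``X`` can be reconstructed (up to diffeomorphism) from delay-coordinate
vectors ``x_t = [X(t), X(t-tau), ..., X(t-(E-1)*tau)]`` — the shadow
manifold of ``X``.  Every cross-mapping operation in this package works on
these manifolds, so the index bookkeeping lives here and is shared by all
downstream modules.

Index convention: sample indices are 0-based and each delay vector is
stamped with the index of its *leading* (most recent) coordinate.  The
first admissible vector therefore has time ``(E-1)*tau`` and the manifold
has ``n - (E-1)*tau`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSeriesError, SeriesLengthError

__all__ = ["TimeSeries", "EmbeddingConfig", "ShadowManifold", "embed", "standardize"]


@dataclass(frozen=True)
class TimeSeries:
    """A named, uniformly sampled scalar sequence.

    Parameters
    ----------
    values : array-like of float
        The samples, length ``n >= 1``.  All values must be finite.
    name : str
        Label used in direction strings such as ``"X→Y"``.
    dt : float
        Sampling interval in arbitrary units (default 1).
    """

    values: np.ndarray
    name: str = "x"
    dt: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError(f"series {self.name!r}: values must be 1-D")
        if values.size < 1:
            raise ValueError(f"series {self.name!r}: at least one sample required")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"series {self.name!r}: values must be finite")
        if not self.dt > 0:
            raise ValueError(f"series {self.name!r}: dt must be positive")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


@dataclass(frozen=True)
class EmbeddingConfig:
    """Shadow-manifold parameters: dimension ``E`` and time lag ``tau``.

    ``E`` is the number of lagged coordinates per delay vector (>= 2) and
    ``tau`` the spacing between them in samples (>= 1).  The window spanned
    by one vector is ``(E-1)*tau`` samples; a series must be strictly longer
    than that to admit any vector.
    """

    E: int = 5
    tau: int = 1

    def __post_init__(self) -> None:
        if int(self.E) != self.E or self.E < 2:
            raise ValueError(f"E must be an integer >= 2, got {self.E}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"tau must be an integer >= 1, got {self.tau}")
        object.__setattr__(self, "E", int(self.E))
        object.__setattr__(self, "tau", int(self.tau))

    @property
    def window(self) -> int:
        """Span ``(E-1)*tau`` of one delay vector, in samples."""
        return (self.E - 1) * self.tau

    def min_length(self) -> int:
        """Smallest series length that admits at least one delay vector."""
        return self.window + 1


@dataclass(frozen=True)
class ShadowManifold:
    """A delay-vector matrix with per-row time stamps.

    ``points`` has one row per delay vector, ordered most-recent-first:
    row for time ``t`` is ``[X(t), X(t-tau), ..., X(t-(E-1)tau)]``.
    ``times`` holds the leading-coordinate sample index of each row and is
    strictly increasing.
    """

    points: np.ndarray
    times: np.ndarray
    config: EmbeddingConfig | None = None
    source_name: str = "x"

    def __post_init__(self) -> None:
        points = np.atleast_2d(np.asarray(self.points, dtype=float))
        times = np.asarray(self.times, dtype=np.intp)
        if points.shape[0] != times.shape[0]:
            raise ValueError("points and times must have the same row count")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "times", times)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def dim(self) -> int:
        return int(self.points.shape[1])

    def row_index(self, query_time: int) -> int:
        """Map a sample index to its manifold row, or raise KeyError."""
        i = int(np.searchsorted(self.times, query_time))
        if i >= self.n_points or self.times[i] != query_time:
            raise KeyError(f"no manifold row at time {query_time}")
        return i


def embed(series: TimeSeries, config: EmbeddingConfig) -> ShadowManifold:
    """Build the shadow manifold of ``series`` under ``config``.

    Returns all admissible delay vectors.  The row for leading time ``t``
    is ``[X(t), X(t-tau), ..., X(t-(E-1)tau)]``; leading times run from
    ``(E-1)*tau`` to ``n-1``.

    Raises
    ------
    SeriesLengthError
        If ``n < (E-1)*tau + 1``.
    """
    n = series.n
    if n < config.min_length():
        raise SeriesLengthError(
            f"series {series.name!r} has n={n} but (E={config.E}, tau={config.tau}) "
            f"requires at least n={config.min_length()}"
        )
    times = np.arange(config.window, n, dtype=np.intp)
    lags = np.arange(config.E) * config.tau
    points = series.values[times[:, None] - lags[None, :]]
    return ShadowManifold(points=points, times=times, config=config,
                          source_name=series.name)


def standardize(series: TimeSeries) -> TimeSeries:
    """Return ``series`` shifted and scaled to zero mean, unit variance.

    Population variance (ddof=0) is used: the result is only consumed for
    distance-scale alignment ahead of joint multivariate embedding, where
    any consistent convention works.

    Raises
    ------
    DegenerateSeriesError
        If the series is constant (or has fewer than two samples).
    """
    if series.n < 2:
        raise DegenerateSeriesError(
            f"series {series.name!r}: need n >= 2 to standardize"
        )
    sd = float(np.std(series.values))
    if sd == 0.0:
        raise DegenerateSeriesError(
            f"series {series.name!r} is constant; standardization undefined"
        )
    values = (series.values - np.mean(series.values)) / sd
    return TimeSeries(values=values, name=series.name, dt=series.dt)
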
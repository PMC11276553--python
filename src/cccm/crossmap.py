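"""Convergent cross mapping (CCM) and its causalized variant (cCCM).

Cross mapping estimates the current value of a target series from the
nearest-neighbor structure of a source series' shadow manifold: if the two
share an attractor, neighbors of ``x_t`` on ``M_x`` index times at which
the target was close to its current value, so the weighted average of the
target over those times is a good reconstruction.  The cross-map skill
``rho = corr(target, reconstruction)`` measures the causal influence of the
target on the source's dynamics (conventionally labelled source→target).

Classic CCM searches neighbors over the whole library, so the present is
reconstructed partly from the future.  The causalized variant (cCCM)
restricts the neighbor search to strictly earlier time indices (t_i < t),
which makes the estimate consistent with the usual definition of causality
and ties it to directed information: for stationary ergodic Gaussian pairs
the average directed information rate is approximately
``-0.5 * log2(1 - rho_cCCM^2)`` bits per sample (see :func:`di_from_rho`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import EmbeddingConfig, ShadowManifold, TimeSeries, embed
from .exceptions import (
    DegenerateSeriesError,
    NotEnoughNeighborsError,
    SeriesLengthError,
)

__all__ = [
    "NeighborSet",
    "CrossMapResult",
    "ConvergenceCurve",
    "NoiseAttenuation",
    "knn",
    "weights",
    "cross_map",
    "convergence_curve",
    "di_from_rho",
    "rho_under_error",
]

Mode = Literal["ccm", "cccm"]


def _check_mode(mode: str) -> str:
    if mode not in ("ccm", "cccm"):
        raise ValueError(f"mode must be 'ccm' or 'cccm', got {mode!r}")
    return mode


@dataclass(frozen=True)
class NeighborSet:
    """The k nearest manifold rows to one query row.

    ``times`` are sample indices ordered closest-to-farthest, ``distances``
    the matching Euclidean distances (nondecreasing).  In cccm mode every
    neighbor time is strictly smaller than ``query_time``; in ccm mode the
    query itself is excluded but future rows are admissible.
    """

    query_time: int
    times: np.ndarray
    distances: np.ndarray
    mode: str = "cccm"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=np.intp))
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=float))


@dataclass(frozen=True)
class CrossMapResult:
    """Outcome of one directional cross map.

    ``direction`` is ``"source→target"``: the target is reconstructed from
    the source's shadow manifold.  ``rho`` is the Pearson correlation
    between target and reconstruction over ``valid_range`` (inclusive
    first/last predicted sample index), ``mse`` the mean squared
    reconstruction error over the same range.
    """

    direction: str
    mode: str
    rho: float
    mse: float
    predictions: np.ndarray
    times: np.ndarray
    valid_range: tuple[int, int]
    config: EmbeddingConfig


@dataclass(frozen=True)
class ConvergenceCurve:
    """Cross-map skill in both directions over a grid of library lengths."""

    library_lengths: np.ndarray
    rhos_xy: np.ndarray
    rhos_yx: np.ndarray
    mode: str


@dataclass(frozen=True)
class NoiseAttenuation:
    """Signal/estimation-error standard deviations for the analytic
    attenuation formula ``rho = sigma_y / sqrt(sigma_y^2 + sigma_e^2)``."""

    sigma_y: float
    sigma_e: float

    def __post_init__(self) -> None:
        if not self.sigma_y > 0:
            raise ValueError("sigma_y must be positive")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be nonnegative")


# ---------------------------------------------------------------------------
# neighbor search
# ---------------------------------------------------------------------------

def knn(manifold: ShadowManifold, query_time: int, k: int,
        mode: Mode = "cccm", theiler: int = 0) -> NeighborSet:
    """Exact k-nearest-neighbor search for one manifold row.

    Candidates are restricted by ``mode``: strictly earlier rows for cccm,
    all rows except the query itself for ccm.  ``theiler`` additionally
    excludes rows within that many samples of the query (default 0, i.e.
    no temporal exclusion beyond the mode's own rule).  Distance ties are
    broken by smaller time index so results are platform deterministic.
    """
    _check_mode(mode)
    i = manifold.row_index(int(query_time))
    times = manifold.times
    if mode == "cccm":
        admissible = times < query_time
    else:
        admissible = times != query_time
    if theiler > 0:
        admissible &= np.abs(times - query_time) > theiler
    cand = np.flatnonzero(admissible)
    if cand.size < k:
        earliest = None
        if mode == "cccm" and k + theiler < manifold.n_points:
            earliest = int(times[k + theiler])
        raise NotEnoughNeighborsError(
            f"query at t={query_time} has {cand.size} admissible rows "
            f"({mode} mode) but k={k} are required",
            earliest_admissible=earliest,
        )
    diffs = manifold.points[cand] - manifold.points[i]
    dists = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
    order = np.lexsort((times[cand], dists))[:k]
    sel = cand[order]
    return NeighborSet(query_time=int(query_time), times=times[sel],
                       distances=dists[order], mode=mode)


def weights(neighbors: NeighborSet | np.ndarray) -> np.ndarray:
    """Exponential cross-map weights from neighbor distances.

    ``w_i = u_i / sum_j u_j`` with ``u_i = exp(-d_i / d_1)`` where ``d_1``
    is the nearest distance.  If ``d_1 == 0`` (exact manifold duplicates)
    the weight is split uniformly over all zero-distance neighbors — the
    limit of the formula for exact matches — and is zero elsewhere.
    """
    d = neighbors.distances if isinstance(neighbors, NeighborSet) else np.asarray(
        neighbors, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("distances must be a nonempty 1-D vector")
    if d[0] == 0.0:
        u = (d == 0.0).astype(float)
    else:
        u = np.exp(-d / d[0])
    return u / u.sum()


def _batch_weights(d: np.ndarray) -> np.ndarray:
    """Row-wise version of :func:`weights` for an (m, k) distance array."""
    d1 = d[:, :1]
    zero_first = d1 == 0.0
    with np.errstate(invalid="ignore"):  # NaN rows stay NaN without warning
        u = np.where(zero_first, (d == 0.0).astype(float),
                     np.exp(-d / np.where(zero_first, 1.0, d1)))
        return u / u.sum(axis=1, keepdims=True)


def _crossmap_predictions(manifold: ShadowManifold, target_values: np.ndarray,
                          k: int, mode: str, theiler: int = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Cross-map ``target_values`` from ``manifold`` at every admissible row.

    Returns ``(times, predictions)`` where ``times`` are the predicted
    sample indices.  This is the shared engine behind bivariate cross
    mapping and the multivariate conditional variant; the ccm/cccm query
    admissibility and the deterministic tie-break (stable sort ⇒ smaller
    time wins) live here.
    """
    m = manifold.n_points
    times = manifold.times
    if mode == "cccm":
        first_row = k + theiler  # first row with k strictly-past candidates
        if first_row >= m:
            raise NotEnoughNeighborsError(
                f"manifold has {m} rows; cccm mode needs at least {k + theiler + 1} "
                f"to admit one query (k={k})",
                earliest_admissible=None,
            )
    else:
        if m - 1 - 2 * theiler < k:
            raise NotEnoughNeighborsError(
                f"manifold has {m} rows but ccm mode needs k={k} candidates "
                "besides the query")
        first_row = 0

    D = cdist(manifold.points, manifold.points)
    if mode == "cccm":
        # candidate row j admissible for query row i iff j < i (- theiler)
        iu = np.triu_indices(m, k=-theiler)
        D[iu] = np.inf
    else:
        np.fill_diagonal(D, np.inf)
        for off in range(1, theiler + 1):
            idx = np.arange(m - off)
            D[idx, idx + off] = np.inf
            D[idx + off, idx] = np.inf
    D = D[first_row:]
    # stable sort: ties broken by smaller row index, i.e. smaller time
    nbr = np.argsort(D, axis=1, kind="stable")[:, :k]
    d = np.take_along_axis(D, nbr, axis=1)
    w = _batch_weights(d)
    preds = np.einsum("ij,ij->i", w, target_values[times[nbr]])
    return times[first_row:], preds


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise DegenerateSeriesError(
            "Pearson correlation undefined: constant vector over the valid range")
    return float(np.corrcoef(a, b)[0, 1])


def cross_map(source: TimeSeries, target: TimeSeries, config: EmbeddingConfig,
              mode: Mode = "cccm", library_length: int | None = None,
              theiler: int = 0) -> CrossMapResult:
    """Reconstruct ``target`` from the shadow manifold of ``source``.

    For each admissible time ``t`` the reconstruction is the weighted
    average of the target over the ``E+1`` nearest neighbors of ``x_t``
    (strictly-past neighbors in cccm mode).  ``rho`` and ``mse`` are
    computed over the predicted range only.  With ``library_length`` both
    series are first truncated to their first ``library_length`` samples,
    which is how convergence with data length is probed.
    """
    _check_mode(mode)
    if source.n != target.n:
        raise SeriesLengthError(
            f"source ({source.n}) and target ({target.n}) lengths differ")
    tv = target.values
    if library_length is not None:
        if not 1 <= library_length <= source.n:
            raise SeriesLengthError(
                f"library_length={library_length} outside [1, n={source.n}]")
        source = TimeSeries(source.values[:library_length], name=source.name,
                            dt=source.dt)
        tv = tv[:library_length]
    manifold = embed(source, config)
    k = config.E + 1
    times, preds = _crossmap_predictions(manifold, tv, k, mode, theiler)
    truth = tv[times]
    rho = _pearson(truth, preds)
    mse = float(np.mean((truth - preds) ** 2))
    return CrossMapResult(
        direction=f"{source.name}→{target.name}",
        mode=mode,
        rho=rho,
        mse=mse,
        predictions=preds,
        times=times,
        valid_range=(int(times[0]), int(times[-1])),
        config=config,
    )


def convergence_curve(x: TimeSeries, y: TimeSeries, config: EmbeddingConfig,
                      mode: Mode = "cccm",
                      lengths: Sequence[int] = (256, 512, 1024, 2048)
                      ) -> ConvergenceCurve:
    """Cross-map skill in both directions over a grid of library lengths.

    Convergence of the skill as the library grows is the operational
    signature of causal coupling; independent series fluctuate near zero
    without converging upward.
    """
    lengths = np.asarray(sorted(int(l) for l in lengths), dtype=np.intp)
    if lengths.size == 0:
        raise ValueError("lengths grid must be nonempty")
    if np.unique(lengths).size != lengths.size:
        raise ValueError("lengths grid must not contain duplicates")
    if lengths[-1] > x.n:
        raise SeriesLengthError(
            f"max library length {lengths[-1]} exceeds series length {x.n}")
    rhos_xy, rhos_yx = [], []
    for length in lengths:
        try:
            rhos_xy.append(cross_map(x, y, config, mode, library_length=int(length)).rho)
            rhos_yx.append(cross_map(y, x, config, mode, library_length=int(length)).rho)
        except (NotEnoughNeighborsError, SeriesLengthError) as exc:
            raise SeriesLengthError(
                f"library length {length} admits no prediction: {exc}") from exc
    return ConvergenceCurve(library_lengths=lengths,
                            rhos_xy=np.asarray(rhos_xy),
                            rhos_yx=np.asarray(rhos_yx), mode=mode)


# ---------------------------------------------------------------------------
# analytic helpers
# ---------------------------------------------------------------------------

def di_from_rho(rho: float) -> float:
    """Average directed information implied by a cCCM skill, in bits/sample.

    For stationary ergodic Gaussian pairs the directed information rate is
    approximately ``-0.5 * log2(1 - rho^2)``.  Defined for ``|rho| < 1``;
    at ``|rho| = 1`` the information is infinite.
    """
    rho = float(rho)
    if abs(rho) >= 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    return -0.5 * float(np.log2(1.0 - rho * rho))


def rho_under_error(noise: NoiseAttenuation) -> float:
    """Attenuated correlation under additive, independent estimation error.

    Modelling the reconstruction as ``Yhat = Y + n_e`` with error variance
    ``sigma_e^2`` independent of ``Y`` gives
    ``corr(Y, Yhat) = sigma_y / sqrt(sigma_y^2 + sigma_e^2)``, so the skill
    decreases monotonically as the estimation-error power grows.
    """
    return noise.sigma_y / float(np.hypot(noise.sigma_y, noise.sigma_e))
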
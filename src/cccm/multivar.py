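"""Multivariate conditional cCCM via the causality ratio.

Bivariate cross mapping cannot tell a genuine link X→Y from a common
driver Z that moves both.  The conditional extension asks how much the
cross-map error of the target shrinks when the candidate source joins a
joint predictor manifold that already contains the conditioning set:

    ratio(X_j -> X_i | S) = [Var(e_i | S) - Var(e_i | S + {X_j})] / Var(e_i | S)

where ``e_i | P`` is the error of cross-mapping X_i from the joint delay
embedding of the predictor set P, with strictly-past (cccm) neighbor
search.  A confounded pair collapses to a ratio near zero once the
confounder is conditioned on, while a genuine source keeps a large ratio.

Each predictor series is standardized before joint embedding so no single
block dominates the Euclidean metric; the ratio itself is variance
normalized and invariant to rescaling any input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .crossmap import _crossmap_predictions
from .embedding import (
    EmbeddingConfig,
    ShadowManifold,
    TimeSeries,
    embed,
    standardize,
)
from .exceptions import DegenerateSeriesError, SeriesLengthError

__all__ = [
    "VariableSet",
    "ConditionalResult",
    "joint_embed",
    "conditional_error_variance",
    "conditional_cccm",
]


@dataclass(frozen=True)
class VariableSet:
    """A collection of equal-length, uniquely named time series."""

    series: tuple[TimeSeries, ...]

    def __init__(self, series: Iterable[TimeSeries]):
        series = tuple(series)
        if not series:
            raise ValueError("VariableSet requires at least one series")
        names = [s.name for s in series]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate series names in {names}")
        lengths = {s.n for s in series}
        if len(lengths) > 1:
            raise SeriesLengthError(
                f"all series must share one length, got {sorted(lengths)}")
        object.__setattr__(self, "series", series)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.series]

    @property
    def n(self) -> int:
        return self.series[0].n

    def __len__(self) -> int:
        return len(self.series)

    def __getitem__(self, name: str) -> TimeSeries:
        for s in self.series:
            if s.name == name:
                return s
        raise KeyError(f"no series named {name!r}; have {self.names}")


@dataclass(frozen=True)
class ConditionalResult:
    """Causality ratio of source→target given a conditioning set.

    ``var_without``/``var_with`` are the cross-map error variances of the
    target from the conditioning predictors excluding/including the
    source; ``ratio = (var_without - var_with) / var_without``.  The ratio
    is at most 1 and may be slightly negative through sampling noise.
    """

    source: str
    target: str
    conditioning: tuple[str, ...]
    var_without: float
    var_with: float
    ratio: float


def joint_embed(vars: VariableSet, subset: Sequence[str],
                config: EmbeddingConfig) -> ShadowManifold:
    """Joint delay embedding of a subset of variables.

    Each series in ``subset`` is standardized and delay-embedded; rows are
    the concatenation of the per-series delay vectors at the same leading
    time, giving width ``E * len(subset)``.  Pairwise row distances are
    invariant to the order of ``subset``.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    manifolds = [embed(standardize(vars[name]), config) for name in subset]
    points = np.hstack([m.points for m in manifolds])
    return ShadowManifold(points=points, times=manifolds[0].times,
                          config=config, source_name="+".join(subset))


def _error_vector(vars: VariableSet, target: str, predictors: Sequence[str],
                  config: EmbeddingConfig, mode: str, k: int | None,
                  theiler: int) -> tuple[np.ndarray, np.ndarray]:
    """(times, errors) of cross-mapping ``target`` from a joint manifold."""
    manifold = joint_embed(vars, predictors, config)
    if k is None:
        k = config.E + 1
    tv = vars[target].values
    times, preds = _crossmap_predictions(manifold, tv, k, mode, theiler)
    return times, tv[times] - preds


def conditional_error_variance(vars: VariableSet, target: str,
                               predictors: Sequence[str],
                               config: EmbeddingConfig, mode: str = "cccm",
                               k: int | None = None, theiler: int = 0,
                               include_target: bool = False) -> float:
    """Variance of the target's cross-map error from a joint predictor set.

    The target is predicted (unstandardized) from the joint manifold of
    ``predictors`` using past-only neighbors and ``k = E + 1`` neighbors by
    default, the same neighbor count as the bivariate cross map regardless
    of the joint dimension.  Holding ``k`` fixed across predictor sets
    keeps the error variances of the with/without-source manifolds
    comparable, which is what the causality ratio requires; ``k`` is
    overridable for sensitivity analysis.  By default the target may not
    appear among its own predictors: including
    its current-valued delay vector makes self-prediction near perfect and
    voids the causality ratio.  Pass ``include_target=True`` to allow the
    literal inclusion for sensitivity analysis.
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("predictors must be nonempty")
    if target in predictors and not include_target:
        raise ValueError(
            f"target {target!r} is among its own predictors; pass "
            "include_target=True to force the literal inclusion")
    _, err = _error_vector(vars, target, predictors, config, mode, k, theiler)
    return float(np.var(err))


def conditional_cccm(vars: VariableSet, source: str, target: str,
                     conditioning: Sequence[str], config: EmbeddingConfig,
                     mode: str = "cccm", k: int | None = None,
                     theiler: int = 0) -> ConditionalResult:
    """Causality ratio of ``source``→``target`` given ``conditioning``.

    Both error variances are population variances computed over the
    intersection of the two valid prediction ranges, so the ratio compares
    like with like.  An empty conditioning set is rejected: without it the
    quantity degenerates to a two-set comparison, not a conditional one.

    Raises
    ------
    DegenerateSeriesError
        If the target is perfectly explained without the source
        (``var_without == 0``), which leaves the ratio undefined.
    """
    conditioning = list(conditioning)
    if source == target:
        raise ValueError("source and target must differ")
    if not conditioning:
        raise ValueError("conditioning set must be nonempty; use bivariate "
                         "cross_map for the unconditional question")
    if source in conditioning or target in conditioning:
        raise ValueError("conditioning set must exclude source and target")
    without_pred = conditioning
    with_pred = conditioning + [source]
    t_wo, e_wo = _error_vector(vars, target, without_pred, config, mode, k,
                               theiler)
    t_wi, e_wi = _error_vector(vars, target, with_pred, config, mode, k,
                               theiler)
    # restrict both error vectors to the common prediction range so the
    # two variances compare like with like
    start = max(t_wo[0], t_wi[0])
    e_wo = e_wo[np.searchsorted(t_wo, start):]
    e_wi = e_wi[np.searchsorted(t_wi, start):]
    var_wo = float(np.var(e_wo))
    var_wi = float(np.var(e_wi))
    if var_wo == 0.0:
        raise DegenerateSeriesError(
            f"target {target!r} is perfectly explained by {conditioning}; "
            "causality ratio undefined")
    return ConditionalResult(source=source, target=target,
                             conditioning=tuple(conditioning),
                             var_without=var_wo, var_with=var_wi,
                             ratio=(var_wo - var_wi) / var_wo)
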
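"""Granger causality (GC) for side-by-side comparison with cCCM.

GC asks whether past values of X improve a linear autoregressive
prediction of Y beyond Y's own past:

    restricted:  Y_i = sum_{j=1..K} a_j Y_{i-j} + e_i
    full:        Y_i = sum_{j=1..K} b_j Y_{i-j} + sum_{j=1..L} c_j X_{i-j} + f_i

    GC(X -> Y) = ln( var(e) / var(f) )

Both regressions use strictly past lags (j >= 1) and, by default, no
intercept.  The absence of a lag-0 term is the mechanism behind GC's
blind spot: a channel whose coupling is instantaneous produces a near-zero
GC even when the coupling is strong, whereas cross mapping still sees it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .embedding import TimeSeries
from .exceptions import SeriesLengthError, SingularFitError
from .multivar import VariableSet

__all__ = ["GcResult", "granger_bivariate", "granger_conditional"]


@dataclass(frozen=True)
class GcResult:
    """Restricted/full residual variances and their log-ratio.

    ``gc = ln(var_restricted / var_full)`` is nonnegative up to numerical
    noise for nested least-squares fits on the same sample window.
    """

    direction: str
    order_restricted: int
    order_full: tuple[int, int]
    var_restricted: float
    var_full: float
    gc: float


def _lag_block(values: np.ndarray, order: int, start: int) -> np.ndarray:
    """Columns [v_{i-1}, ..., v_{i-order}] for i = start .. n-1."""
    n = values.size
    return np.column_stack([values[start - j:n - j] for j in range(1, order + 1)])


def _ols_residual_var(X: np.ndarray, y: np.ndarray, intercept: bool) -> float:
    if intercept:
        X = np.column_stack([np.ones(len(y)), X])
    if X.shape[0] <= X.shape[1]:
        raise SeriesLengthError(
            f"{X.shape[0]} observations cannot identify {X.shape[1]} coefficients")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularFitError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)")
    resid = y - X @ coef
    return float(np.mean(resid ** 2))


def granger_bivariate(x: TimeSeries, y: TimeSeries, K: int = 5, L: int = 5,
                      intercept: bool = False) -> GcResult:
    """GC(x -> y) from two no-intercept least-squares fits.

    Both models are fitted over the common window ``i in [max(K, L), n)``
    and residual variances use the population (1/n_window) normalization,
    whose shared constant cancels in the ratio.
    """
    if K < 1 or L < 1:
        raise ValueError("lag orders K and L must be >= 1")
    if x.n != y.n:
        raise SeriesLengthError(f"lengths differ: {x.n} vs {y.n}")
    n = y.n
    start = max(K, L)
    if n <= start + 10:
        raise SeriesLengthError(
            f"n={n} too short for lag orders (K={K}, L={L}); need n > {start + 10}")
    yy = y.values[start:]
    X_r = _lag_block(y.values, K, start)
    X_f = np.hstack([X_r, _lag_block(x.values, L, start)])
    var_r = _ols_residual_var(X_r, yy, intercept)
    var_f = _ols_residual_var(X_f, yy, intercept)
    return GcResult(direction=f"{x.name}→{y.name}", order_restricted=K,
                    order_full=(K, L), var_restricted=var_r, var_full=var_f,
                    gc=float(np.log(var_r / var_f)))


def granger_conditional(vars: VariableSet, source: str, target: str,
                        conditioning: Sequence[str], K: int = 5,
                        intercept: bool = False) -> GcResult:
    """Conditional GC(source -> target | conditioning).

    The restricted model regresses the target on K lags of itself and of
    every conditioning series; the full model adds K lags of the source.
    With an empty conditioning set this reduces exactly to
    :func:`granger_bivariate` with ``L = K``.
    """
    conditioning = list(conditioning)
    if source == target:
        raise ValueError("source and target must differ")
    if source in conditioning or target in conditioning:
        raise ValueError("conditioning set must exclude source and target")
    if K < 1:
        raise ValueError("lag order K must be >= 1")
    n = vars.n
    if n <= K + 10:
        raise SeriesLengthError(f"n={n} too short for lag order K={K}")
    start = K
    yy = vars[target].values[start:]
    blocks = [_lag_block(vars[target].values, K, start)]
    blocks += [_lag_block(vars[name].values, K, start) for name in conditioning]
    X_r = np.hstack(blocks)
    X_f = np.hstack(blocks + [_lag_block(vars[source].values, K, start)])
    var_r = _ols_residual_var(X_r, yy, intercept)
    var_f = _ols_residual_var(X_f, yy, intercept)
    cond = ",".join(conditioning) if conditioning else "∅"
    return GcResult(direction=f"{source}→{target}|{cond}", order_restricted=K,
                    order_full=(K, K), var_restricted=var_r, var_full=var_f,
                    gc=float(np.log(var_r / var_f)))
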
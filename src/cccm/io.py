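"""CSV/JSON interfaces and the pairwise/conditional network pipeline.

This module mirrors the shape of a multichannel effective-connectivity
analysis: read a matrix of time series (one column per channel, e.g.
ROI-averaged BOLD signals), optionally upsample each channel with a cubic
spline, then fill a directed causality matrix (rows = source, columns =
target) with cross-map skill, Granger causality or conditional causality
ratios.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .crossmap import cross_map
from .embedding import EmbeddingConfig, TimeSeries
from .exceptions import CCMError, DegenerateSeriesError
from .granger import granger_bivariate
from .multivar import VariableSet, conditional_cccm
from .synthetic import resample_spline

__all__ = [
    "AnalysisConfig",
    "CausalityMatrix",
    "read_series_csv",
    "pairwise_matrix",
    "conditional_matrix",
    "average_matrices",
    "write_results",
    "read_matrix_csv",
]

logger = logging.getLogger("cccm")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the network pipeline.

    ``upsample_factor`` > 1 applies cubic-spline interpolation to every
    channel before embedding; all reported values then refer to the
    upsampled series.  ``mode`` selects full-library (ccm) or strictly
    past (cccm) neighbor search.
    """

    E: int = 5
    tau: int = 1
    mode: Literal["ccm", "cccm"] = "cccm"
    upsample_factor: int = 1
    library_grid: tuple[int, ...] | None = None
    gc_order: int = 5
    theiler: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ccm", "cccm"):
            raise ValueError(f"mode must be 'ccm' or 'cccm', got {self.mode!r}")
        for name in ("E", "tau", "upsample_factor", "gc_order"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def embedding(self) -> EmbeddingConfig:
        return EmbeddingConfig(E=self.E, tau=self.tau)


@dataclass(frozen=True)
class CausalityMatrix:
    """Directed causality values between named channels.

    Orientation: ``values[i, j]`` is the metric for direction
    ``names[i] → names[j]``; the diagonal is NaN (undefined).
    """

    names: tuple[str, ...]
    values: np.ndarray
    metric: str
    config: AnalysisConfig

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.names), len(self.names)):
            raise ValueError("values must be square and match names")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))


def read_series_csv(path: str | Path) -> VariableSet:
    """Read a multichannel time-series CSV into a :class:`VariableSet`.

    One column per series, one row per sample; an optional header row
    provides names, otherwise columns are auto-named ``col0, col1, ...``.
    Parsing is locale independent ('.' decimal separator).  Ragged
    columns, non-numeric cells and NaNs are rejected with errors naming
    the offending column (missing-data semantics are undefined for cross
    mapping).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head = pd.read_csv(path, header=None, nrows=1)
    if head.empty:
        raise ValueError(f"{path}: empty file")
    has_header = any(isinstance(v, str) for v in head.iloc[0])
    df = pd.read_csv(path, header=0 if has_header else None)
    if not has_header:
        df.columns = [f"col{i}" for i in range(df.shape[1])]
    series = []
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: column {col!r} has a missing or non-numeric cell "
                f"at data row {row} (ragged columns and NaNs are rejected)")
        series.append(TimeSeries(values.to_numpy(dtype=float), name=str(col)))
    return VariableSet(series)


def _prepare(vars: VariableSet, cfg: AnalysisConfig) -> VariableSet:
    if cfg.upsample_factor > 1:
        vars = VariableSet(
            [resample_spline(s, cfg.upsample_factor) for s in vars.series])
    n = vars.n
    span = (cfg.E - 1) * cfg.tau
    if cfg.E * cfg.tau > n / 10:
        logger.warning(
            "E*tau = %d exceeds n/10 = %.0f; an over-long embedding window "
            "thins the neighbor density and can degrade cross-map skill",
            cfg.E * cfg.tau, n / 10)
    logger.info("analysis on n=%d samples, embedding span (E-1)*tau=%d, "
                "effective predictions per cccm pair=%d",
                n, span, max(0, n - span - cfg.E - 1))
    return vars


def pairwise_matrix(vars: VariableSet, cfg: AnalysisConfig,
                    metric: Literal["rho", "gc"] = "rho") -> CausalityMatrix:
    """Directed cross-map skill (or GC) for every ordered channel pair.

    Channels are upsampled first when requested.  A failed pair (e.g. a
    constant channel) is recorded as NaN with a logged warning rather than
    aborting the whole matrix.
    """
    if len(vars) < 2:
        raise ValueError("pairwise analysis needs at least 2 series")
    vars = _prepare(vars, cfg)
    L = len(vars)
    values = np.full((L, L), np.nan)
    for i, src in enumerate(vars.series):
        for j, tgt in enumerate(vars.series):
            if i == j:
                continue
            try:
                if metric == "rho":
                    values[i, j] = cross_map(src, tgt, cfg.embedding,
                                             mode=cfg.mode,
                                             theiler=cfg.theiler).rho
                elif metric == "gc":
                    values[i, j] = granger_bivariate(src, tgt, K=cfg.gc_order,
                                                     L=cfg.gc_order).gc
                else:
                    raise ValueError(f"unknown metric {metric!r}")
            except CCMError as exc:
                logger.warning("pair %s→%s failed: %s", src.name, tgt.name, exc)
    metric_label = f"{cfg.mode}_rho" if metric == "rho" else "gc"
    return CausalityMatrix(names=tuple(vars.names), values=values,
                           metric=metric_label, config=cfg)


def conditional_matrix(vars: VariableSet, source: str, target: str,
                       cfg: AnalysisConfig) -> pd.DataFrame:
    """Conditional causality ratio of source→target given each other channel.

    Returns a table with one row per conditioning variable Z (all channels
    except source and target, i.e. L-2 rows) and the causality ratio of
    ``source → target | {Z}``.
    """
    if len(vars) < 3:
        raise ValueError("conditional analysis needs at least 3 series")
    vars = _prepare(vars, cfg)
    rows = []
    for name in vars.names:
        if name in (source, target):
            continue
        try:
            res = conditional_cccm(vars, source, target, [name], cfg.embedding,
                                   theiler=cfg.theiler)
            rows.append({"conditioning": name, "ratio": res.ratio,
                         "var_without": res.var_without,
                         "var_with": res.var_with})
        except CCMError as exc:
            logger.warning("conditional %s→%s|%s failed: %s",
                           source, target, name, exc)
            rows.append({"conditioning": name, "ratio": np.nan,
                         "var_without": np.nan, "var_with": np.nan})
    return pd.DataFrame(rows)


def average_matrices(matrices: Sequence[CausalityMatrix]) -> CausalityMatrix:
    """Entry-wise mean of causality matrices over multiple recordings.

    All matrices must share names and metric.  Averaging is on the plain
    metric scale (no Fisher-z transform); it is associative and
    independent of input order.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.names != first.names:
            raise ValueError(f"name mismatch: {m.names} vs {first.names}")
        if m.metric != first.metric:
            raise ValueError(f"metric mismatch: {m.metric} vs {first.metric}")
    values = np.mean([m.values for m in matrices], axis=0)
    return CausalityMatrix(names=first.names, values=values,
                           metric=first.metric, config=first.config)


def write_results(result: CausalityMatrix | pd.DataFrame, path: str | Path,
                  format: Literal["csv", "json"] = "csv") -> None:
    """Write a causality matrix or table to CSV or JSON.

    CSV matrices have a source-label index column and target-label header
    (rows = source, columns = target); NaN diagonals are written as empty
    cells in CSV and ``null`` in JSON.  JSON output embeds the full
    analysis-config echo.  Written values round-trip to 1e-12.
    """
    path = Path(path)
    if isinstance(result, pd.DataFrame):
        if format == "csv":
            result.to_csv(path, index=False)
        else:
            path.write_text(json.dumps(
                json.loads(result.to_json(orient="records")), indent=1))
        return
    if format == "csv":
        df = pd.DataFrame(result.values, index=list(result.names),
                          columns=list(result.names))
        df.index.name = f"source\\target ({result.metric})"
        df.to_csv(path)
    elif format == "json":
        payload = {
            "metric": result.metric,
            "orientation": "rows=source, columns=target",
            "names": list(result.names),
            "values": [[None if np.isnan(v) else v for v in row]
                       for row in result.values],
            "config": asdict(result.config),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_matrix_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read back a matrix written by :func:`write_results` (CSV form)."""
    df = pd.read_csv(path, index_col=0)
    return list(df.columns), df.to_numpy(dtype=float)
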
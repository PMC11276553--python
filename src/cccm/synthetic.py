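"""Seeded generators for the simulated benchmark systems.

Every simulated system used to exercise the causality estimators lives
here: coupled logistic maps, coupled AR(1) pairs, two-tone sinusoids in
noise, FIR systems with memory, sign/square transforms of a Gaussian,
independent white-noise pairs, and a confounded trio driven by a common
latent input.  A :class:`SystemSpec` pins the system, its printed
coefficients, the length, the seed and an optional SNR, so every generated
dataset is reproducible bit-for-bit from its spec.

Noise is injected at a calibrated signal-to-noise ratio: the noise
variance is ``mean-square(signal) / 10**(snr_db/10)``, i.e. SNR is defined
on the mean-square power of the noise-free signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.interpolate import CubicSpline

from .embedding import TimeSeries
from .exceptions import DegenerateSeriesError, SeriesLengthError

__all__ = [
    "NoiseSpec",
    "SystemSpec",
    "generate",
    "add_awgn",
    "repeat_concat",
    "resample_spline",
    "time_grid",
    "PRESETS",
    "preset_spec",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise level; ``snr_db=None`` means noise-free."""

    snr_db: float | None = None

    def __post_init__(self) -> None:
        if self.snr_db is not None and not math.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite when given")


@dataclass(frozen=True)
class SystemSpec:
    """Full, reproducible description of one simulated dataset."""

    system_id: str
    params: dict[str, Any] = field(default_factory=dict)
    n: int = 1024
    seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


def time_grid(step: float, t_max: float) -> np.ndarray:
    """Inclusive grid ``0, step, 2*step, ..., t_max`` (MATLAB colon style).

    The endpoint is included only when it is an (approximate) integer
    multiple of the step, e.g. ``step=0.01*pi, t_max=2*pi`` yields 201
    points while ``step=0.01, t_max=2*pi`` yields 629.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n_pts = int(math.floor(t_max / step + 1e-9)) + 1
    return np.arange(n_pts) * step


def add_awgn(series: TimeSeries, noise: NoiseSpec,
             seed: int | np.random.Generator = 0) -> TimeSeries:
    """Add zero-mean Gaussian noise at the requested SNR.

    Noise variance is ``P / 10**(snr_db/10)`` where ``P`` is the mean
    square of the input.  A noise-free spec returns the input unchanged.
    """
    if noise.snr_db is None:
        return series
    power = float(np.mean(series.values ** 2))
    if power == 0.0:
        raise DegenerateSeriesError(
            f"series {series.name!r} has zero power; SNR undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = math.sqrt(power / 10.0 ** (noise.snr_db / 10.0))
    return TimeSeries(series.values + rng.normal(0.0, sigma, series.n),
                      name=series.name, dt=series.dt)


def repeat_concat(series: TimeSeries, copies: int) -> TimeSeries:
    """Concatenate ``copies`` verbatim copies of the series end to end.

    Used to demonstrate the data-repetition artifact: repetition plants
    exact recurrences in the shadow manifold and can manufacture strong
    spurious cross-map skill between independent series.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    return TimeSeries(np.tile(series.values, copies), name=series.name,
                      dt=series.dt)


def resample_spline(series: TimeSeries, factor: int) -> TimeSeries:
    """Cubic-spline upsampling by an integer factor.

    The output grid has ``(n-1)*factor + 1`` points spanning the original
    time range; original samples are reproduced exactly at their grid
    positions.  Requires at least 4 samples (cubic spline).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be an integer >= 1")
    if factor == 1:
        return series
    if series.n < 4:
        raise SeriesLengthError(
            f"series {series.name!r}: need n >= 4 for cubic-spline resampling")
    t = np.arange(series.n, dtype=float)
    fine = np.arange((series.n - 1) * factor + 1) / factor
    values = CubicSpline(t, series.values)(fine)
    return TimeSeries(values, name=series.name, dt=series.dt / factor)


# ---------------------------------------------------------------------------
# individual systems
# ---------------------------------------------------------------------------

def _noisy_pair(clean: list[np.ndarray], names: list[str], spec: SystemSpec,
                rng: np.random.Generator, dt: float = 1.0) -> list[TimeSeries]:
    out = []
    for values, name in zip(clean, names):
        ts = TimeSeries(values, name=name, dt=dt)
        out.append(add_awgn(ts, spec.noise, rng))
    return out


def _gen_sign_map(spec: SystemSpec, rng: np.random.Generator) -> list[TimeSeries]:
    """X = X0 + n1, Y = sgn(X0) + n2 for standard-normal X0 (sgn(0) = 0)."""
    x0 = rng.standard_normal(spec.n)
    return _noisy_pair([x0, np.sign(x0)], ["X", "Y"], spec, rng)


def _gen_square_map(spec: SystemSpec, rng: np.random.Generator) -> list[TimeSeries]:
    """X = X0 + n1, Y = X0**2 + n2 for standard-normal X0."""
    x0 = rng.standard_normal(spec.n)
    return _noisy_pair([x0, x0 ** 2], ["X", "Y"], spec, rng)


def _gen_sin_cos(spec: SystemSpec, rng: np.random.Generator) -> list[TimeSeries]:
    """X = sin(k*t) + n1, Y = cos(k*t) + n2 on an inclusive step grid.

    params: ``step`` (default 0.01*pi), ``t_max`` (default 2*pi), ``k``
    (angular frequency multiplier, default 1).  ``n`` in the spec is
    ignored; the grid determines the length.
    """
    p = spec.params
    step = float(p.get("step", 0.01 * math.pi))
    t_max = float(p.get("t_max", 2.0 * math.pi))
    k = float(p.get("k", 1.0))
    t = time_grid(step, t_max)
    return _noisy_pair([np.sin(k * t), np.cos(k * t)], ["X", "Y"], spec, rng,
                       dt=step)


def _gen_ar_coupled(spec: SystemSpec, rng: np.random.Generator) -> list[TimeSeries]:
    """Coupled AR(1) pair with independent Gaussian innovations.

    X(t+1) = a_xx X(t) + a_xy Y(t) + n1(t)
    Y(t+1) = a_yx X(t) + a_yy Y(t) + n2(t)

    params: ``a`` (2x2 coefficient matrix [[a_xx, a_xy], [a_yx, a_yy]]),
    ``noise_sd`` (default 0.05), ``x0``/``y0`` (default 1.5).
    """
    p = spec.params
    a = np.asarray(p["a"], dtype=float)
    if a.shape != (2, 2):
        raise ValueError("ar_coupled requires a 2x2 coefficient matrix 'a'")
    sd = float(p.get("noise_sd", 0.05))
    x = np.empty(spec.n)
    y = np.empty(spec.n)
    x[0], y[0] = float(p.get("x0", 1.5)), float(p.get("y0", 1.5))
    e = rng.normal(0.0, sd, size=(2, spec.n - 1)) if spec.n > 1 else np.empty((2, 0))
    for t in range(spec.n - 1):
        x[t + 1] = a[0, 0] * x[t] + a[0, 1] * y[t] + e[0, t]
        y[t + 1] = a[1, 0] * x[t] + a[1, 1] * y[t] + e[1, t]
    return [TimeSeries(x, name="X"), TimeSeries(y, name="Y")]


def _gen_two_tone(spec: SystemSpec, rng: np.random.Generator) -> list[TimeSeries]:
    """Two sinusoidal tones with a shared component, embedded in noise.

    X(t) = ax1 sin(2*pi*f1*t) + ax2 sin(2*pi*f2*t) + n1(t)
    Y(t) = ay2 sin(2*pi*f2*t) + n2(t)

    params: amplitudes ``ax1``, ``ax2``, ``ay2``; frequencies ``f1``
    (default 2.5), ``f2`` (default 10); grid ``step`` (default 0.005) and
    ``t_max`` (default 2).  SNR applies per series on its own clean power.
    """
    p = spec.params
    step = float(p.get("step", 0.005))
    t = time_grid(step, float(p.get("t_max", 2.0)))
    w1 = 2.0 * math.pi * float(p.get("f1", 2.5))
    w2 = 2.0 * math.pi * float(p.get("f2", 10.0))
    x = float(p["ax1"]) * np.sin(w1 * t) + float(p["ax2"]) * np.sin(w2 * t)
    y = float(p["ay2"]) * np.sin(w2 * t)
    return _noisy_pair([x, y], ["X", "Y"], spec, rng, dt=step)


def _gen_logistic_coupled(spec: SystemSpec, rng: np.random.Generator
                          ) -> list[TimeSeries]:
    """Coupled logistic maps iterated with the grouping X(t)*[a - a*X - c*Y].

    X(t+1) = X(t) * (ax - ax*X(t) - cxy*Y(t))
    Y(t+1) = Y(t) * (ay - ay*Y(t) - cyx*X(t))

    params: ``ax`` (default 3.8), ``ay`` (default 3.2), couplings ``cxy``
    (Y into X's map, default 0) and ``cyx`` (X into Y's map, default 0.1),
    initial conditions ``x0`` (default 0.7) and ``y0`` (default 0.1).
    Deterministic; the seed is unused.
    """
    p = spec.params
    ax = float(p.get("ax", 3.8))
    ay = float(p.get("ay", 3.2))
    cxy = float(p.get("cxy", 0.0))
    cyx = float(p.get("cyx", 0.1))
    x = np.empty(spec.n)
    y = np.empty(spec.n)
    x[0], y[0] = float(p.get("x0", 0.7)), float(p.get("y0", 0.1))
    for t in range(spec.n - 1):
        x[t + 1] = x[t] * (ax - ax * x[t] - cxy * y[t])
        y[t + 1] = y[t] * (ay - ay * y[t] - cyx * x[t])
    return [TimeSeries(x, name="X"), TimeSeries(y, name="Y")]


def _gen_fir_memory(spec: SystemSpec, rng: np.random.Generator) -> list[TimeSeries]:
    """White-noise input through an FIR channel with zero pre-history.

    X(t) ~ N(0, 1) iid;  Y(t) = sum_l h(l) X(t-l) + n(t) with X(t) = 0
    for t < 0.

    params: ``taps`` mapping lag -> coefficient (lag 0 allowed, which is
    an instantaneous exchange term), ``noise_var`` (default 0).
    """
    p = spec.params
    taps = {int(k): float(v) for k, v in dict(p["taps"]).items()}
    if any(lag < 0 for lag in taps):
        raise ValueError("FIR tap lags must be nonnegative")
    x = rng.standard_normal(spec.n)
    y = np.zeros(spec.n)
    for lag, coef in taps.items():
        if lag < spec.n:
            y[lag:] += coef * x[:spec.n - lag]
    noise_var = float(p.get("noise_var", 0.0))
    if noise_var > 0:
        y = y + rng.normal(0.0, math.sqrt(noise_var), spec.n)
    return [TimeSeries(x, name="X"), TimeSeries(y, name="Y")]


def _gen_white_pair(spec: SystemSpec, rng: np.random.Generator) -> list[TimeSeries]:
    """Two independent standard-normal series (the null system)."""
    return [TimeSeries(rng.standard_normal(spec.n), name="X"),
            TimeSeries(rng.standard_normal(spec.n), name="Y")]


def _gen_confounded_trio(spec: SystemSpec, rng: np.random.Generator
                         ) -> list[TimeSeries]:
    """X and Y driven by a shared latent input Z but not by each other.

    X = wx0*X0 + wxz*Z,  Y = wy0*Y0 + wyz*Z with X0, Y0, Z independent
    standard normal.  params: ``wx0`` (default 0.7), ``wxz`` (default 10),
    ``wy0`` (default 0.4), ``wyz`` (default 12).  Returns [X, Y, Z].
    """
    p = spec.params
    x0 = rng.standard_normal(spec.n)
    y0 = rng.standard_normal(spec.n)
    z = rng.standard_normal(spec.n)
    x = float(p.get("wx0", 0.7)) * x0 + float(p.get("wxz", 10.0)) * z
    y = float(p.get("wy0", 0.4)) * y0 + float(p.get("wyz", 12.0)) * z
    return [TimeSeries(x, name="X"), TimeSeries(y, name="Y"),
            TimeSeries(z, name="Z")]


_GENERATORS: dict[str, Callable[[SystemSpec, np.random.Generator], list[TimeSeries]]] = {
    "sign_map": _gen_sign_map,
    "square_map": _gen_square_map,
    "sin_cos": _gen_sin_cos,
    "ar_coupled": _gen_ar_coupled,
    "two_tone": _gen_two_tone,
    "logistic_coupled": _gen_logistic_coupled,
    "fir_memory": _gen_fir_memory,
    "white_pair": _gen_white_pair,
    "confounded_trio": _gen_confounded_trio,
}


def generate(spec: SystemSpec) -> list[TimeSeries]:
    """Generate the time series of ``spec``; reproducible from its fields."""
    try:
        gen = _GENERATORS[spec.system_id]
    except KeyError:
        raise ValueError(
            f"unknown system_id {spec.system_id!r}; "
            f"known: {sorted(_GENERATORS)}") from None
    rng = np.random.default_rng(spec.seed)
    return gen(spec, rng)


#: Canonical parameterizations of the benchmark systems, keyed by a
#: descriptive name.  Each entry is (system_id, params, default n).
PRESETS: dict[str, tuple[str, dict[str, Any], int]] = {
    # AR pair with strong X->Y coupling (0.65) and weak feedback (0.05)
    "ar_unidirectional": ("ar_coupled",
                          {"a": [[0.5, 0.05], [0.65, 0.08]],
                           "noise_sd": 0.05, "x0": 1.5, "y0": 1.5}, 2048),
    # AR pair where Y drives X (0.3) with weak reverse coupling (0.02)
    "ar_feedback": ("ar_coupled",
                    {"a": [[0.6, 0.3], [0.02, 0.8]],
                     "noise_sd": 0.05, "x0": 1.5, "y0": 1.5}, 2048),
    # shared tone dominates X -> near-symmetric coupling
    "two_tone_shared_dominant": ("two_tone",
                                 {"ax1": 0.1, "ax2": 0.6, "ay2": 0.6}, 401),
    # shared tone weak in X -> one-sided coupling
    "two_tone_weak_shared": ("two_tone",
                             {"ax1": 0.6, "ax2": 0.1, "ay2": 0.1}, 401),
    # chaotic maps, X autonomous, Y weakly driven by X
    "logistic_unidirectional": ("logistic_coupled",
                                {"ax": 3.8, "ay": 3.2, "cxy": 0.0, "cyx": 0.1,
                                 "x0": 0.7, "y0": 0.1}, 2048),
    # chaotic maps, mutual -0.1 coupling terms
    "logistic_bidirectional": ("logistic_coupled",
                               {"ax": 3.8, "ay": 3.2, "cxy": 0.1, "cyx": 0.1,
                                "x0": 0.7, "y0": 0.1}, 2048),
    "fir_lags_1_4": ("fir_memory", {"taps": {1: 0.2, 4: 0.85}}, 1024),
    "fir_equal_1_4": ("fir_memory", {"taps": {1: 0.85, 4: 0.85}}, 1024),
    "fir_equal_2_4": ("fir_memory", {"taps": {2: 0.85, 4: 0.85}}, 1024),
    "fir_three_tap": ("fir_memory", {"taps": {1: 0.8, 4: 0.8, 5: 0.6}}, 1024),
    "fir_lags_4_5": ("fir_memory", {"taps": {4: 0.8, 5: 0.6}}, 1024),
    # instantaneous (lag-0) exchange present: GC-blind spot
    "fir_instantaneous": ("fir_memory",
                          {"taps": {0: 0.8, 1: 0.2, 2: 0.2, 5: 0.2},
                           "noise_var": 0.0}, 1024),
    # strictly causal channel with tiny output noise
    "fir_strictly_causal": ("fir_memory",
                            {"taps": {1: 0.8, 2: 0.2, 5: 0.2},
                             "noise_var": 1e-6}, 1024),
    "sine_cosine": ("sin_cos", {"step": 0.01 * math.pi, "t_max": 2 * math.pi,
                                "k": 1.0}, 201),
    "white_pair": ("white_pair", {}, 1000),
    "confounded_trio": ("confounded_trio",
                        {"wx0": 0.7, "wxz": 10.0, "wy0": 0.4, "wyz": 12.0}, 1024),
}


def preset_spec(name: str, n: int | None = None, seed: int = 0,
                noise: NoiseSpec | None = None, **overrides: Any) -> SystemSpec:
    """Build a :class:`SystemSpec` from a named preset, optionally overriding
    individual parameters."""
    system_id, params, default_n = PRESETS[name]
    params = {**params, **overrides}
    return SystemSpec(system_id=system_id, params=params,
                      n=default_n if n is None else n, seed=seed,
                      noise=noise or NoiseSpec())
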
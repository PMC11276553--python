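# Methods

## Model and assumptions

Cross mapping rests on state-space reconstruction: if two observables `X`
and `Y` are coupled through a shared attractor, the delay embedding
`x_t = [X(t), X(t−τ), …, X(t−(E−1)τ)]` reconstructs that attractor (up to
diffeomorphism) from `X` alone, and neighborhoods on the shadow manifold
`M_x` index times at which the full system state — hence `Y` — was
similar. Cross-map skill `ρ(X→Y) = corr(Y, Ŷ|M_x)` therefore measures
how strongly `Y`'s dynamics are written into `X`'s history. The method
assumes uniformly sampled, stationary series, a sampling rate above the
Nyquist rate of the underlying signals (under-sampled series cannot carry
the full state information and yield invalid skill), and enough data that
the manifold is populated: the neighbor search is O(n²) in the series
length and skill converges upward with the library length only under
genuine coupling.

The causalized variant (cCCM) restricts the neighbor search for the
estimate at time `t` to manifold rows with strictly earlier leading
times, so the reconstruction of the present never reads the future. This
is the package's primary estimator; classic CCM (full-library search,
query excluded) is kept for comparison and tends to score slightly
higher since it may exploit future recurrences.

## Estimator conventions

These choices are fixed and tested; most are invisible in typical use
but matter for exact reproducibility.

- **Indexing.** 0-based sample indices; each delay vector is stamped with
  its leading (most recent) coordinate's index; vectors are ordered
  most-recent-first. Manifold rows exist for `t = (E−1)τ … n−1`.
- **Neighbor count.** `k = E+1` (simplex rule: dimension of the manifold
  plus one). In the multivariate conditional estimator `k` stays `E+1`
  regardless of the joint dimension: the causality ratio compares error
  variances across predictor sets of different sizes, and holding the
  amount of neighbor averaging fixed keeps those variances comparable —
  with a dimension-proportional `k`, the richer predictor set is
  penalized by extra averaging and the ratio acquires a negative bias.
  `k` is overridable everywhere.
- **Valid prediction range.** cCCM predicts at the first `t` with at
  least `E+1` strictly-past rows, i.e. `t ≥ (E−1)τ + E + 1`; CCM predicts
  at every manifold time. Skill (`ρ`) and MSE are computed only over
  predicted indices — undefined predictions never enter the correlation,
  and negative correlations are reported as-is, never clamped.
- **Ties and duplicates.** Distance ties are broken by the smaller time
  index (stable sort), making results platform deterministic. If the
  nearest distance is exactly zero (duplicate delay vectors, as produced
  by repeated data), the weight is split uniformly over all zero-distance
  neighbors — the limit of the exponential kernel for exact matches —
  avoiding 0/0 while leaving the kernel untouched elsewhere.
- **Temporal exclusion.** No Theiler window by default (temporally
  adjacent points are admissible neighbors); an optional `theiler`
  parameter excludes `|t_i − t| ≤ w` for users who need it.
- **Library truncation.** Convergence curves evaluate prefixes: both
  series are truncated to the first `L` samples before embedding, and the
  skill at length `L` uses the truncated target.
- **Standardization.** Only the multivariate joint embedding standardizes
  inputs (population ddof=0), so no variable's scale dominates the joint
  Euclidean metric; bivariate cross mapping runs on raw values, to which
  Pearson correlation is invariant anyway. The conditional ratio is
  invariant to rescaling any input.
- **Conditional ratio.** `ratio = (Var(e|S) − Var(e|S∪{src})) / Var(e|S)`
  with population variances over the intersection of the two valid
  ranges. The target is never among its own predictors by default
  (self-prediction from its current-valued delay vector is near perfect
  and would null the ratio); a flag restores the literal inclusion for
  sensitivity analysis. An empty conditioning set is rejected — that
  question is the bivariate one.
- **Directed information.** `−½·log₂(1−ρ²)` in bits/sample, defined for
  `|ρ| < 1`; base 2 is deliberate (bits, not nats).
- **Granger causality.** Strictly past lags (`j ≥ 1`), no intercept by
  default (flag available), both models fitted over the common window
  `i ∈ [max(K,L), n)`, population-normalized residual variances (the
  shared constant cancels in the ratio), `gc = ln(var_r/var_f)`. Default
  `K = L = 5`, matching the span of the default `E = 5` embedding; rank
  deficiency raises rather than silently pseudo-inverting (a noise-free
  channel can make target lags exact combinations of source lags).
- **SNR calibration.** Noise variance is `mean-square(signal)/10^(SNR/10)`:
  SNR is defined on the mean-square power of the noise-free signal, so
  deterministic offsets count as signal.

## Parameters that matter

| parameter | meaning | default | guidance |
|---|---|---|---|
| `E` | embedding dimension (coordinates per delay vector) | 5 | ≥ attractor-dimension heuristic `2d+1`; too large thins neighbor density and degrades skill |
| `tau` | lag between coordinates (samples) | 1 | raise for over-sampled signals; noise immunity grows with the span `E·τ` |
| `k` | neighbors per query | `E+1` | simplex rule; fixed across predictor sets in the conditional estimator |
| `theiler` | temporal exclusion radius (samples) | 0 | set > 0 to suppress serial-correlation shortcuts |
| `K`, `L` | GC lag orders | 5 | GC values depend strongly on these; comparisons should hold them fixed |
| `snr_db` | generator noise level (dB) | none | skill degrades below ~15 dB; see the noise sweep tests |
| `upsample_factor` | cubic-spline upsampling before embedding | 1 | applied channel-wise, before any embedding; results refer to the upsampled series |

For FIR-type systems with memory, skill is high only when the delay
window `{0, τ, …, (E−1)τ}` covers every dominant channel lag: `E·τ`
must exceed the largest dominant delay, and each dominant lag must be
representable on the window grid. This phenomenology is asserted in the
acceptance tests across three tap configurations.

## Synthetic benchmark systems

The generator module is first-class code: every system used in the tests
and in `scripts/acceptance.py` is produced by `generate(SystemSpec(...))`
and reproducible bit-for-bit from `(system_id, params, n, seed, noise)`.
The systems emulate canonical causal structures — unidirectional and
bidirectional chaotic coupling (logistic maps iterated exactly as
`X(t)·[a − aX(t) − cY(t)]`), linear AR coupling with weak feedback,
shared spectral components in noise, strictly-causal and instantaneous
FIR channels with zero pre-history, a latent common driver, and the
data-repetition artifact (concatenating copies of independent series
plants exact manifold recurrences and manufactures spurious skill ≈0.78).

What they do *not* emulate: real measurement chains. In particular, no
hemodynamic response, scanner drift or physiological noise for fMRI-like
data — a passing suite shows the estimators behave correctly on systems
with known ground truth, not that any particular real recording meets
the stationarity/sampling assumptions. The `randn`-based systems match
reference values in multi-seed distribution, never per-draw.

## Numerical notes

- Distances are exact Euclidean (`scipy.spatial.distance.cdist`); the
  batch path uses a stable full argsort per query row so that tie-breaks
  are identical to the single-query search (tested against brute force).
- Degenerate inputs raise typed errors: constant series (standardization,
  correlation), series shorter than `(E−1)τ+1`, queries without `k`
  admissible candidates (the error carries the earliest admissible query
  time), rank-deficient GC designs, zero-power signals with finite SNR.
- Spline upsampling uses a natural cubic spline on the integer grid with
  `(n−1)·factor+1` output points; original samples are reproduced
  exactly.
- Multi-seed quantities in tests and the acceptance script use 20 seeds
  (10 for the parameter sweeps) at the benchmark lengths n = 1024–3000;
  a single n = 2048 directional cross map costs a fraction of a second,
  so the whole reproduction runs in well under a minute.

## Known limitations

- O(n²) memory and time in the library length: fine for n ≤ ~10⁴ on one
  CPU, not for long recordings without windowing.
- No surrogate-based significance testing for ρ; judgments of "large vs
  small" skill are left to the user or to the convergence diagnostic.
- No automatic selection of `E`/`τ` (false-nearest-neighbor or
  mutual-information heuristics are out of scope); both are user
  parameters, and the attractor dimension `d` in the `2d+1` rule is not
  estimated.
- GC magnitudes are order-dependent; only signs/contrasts at fixed order
  are meaningful for comparison with cross-map skill.
- Missing data are rejected outright; the method has no missing-data
  semantics.
- Time-varying (sliding-window) causality is not implemented.
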
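import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cccm import (
    EmbeddingConfig,
    NoiseAttenuation,
    ShadowManifold,
    TimeSeries,
    convergence_curve,
    cross_map,
    di_from_rho,
    knn,
    rho_under_error,
    weights,
)
from cccm.exceptions import (
    DegenerateSeriesError,
    NotEnoughNeighborsError,
    SeriesLengthError,
)


@pytest.fixture
def line_manifold():
    # width-1 manifold with hand-checkable distances
    return ShadowManifold(points=np.array([[0.0], [1.0], [4.0], [9.0], [16.0]]),
                          times=np.arange(5))


class TestKnn:
    def test_past_only_search(self, line_manifold):
        ns = knn(line_manifold, query_time=3, k=2, mode="cccm")
        np.testing.assert_array_equal(ns.times, [2, 1])
        np.testing.assert_allclose(ns.distances, [5.0, 8.0])

    def test_full_library_search_admits_future_excludes_self(self, line_manifold):
        ns = knn(line_manifold, query_time=3, k=2, mode="ccm")
        np.testing.assert_array_equal(ns.times, [2, 4])
        np.testing.assert_allclose(ns.distances, [5.0, 7.0])

    def test_exact_duplicate_is_first_neighbor_with_zero_distance(self):
        m = ShadowManifold(points=np.array([[3.0], [9.0], [1.0], [9.0]]),
                           times=np.arange(4))
        ns = knn(m, query_time=3, k=2, mode="cccm")
        assert ns.times[0] == 1 and ns.distances[0] == 0.0

    def test_insufficient_past_candidates_reports_earliest_admissible(
            self, line_manifold):
        with pytest.raises(NotEnoughNeighborsError) as exc:
            knn(line_manifold, query_time=1, k=3, mode="cccm")
        assert exc.value.earliest_admissible == 3

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(n=st.integers(10, 200), k=st.integers(1, 6),
           seed=st.integers(0, 50), mode=st.sampled_from(["ccm", "cccm"]))
    def test_matches_exhaustive_search(self, n, k, seed, mode):
        """knn agrees with a brute-force scan of all pairwise distances,
        including the tie-break on smaller time index."""
        rng = np.random.default_rng(seed)
        # round to one decimal to provoke exact distance ties
        pts = np.round(rng.standard_normal((n, 2)), 1)
        m = ShadowManifold(points=pts, times=np.arange(n))
        q = int(rng.integers(k + 1, n))
        ns = knn(m, query_time=q, k=k, mode=mode)
        cand = [t for t in range(n)
                if (t < q if mode == "cccm" else t != q)]
        brute = sorted((float(np.linalg.norm(pts[t] - pts[q])), t) for t in cand)
        np.testing.assert_array_equal(ns.times, [t for _, t in brute[:k]])
        np.testing.assert_allclose(ns.distances, [d for d, _ in brute[:k]])


class TestWeights:
    def test_exponential_kernel_values(self):
        w = weights(np.array([1.0, 2.0]))
        e1 = np.exp(-1.0)
        np.testing.assert_allclose(w, [1 / (1 + e1), e1 / (1 + e1)])
        np.testing.assert_allclose(w, [0.7311, 0.2689], atol=1e-4)

    @pytest.mark.parametrize("c", [0.1, 1.0, 42.0])
    def test_equal_distances_give_uniform_weights(self, c):
        np.testing.assert_allclose(weights(np.full(3, c)), [1 / 3] * 3)

    def test_zero_distance_neighbors_share_all_weight(self):
        np.testing.assert_allclose(weights(np.array([0.0, 0.0, 5.0])),
                                   [0.5, 0.5, 0.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=10))
    def test_weights_simplex_and_monotone(self, ds):
        d = np.sort(np.asarray(ds))
        w = weights(d)
        assert np.isclose(w.sum(), 1.0)
        assert np.all(w >= 0) and np.all(w <= 1)
        assert np.all(np.diff(w) <= 1e-12)  # nonincreasing in distance


class TestCrossMap:
    def test_self_map_of_deterministic_signal_is_near_perfect(self):
        t = np.arange(500) * 0.05
        x = TimeSeries(np.sin(t), name="X")
        y = TimeSeries(np.sin(t), name="Y")
        res = cross_map(x, y, EmbeddingConfig(5, 5), mode="cccm")
        assert res.rho > 0.99
        assert res.mse < 1e-3

    def test_independent_white_noise_has_no_skill(self, cfg51):
        rhos = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            x = TimeSeries(rng.standard_normal(1000), name="X")
            y = TimeSeries(rng.standard_normal(1000), name="Y")
            for mode in ("ccm", "cccm"):
                rhos.append(cross_map(x, y, cfg51, mode=mode).rho)
                rhos.append(cross_map(y, x, cfg51, mode=mode).rho)
        assert np.max(np.abs(rhos)) < 0.1

    def test_valid_range_starts_after_enough_past_rows(self, cfg51):
        rng = np.random.default_rng(0)
        x = TimeSeries(rng.standard_normal(64), name="X")
        y = TimeSeries(rng.standard_normal(64), name="Y")
        res = cross_map(x, y, cfg51, mode="cccm")
        # first query needs E+1 strictly-past rows: t = (E-1)tau + E + 1
        assert res.valid_range[0] == (cfg51.E - 1) * cfg51.tau + cfg51.E + 1
        full = cross_map(x, y, cfg51, mode="ccm")
        assert full.valid_range[0] == (cfg51.E - 1) * cfg51.tau

    def test_causalized_predictions_never_read_the_future(self, cfg51):
        """Poisoning all samples after a cutoff leaves earlier cccm
        predictions bit-identical: the estimate of the present uses only
        the past."""
        rng = np.random.default_rng(7)
        x = TimeSeries(rng.standard_normal(300), name="X")
        y = TimeSeries(rng.standard_normal(300), name="Y")
        ref = cross_map(x, y, cfg51, mode="cccm")
        cutoff = 150
        x.values[cutoff + 1:] = np.nan  # in-place poison, bypasses validation
        y.values[cutoff + 1:] = np.nan
        poisoned = cross_map(x, y, cfg51, mode="cccm")
        np.testing.assert_array_equal(poisoned.times, ref.times)
        keep = ref.times <= cutoff
        np.testing.assert_array_equal(poisoned.predictions[keep],
                                      ref.predictions[keep])

    def test_constant_target_rejected(self, cfg51):
        x = TimeSeries(np.random.default_rng(0).standard_normal(100), name="X")
        with pytest.raises(DegenerateSeriesError):
            cross_map(x, TimeSeries(np.ones(100), name="Y"), cfg51)

    def test_mismatched_lengths_rejected(self, cfg51):
        with pytest.raises(SeriesLengthError):
            cross_map(TimeSeries(np.arange(50.0) % 7),
                      TimeSeries(np.arange(49.0) % 5), cfg51)

    def test_library_truncation_equals_truncated_input(self, cfg51):
        rng = np.random.default_rng(1)
        xv, yv = rng.standard_normal(400), rng.standard_normal(400)
        a = cross_map(TimeSeries(xv, name="X"), TimeSeries(yv, name="Y"),
                      cfg51, library_length=250)
        b = cross_map(TimeSeries(xv[:250], name="X"), TimeSeries(yv[:250], name="Y"),
                      cfg51)
        assert a.rho == b.rho and a.mse == b.mse


class TestConvergenceCurve:
    def test_single_length_grid_equals_one_cross_map(self, cfg51):
        rng = np.random.default_rng(2)
        x = TimeSeries(rng.standard_normal(300), name="X")
        y = TimeSeries(np.roll(x.values, 1) + 0.05 * rng.standard_normal(300),
                       name="Y")
        curve = convergence_curve(x, y, cfg51, lengths=[300])
        assert curve.rhos_xy[0] == cross_map(x, y, cfg51).rho
        assert curve.rhos_yx[0] == cross_map(y, x, cfg51).rho

    def test_coupled_system_skill_grows_with_library(self, cfg51):
        from cccm import generate, preset_spec
        x, y = generate(preset_spec("ar_unidirectional", n=1024, seed=0))
        curve = convergence_curve(x, y, cfg51, lengths=[128, 512, 1024])
        assert curve.rhos_xy[-1] > curve.rhos_xy[0]

    def test_independent_noise_does_not_converge_upward(self, cfg51):
        rng = np.random.default_rng(3)
        x = TimeSeries(rng.standard_normal(1024), name="X")
        y = TimeSeries(rng.standard_normal(1024), name="Y")
        curve = convergence_curve(x, y, cfg51, lengths=[256, 512, 1024])
        assert np.max(np.abs(curve.rhos_xy)) < 0.15
        assert np.max(np.abs(curve.rhos_yx)) < 0.15


class TestInformationLink:
    def test_zero_correlation_carries_zero_information(self):
        assert di_from_rho(0.0) == 0.0

    @pytest.mark.parametrize("rho, bits", [(0.5067, 0.21404), (0.99, 2.82554),
                                           (0.98, 2.32918)])
    def test_closed_form_values(self, rho, bits):
        import math
        assert di_from_rho(rho) == pytest.approx(bits, abs=5e-6)
        # independent closed-form route in nats converted to bits
        assert di_from_rho(rho) == pytest.approx(
            -0.5 * math.log(1 - rho ** 2) / math.log(2), abs=1e-12)

    def test_perfect_correlation_is_out_of_domain(self):
        with pytest.raises(ValueError):
            di_from_rho(1.0)

    def test_strictly_increasing_in_magnitude(self):
        grid = np.linspace(0, 0.999, 50)
        vals = [di_from_rho(r) for r in grid]
        assert np.all(np.diff(vals) > 0)
        assert di_from_rho(-0.7) == di_from_rho(0.7)


class TestNoiseAttenuation:
    def test_error_free_limit(self):
        assert rho_under_error(NoiseAttenuation(2.0, 0.0)) == 1.0

    def test_equal_power_case(self):
        assert rho_under_error(NoiseAttenuation(1.3, 1.3)) == pytest.approx(
            1 / np.sqrt(2))

    def test_monotone_decreasing_in_error_power(self):
        vals = [rho_under_error(NoiseAttenuation(1.0, se))
                for se in np.linspace(0, 5, 30)]
        assert np.all(np.diff(vals) < 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NoiseAttenuation(0.0, 1.0)
        with pytest.raises(ValueError):
            NoiseAttenuation(1.0, -0.1)

    def test_closed_form_matches_empirical_correlation(self):
        """corr(Y, Y + e) for independent Gaussian error matches
        sigma_y/sqrt(sigma_y^2+sigma_e^2) within 0.02 at n=10^4."""
        n = 10_000
        for seed, sigma_e in [(0, 0.5), (1, 1.0), (2, 2.0)]:
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(n) * 1.5
            yhat = y + rng.normal(0, sigma_e, n)
            measured = np.corrcoef(y, yhat)[0, 1]
            predicted = rho_under_error(NoiseAttenuation(1.5, sigma_e))
            assert measured == pytest.approx(predicted, abs=0.02)

    def test_information_increases_with_snr(self):
        infos = [di_from_rho(rho_under_error(NoiseAttenuation(1.0, se)))
                 for se in [2.0, 1.0, 0.5, 0.25, 0.1]]
        assert np.all(np.diff(infos) > 0)
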
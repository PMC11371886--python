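import math

import numpy as np
import pytest

from hrvcohort.nonlinear import (
    MarkerUndefined,
    NonlinearParams,
    correlation_dimension,
    correlation_dimension_points,
    correlation_sums,
    embedding_dimension,
    max_lyapunov,
    nonlinear_markers,
    prsa_capacity,
    sample_entropy,
    time_lag,
)
from conftest import make_nn
from oracles import correlation_sums_naive, prsa_naive, sample_entropy_naive


class TestPRSA:
    def test_alternating_series_cancels(self):
        nn = make_nn([800.0, 810] * 50)
        dc, prof = prsa_capacity(nn, "deceleration")
        assert dc == pytest.approx(0.0, abs=1e-12)
        assert prof.anchor_count > 0

    def test_ascending_ramp_dc_exact(self):
        nn = make_nn(800.0 + 2 * np.arange(200))
        dc, _ = prsa_capacity(nn, "deceleration")
        assert dc == 2.0
        with pytest.raises(MarkerUndefined):  # no accelerations on a ramp
            prsa_capacity(nn, "acceleration")

    def test_descending_ramp_ac_exact(self):
        nn = make_nn(1000.0 - 2 * np.arange(200))
        ac, _ = prsa_capacity(nn, "acceleration")
        assert ac == -2.0

    def test_matches_naive_oracle(self, rng):
        iv = 800 + rng.normal(0, 20, 400)
        nn = make_nn(iv)
        for direction in ("deceleration", "acceleration"):
            cap, _ = prsa_capacity(nn, direction)
            assert cap == pytest.approx(prsa_naive(iv, direction), abs=1e-10)

    def test_offset_invariance_and_scale_equivariance(self, rng):
        iv = 800 + rng.normal(0, 15, 500)
        nn = make_nn(iv)
        dc, _ = prsa_capacity(nn, "deceleration")
        dc_off, _ = prsa_capacity(make_nn(iv + 100), "deceleration")
        # the 5% anchor filter is relative, so exact invariance needs the
        # filter loosened for the shifted copy check
        p = NonlinearParams(prsa_max_rel_change=0.5)
        dc_a, _ = prsa_capacity(make_nn(iv), "deceleration", p)
        dc_b, _ = prsa_capacity(make_nn(iv * 2), "deceleration", p)
        assert dc_b == pytest.approx(2 * dc_a, rel=1e-9)
        assert dc_off == pytest.approx(dc, abs=0.5)


class TestTimeLag:
    def test_iid_noise_decorrelates_immediately(self, rng):
        assert time_lag(rng.normal(size=10_000)).lag == 1

    def test_ar_process_analytic_lag(self):
        # AR(1) with coefficient 0.9: first k with 0.9^k < 1/e is 10
        rng = np.random.default_rng(42)
        n = 100_000
        e = rng.normal(size=n)
        x = np.empty(n)
        x[0] = 0.0
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + e[i]
        assert abs(time_lag(x).lag - 10) <= 1

    def test_constant_series_undefined(self):
        with pytest.raises(MarkerUndefined, match="zero_variance"):
            time_lag(np.full(1000, 5.0))

    def test_monotone_in_ar_coefficient(self):
        rng = np.random.default_rng(9)
        n = 100_000
        e = rng.normal(size=n)
        lags = []
        for coef in (0.5, 0.9):
            x = np.empty(n)
            x[0] = 0.0
            for i in range(1, n):
                x[i] = coef * x[i - 1] + e[i]
            lags.append(time_lag(x).lag)
        assert lags[1] >= lags[0]

    def test_saturation_flag(self):
        t = np.arange(5000)
        slow = np.sin(2 * np.pi * t / 4000)  # decorrelates beyond max_lag
        est = time_lag(slow, NonlinearParams(max_lag=20))
        assert est.saturated and est.lag == 20


class TestEmbeddingDimension:
    def test_henon_attractor(self, henon_series):
        est = embedding_dimension(henon_series, lag=1, p=NonlinearParams(max_points=5000))
        assert est.dim in (2, 3)
        assert not est.saturated
        assert est.e1[est.dim - 1] >= 0.95

    def test_iid_noise_saturates(self, rng):
        est = embedding_dimension(rng.normal(size=3000), lag=1,
                                  p=NonlinearParams(max_points=3000))
        assert est.saturated
        assert est.dim == 15

    def test_sine_unfolds_in_two_dimensions(self):
        x = np.sin(2 * np.pi * np.arange(2000) / 40.7)
        est = embedding_dimension(x, lag=10, p=NonlinearParams(max_points=2000))
        assert est.dim <= 2


class TestCorrelationDimension:
    def test_logistic_map_dimension_one(self, logistic_series):
        d2 = correlation_dimension(
            logistic_series, m=2, lag=1,
            p=NonlinearParams(theiler_window=10, max_points=5000),
        )
        assert 0.85 <= d2 <= 1.15

    def test_line_segment_in_three_dims(self, rng):
        u = rng.uniform(0, 1, 2000)
        pts = np.outer(u, np.ones(3))
        d2 = correlation_dimension_points(pts, np.logspace(-2.5, -0.5, 20), theiler=5)
        assert d2 == pytest.approx(1.0, abs=0.1)

    def test_repeated_point_zero_dimension(self):
        d2 = correlation_dimension(np.full(500, 3.0), m=2, lag=1)
        assert d2 == 0.0

    def test_correlation_sums_match_naive(self, rng):
        y = rng.normal(size=(120, 3))
        radii = np.logspace(-1.5, 0.5, 8)
        fast = correlation_sums(y, radii, theiler=2)
        slow = correlation_sums_naive(y, radii, theiler=2)
        np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestSampleEntropy:
    def test_periodic_series_is_perfectly_regular(self):
        assert sample_entropy(np.array([1.0, 2.0] * 500)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_on_random_series(self, rng):
        x = rng.uniform(size=200)
        assert sample_entropy(x) == pytest.approx(
            sample_entropy_naive(x), abs=1e-12
        )

    def test_no_extended_matches_path(self):
        # the two m-templates (0, 0.1) match but their extensions differ
        x = np.array([0.0, 0.1, 5.0, 0.0, 0.1, 9.0])
        with pytest.raises(MarkerUndefined, match="no_extended_matches"):
            sample_entropy(x, NonlinearParams(sampen_r_frac=0.05))

    def test_zero_variance_undefined(self):
        with pytest.raises(MarkerUndefined, match="zero_variance"):
            sample_entropy(np.full(100, 1.0))

    def test_decreasing_in_tolerance(self, rng):
        x = rng.normal(size=400)
        lo = sample_entropy(x, NonlinearParams(sampen_r_frac=0.1))
        hi = sample_entropy(x, NonlinearParams(sampen_r_frac=0.3))
        assert hi <= lo


class TestMaxLyapunov:
    def test_logistic_map_ln2(self, logistic_series):
        lam = max_lyapunov(
            logistic_series, m=1, lag=1,
            p=NonlinearParams(lyap_radius=0.05, theiler_window=1, max_points=10000),
        )
        assert lam == pytest.approx(math.log(2), abs=0.07)

    def test_periodic_signal_non_positive(self):
        x = np.sin(2 * np.pi * np.arange(3000) / 40.7)
        lam = max_lyapunov(
            x, m=2, lag=10,
            p=NonlinearParams(lyap_radius=0.3, theiler_window=20, max_points=3000),
        )
        assert lam <= 0.02

    def test_noise_with_tiny_radius_missing(self, rng):
        with pytest.raises(MarkerUndefined, match="no_neighbours"):
            max_lyapunov(
                rng.normal(0, 100, 2000), m=2, lag=1,
                p=NonlinearParams(lyap_radius=1e-6, max_points=2000),
            )


class TestOrchestration:
    def test_all_seven_markers_on_synthetic_record(self, short_nn):
        values, reasons = nonlinear_markers(short_nn, NonlinearParams(max_points=2000))
        assert set(values) == {
            "ac", "dc", "time_lag", "embedding_dim", "fractal_dim",
            "sample_entropy", "max_lyapunov",
        }
        assert values["dc"] is not None and values["dc"] > 0
        assert values["ac"] is not None and values["ac"] < 0
        assert values["time_lag"] >= 1

    def test_missing_markers_carry_reasons_not_zeros(self):
        nn = make_nn(np.full(2000, 800.0))  # zero variance
        values, reasons = nonlinear_markers(nn)
        assert values["time_lag"] is None
        assert reasons["time_lag"] == "zero_variance"
        assert values["sample_entropy"] is None
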
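"""Population statistics: sparseness, selectivity, tuning, overlap, ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popfam.popmetrics import (
    OverlapCurve,
    fit_overlap_decay,
    fit_von_mises,
    fwhm,
    neural_overlap,
    plasticity_ratios,
    population_sparseness,
    selectivity_index,
    von_mises,
)


def _sparseness_oracle(R):
    """Direct formula evaluation, independent of the implementation path."""
    R = np.clip(np.asarray(R, dtype=float), 0, None)
    n = len(R)
    num = (R.sum() / n) ** 2
    den = (R**2).sum() / n
    return (1 - num / den) / (1 - 1 / n)


class TestSparseness:
    def test_single_active_neuron_is_one(self):
        R = np.zeros(10)
        R[3] = 5.0
        assert population_sparseness(R) == pytest.approx(1.0)

    def test_equal_activity_is_zero(self):
        assert population_sparseness(np.full(10, 2.0)) == pytest.approx(0.0)

    def test_hand_evaluated_case(self):
        assert population_sparseness([1, 1, 0, 0]) == pytest.approx(2 / 3)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            R = rng.uniform(0, 1, rng.integers(2, 12))
            assert population_sparseness(R) == pytest.approx(_sparseness_oracle(R))

    @settings(deadline=None, max_examples=30)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        R = np.array([0.3, 0.0, 1.2, 0.5, 0.05])
        assert population_sparseness(c * R) == pytest.approx(population_sparseness(R))

    def test_spreading_activity_decreases_sparseness(self):
        # constant total activity spread over more neurons: S strictly drops
        n = 8
        values = []
        for k in range(1, n + 1):
            R = np.zeros(n)
            R[:k] = 1.0 / k
            values.append(population_sparseness(R))
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(1.0)
        assert values[-1] == pytest.approx(0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            population_sparseness(np.zeros(5))
        # negative responses are clipped, not counted as activity
        assert population_sparseness([-1.0, 2.0, 0.0]) == pytest.approx(1.0)


class TestSelectivity:
    def test_equal_frames_zero(self):
        assert selectivity_index(np.full(13, 3.0)) == pytest.approx(0.0)

    def test_single_frame_of_13(self):
        amp = np.zeros(13)
        amp[4] = 7.0
        assert selectivity_index(amp) == pytest.approx(12 / 13)

    def test_two_frames_of_13(self):
        amp = np.zeros(13)
        amp[[2, 9]] = 5.0
        assert selectivity_index(amp) == pytest.approx(11 / 13)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            selectivity_index(np.zeros(13))


class TestVonMises:
    @pytest.mark.parametrize(
        "theta_deg,K,A,b",
        [(45.0, 2.0, 1.0, 0.1), (30.0, 1.2, 0.8, 0.0), (100.0, 3.0, 0.5, 0.2),
         (0.0, 0.7, 2.0, -0.05)],
    )
    def test_exact_recovery(self, theta_deg, K, A, b):
        phi = np.deg2rad([0, 45, 90, 135])
        R = von_mises(phi, np.deg2rad(theta_deg), K, A, b)
        fit = fit_von_mises(R)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.valid
        d = abs(fit.theta - np.deg2rad(theta_deg)) % np.pi
        assert min(d, np.pi - d) < 1e-3
        assert fit.K == pytest.approx(K, rel=1e-3)
        assert fit.A == pytest.approx(A, rel=1e-3)
        assert fit.b == pytest.approx(b, abs=1e-3)

    def test_fit_reproduces_inputs_when_exact(self):
        phi = np.deg2rad([0, 45, 90, 135])
        R = von_mises(phi, 0.6, 1.5, 1.1, 0.05)
        fit = fit_von_mises(R)
        assert np.allclose(fit(phi), R, atol=1e-6)

    def test_flat_responses_invalid(self):
        fit = fit_von_mises(np.full(4, 0.3))
        assert not fit.valid
        assert np.isnan(fit.r2)

    def test_angle_relabel_equivariance(self):
        # shifting all angle labels by 90 deg shifts theta by 90 deg mod 180
        phi = np.deg2rad([0, 45, 90, 135])
        R = von_mises(phi, np.deg2rad(30), 2.0, 1.0, 0.1)
        f1 = fit_von_mises(R, angles_deg=(0, 45, 90, 135))
        f2 = fit_von_mises(R, angles_deg=(90, 135, 180, 225))
        d = abs((f2.theta - f1.theta) - np.pi / 2) % np.pi
        assert min(d, np.pi - d) < 1e-6
        assert f2.K == pytest.approx(f1.K, rel=1e-6)


class TestFwhm:
    def test_hand_evaluated_k1(self):
        assert fwhm(1.0) == pytest.approx(np.arccos(np.log(np.cosh(1.0))), rel=1e-12)
        assert fwhm(1.0) == pytest.approx(1.122, abs=1e-3)

    def test_small_k_limit_is_half_pi(self):
        # series: ln(cosh K)/K -> K/2 -> arccos -> pi/2
        assert fwhm(1e-6) == pytest.approx(np.pi / 2, abs=1e-5)

    def test_strictly_decreasing_in_k(self):
        grid = np.linspace(0.05, 10, 50)
        vals = [fwhm(k) for k in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            fwhm(0.0)


class TestOverlap:
    def test_identical_frames_give_one(self):
        X = np.tile(np.array([[0.2], [0.1], [0.0], [0.3]]), (1, 80))
        curve = neural_overlap(X, np.arange(20), max_lag=50)
        assert np.allclose(curve.overlap, 1.0)

    def test_orthogonal_alternation(self):
        X = np.zeros((2, 40))
        X[0, ::2] = 1.0
        X[1, 1::2] = 1.0
        curve = neural_overlap(X, np.arange(10), max_lag=5)
        assert np.allclose(curve.overlap[::2], 0.0)  # odd lags
        assert np.allclose(curve.overlap[1::2], 1.0)  # even lags

    def test_hand_dot_product(self):
        X = np.array([[1.0, 1.0], [1.0, 0.0], [0.0, 0.0]])
        curve = neural_overlap(X, np.array([0]), max_lag=1)
        assert curve.overlap[0] == pytest.approx(1 / np.sqrt(2))

    def test_bounded_and_scale_invariant(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (6, 120))
        c1 = neural_overlap(X, np.arange(40), max_lag=30)
        c2 = neural_overlap(3.7 * X, np.arange(40), max_lag=30)
        assert np.allclose(c1.overlap, c2.overlap)
        assert (np.abs(c1.overlap) <= 1 + 1e-12).all()

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="window"):
            neural_overlap(np.ones((2, 30)), np.arange(10), max_lag=50)


class TestOverlapDecay:
    def test_parameter_recovery_under_noise(self):
        rng = np.random.default_rng(2)
        t = np.arange(1, 51)
        y = 0.7 * np.exp(-0.1 * t) + 0.3 + rng.normal(0, 0.01, 50)
        tau, b = fit_overlap_decay(OverlapCurve(t, y))
        assert tau == pytest.approx(-0.1, rel=0.1)
        assert b == pytest.approx(0.3, rel=0.1)

    def test_fitted_value_at_zero_lag_is_one(self):
        rng = np.random.default_rng(3)
        t = np.arange(1, 51)
        y = 0.5 * np.exp(-0.25 * t) + 0.5 + rng.normal(0, 0.02, 50)
        tau, b = fit_overlap_decay(OverlapCurve(t, y))
        assert (1 - b) * np.exp(tau * 0.0) + b == pytest.approx(1.0)

    def test_constant_curve_degenerate(self):
        t = np.arange(1, 21)
        y = np.full(20, 0.4)
        tau, b = fit_overlap_decay(OverlapCurve(t, y))
        assert b == pytest.approx(0.4, abs=0.01)
        assert tau < -1.0  # decay pushed to the fast boundary

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError):
            fit_overlap_decay(OverlapCurve(np.arange(1, 4), np.ones(3)))


class TestPlasticityRatios:
    def test_identical_sessions_all_ones(self):
        pre = {"auc": 1.2, "active_fraction": 0.5, "tau": -0.1}
        out = plasticity_ratios(pre, dict(pre))
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_doubled_decay_rate(self):
        out = plasticity_ratios({"tau": -0.1}, {"tau": -0.2})
        assert out["tau"] == pytest.approx(2.0)

    def test_zero_denominator_flagged(self):
        out = plasticity_ratios({"auc": 0.0}, {"auc": 1.0})
        assert np.isnan(out["auc"])
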
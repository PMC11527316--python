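"""Delta-rule learner: update arithmetic, likelihood, forward recursion."""

import math

import numpy as np
import pytest
from scipy import stats

from curiolearn.learner import (
    BeliefState,
    LatentPath,
    LearnerParams,
    delta_update,
    forward_filter,
    response_loglik,
    select_alpha,
    simulate_learner,
)
from curiolearn.task import PatternSpec, generate_hiding_sequence


def _params(**kw):
    base = dict(alpha_low=0.2, alpha_high=0.8, phi=0.1, beta_drift=0.05, eta=0.0025)
    base.update(kw)
    return LearnerParams(**base)


class TestDeltaUpdate:
    def test_half_update_no_drift(self):
        out = delta_update(BeliefState(V=0, V_drift=0), r=10, alpha=0.5, beta=0)
        assert (out.V, out.V_drift) == (5, 0)

    def test_pure_drift_extrapolation(self):
        out = delta_update(BeliefState(V=2, V_drift=1), r=7, alpha=0, beta=0)
        assert (out.V, out.V_drift) == (3, 1)

    def test_full_update_with_drift_learning(self):
        out = delta_update(BeliefState(V=0, V_drift=0), r=10, alpha=1, beta=0.1)
        assert (out.V, out.V_drift) == (10, 1)

    def test_updates_use_pre_update_state(self):
        # the position update must add the OLD drift, not the updated one
        out = delta_update(BeliefState(V=0, V_drift=2), r=1, alpha=0, beta=1)
        assert out.V == 2  # 0 + old drift 2 + 0
        assert out.V_drift == 3  # 2 + 1*(1-0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            delta_update(BeliefState(V=0), r=float("nan"), alpha=0.5, beta=0)


class TestSelectAlpha:
    def test_indicator_selects_rate(self):
        p = _params()
        assert select_alpha(1, p) == 0.8
        assert select_alpha(0, p) == 0.2

    def test_invalid_indicator(self):
        with pytest.raises(ValueError):
            select_alpha(2, _params())


class TestResponseLoglik:
    def test_mode_value(self):
        eta = 0.04
        assert response_loglik(0.3, 0.3, eta) == pytest.approx(-0.5 * math.log(2 * math.pi * eta))

    def test_symmetry(self):
        for d in (0.01, 0.3, 2.0):
            assert response_loglik(0.5 + d, 0.5, 0.1) == pytest.approx(
                response_loglik(0.5 - d, 0.5, 0.1)
            )

    def test_matches_scipy_normal_density(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            B, V = rng.normal(size=2)
            eta = float(rng.uniform(0.001, 2.0))
            expected = stats.norm.logpdf(B, loc=V, scale=math.sqrt(eta))
            assert response_loglik(B, V, eta) == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            response_loglik(0.1, 0.2, 0.0)


def _oracle_forward(B, r, z, p):
    """Independent scalar recursion, written step by step."""
    V = r[0]
    Vd = 0.0
    ll = 0.0
    Vs = []
    for t in range(len(B)):
        Vs.append(V)
        ll += -0.5 * math.log(2 * math.pi * p.eta) - (B[t] - V) ** 2 / (2 * p.eta)
        alpha = p.alpha_high if z[t] else p.alpha_low
        err = r[t] - V
        V_new = V + Vd + alpha * err
        Vd = Vd + p.beta_drift * err
        V = V_new
    return np.array(Vs), ll


class TestForwardFilter:
    def test_single_trial_equals_response_loglik(self):
        p = _params()
        B, r = np.array([0.4]), np.array([0.6])
        V, ll = forward_filter(B, r, p, LatentPath([1]))
        assert ll == pytest.approx(response_loglik(0.4, 0.6, p.eta))
        assert V[0] == 0.6  # belief initialised at the first observation

    def test_matches_independent_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            T = int(rng.integers(2, 60))
            B = rng.uniform(0, 1, T)
            r = rng.uniform(0, 1, T)
            z = rng.integers(0, 2, T)
            p = _params(
                alpha_low=float(rng.uniform(0.01, 0.45)),
                alpha_high=float(rng.uniform(0.5, 0.99)),
                beta_drift=float(rng.uniform(0.0, 0.3) + 1e-4),
                eta=float(rng.uniform(0.001, 0.1)),
            )
            V, ll = forward_filter(B, r, p, LatentPath(z))
            V_o, ll_o = _oracle_forward(B, r, z, p)
            assert np.abs(V - V_o).max() < 1e-10
            assert abs(ll - ll_o) < 1e-10

    def test_z_irrelevant_when_rates_equal(self):
        rng = np.random.default_rng(5)
        B, r = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
        p = LearnerParams(0.3, 0.3 + 1e-12, 0.5, 0.1, 0.01)
        _, ll_a = forward_filter(B, r, p, LatentPath(rng.integers(0, 2, 30)))
        _, ll_b = forward_filter(B, r, p, LatentPath(rng.integers(0, 2, 30)))
        assert ll_a == pytest.approx(ll_b, abs=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            forward_filter(np.zeros(3), np.zeros(3), _params(), LatentPath([0, 1]))


class TestSimulateLearner:
    def test_degenerate_constant(self):
        seq = generate_hiding_sequence(
            PatternSpec("HIGH_NOISE", mean0=0.4, noise_sd=0, drift_rate=0, cpp=0), 20, 0
        )
        p = _params(phi=1e-9, eta=1e-12)
        sim = simulate_learner(p, seq, rng_seed=1)
        assert np.allclose(sim["B"], 0.4, atol=1e-4)

    def test_indicator_frequency_matches_phi(self):
        seq = generate_hiding_sequence(PatternSpec("HIGH_CPP", cpp=0.1, noise_sd=0.05), 10000, 3)
        p = _params(phi=0.1)
        sim = simulate_learner(p, seq, rng_seed=2)
        freq = sim["z"].mean()
        # three binomial SDs around the true rate
        assert abs(freq - 0.1) < 3 * math.sqrt(0.1 * 0.9 / 10000)

    def test_reproducible(self):
        seq = generate_hiding_sequence(PatternSpec("DRIFT_CPP", cpp=0.15, noise_sd=0.03), 50, 4)
        a = simulate_learner(_params(), seq, rng_seed=9)
        b = simulate_learner(_params(), seq, rng_seed=9)
        assert np.array_equal(a["B"], b["B"]) and np.array_equal(a["z"], b["z"])


class TestLearnerParamsValidation:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            LearnerParams(0.8, 0.2, 0.1, 0.05, 0.0025)

    @pytest.mark.parametrize("field, value", [
        ("alpha_low", 0.0), ("alpha_high", 1.0), ("phi", 1.2), ("eta", 0.0),
    ])
    def test_bounds_strict(self, field, value):
        kw = dict(alpha_low=0.2, alpha_high=0.8, phi=0.1, beta_drift=0.05, eta=0.0025)
        kw[field] = value
        with pytest.raises(ValueError):
            LearnerParams(**kw)
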
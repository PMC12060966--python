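import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from banditexplore.agents import (
    KalmanBelief,
    KalmanParams,
    RLCKParams,
    RLCKState,
    initial_kalman_belief,
    initial_rlck_state,
    kalman_choice_probs,
    kalman_update,
    rlck_choice_probs,
    rlck_update,
    simulate_session,
)
from banditexplore.task_env import chance_level


def belief(mu, var, prev=None):
    return KalmanBelief(mu=np.array(mu, float), var=np.array(var, float),
                        prev_choice=prev)


class TestKalmanChoice:
    def test_zero_beta_uniform(self):
        p = kalman_choice_probs(
            belief((0.9, 0.1, 0.4), (1.0, 2.0, 0.5), prev=1),
            KalmanParams(phi=1.0, omega=2.0, beta=0.0),
        )
        assert np.allclose(p, 1 / 3)

    def test_symmetry_uniform(self):
        p = kalman_choice_probs(
            belief((0.5, 0.5, 0.5), (1.0, 1.0, 1.0)),
            KalmanParams(phi=0.7, omega=0.3, beta=4.0),
        )
        assert np.allclose(p, 1 / 3)

    def test_hand_softmax(self):
        # softmax of (1, 0, 0): e/(e+2) and 1/(e+2)
        p = kalman_choice_probs(
            belief((1.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
            KalmanParams(phi=0.0, omega=0.0, beta=1.0),
        )
        e = np.e
        assert p == pytest.approx((e / (e + 2), 1 / (e + 2), 1 / (e + 2)))

    def test_perseveration_only_on_previous_choice(self):
        params = KalmanParams(phi=0.0, omega=1.0, beta=1.0)
        p_none = kalman_choice_probs(belief((0.5,) * 3, (1.0,) * 3), params)
        p_prev2 = kalman_choice_probs(
            belief((0.5,) * 3, (1.0,) * 3, prev=2), params
        )
        assert np.allclose(p_none, 1 / 3)
        assert p_prev2[1] > p_prev2[0] == p_prev2[2]

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            kalman_choice_probs(
                belief((np.nan, 0, 0), (1, 1, 1)),
                KalmanParams(phi=0, omega=0, beta=1),
            )

    @given(
        mu=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        var=st.lists(st.floats(0.01, 10), min_size=3, max_size=3),
        beta=st.floats(0, 30),
        phi=st.floats(-3, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_normalization(self, mu, var, beta, phi):
        p = kalman_choice_probs(
            belief(mu, var), KalmanParams(phi=phi, omega=0.5, beta=beta)
        )
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p > 0).all()


class TestKalmanUpdate:
    PARAMS = KalmanParams(phi=0.0, omega=0.0, beta=1.0)

    def test_zero_prediction_error(self):
        b = belief((1.0, 0.5, 0.5), (0.25, 0.25, 0.25))
        out = kalman_update(b, 1, 1.0, self.PARAMS)
        assert out.last_pe == pytest.approx(0.0)
        # mean unchanged by the update step, then decayed toward 0.5
        assert out.mu[0] == pytest.approx(0.99 * 1.0 + 0.01 * 0.5)

    def test_gain_half_at_equal_variances(self):
        b = belief((0.5,) * 3, (0.25,) * 3)
        out = kalman_update(b, 2, 1.0, self.PARAMS)
        assert out.last_gain == pytest.approx(0.5)

    def test_hand_worked_update(self):
        # mu 0.5, var 0.25, r=1: gain 0.5 -> post (0.75, 0.125);
        # decay: mu = .99*.75 + .01*.5 = .7475, var = .9801*.125 + .1
        b = belief((0.5,) * 3, (0.25,) * 3)
        out = kalman_update(b, 1, 1.0, self.PARAMS)
        assert out.mu[0] == pytest.approx(0.7475)
        assert out.var[0] == pytest.approx(0.2225125)

    def test_gain_increasing_in_prior_variance(self):
        gains = []
        for v in (0.1, 0.5, 2.0, 10.0):
            out = kalman_update(belief((0.5,) * 3, (v,) * 3), 1, 1.0, self.PARAMS)
            gains.append(out.last_gain)
            assert 0.0 < out.last_gain < 1.0
        assert np.all(np.diff(gains) > 0)

    def test_decay_fixed_points_under_nonselection(self):
        # an arm never chosen converges to mu=theta, var=sigma_D^2/(1-lam^2)
        b = initial_kalman_belief(self.PARAMS)
        b.mu[2] = 0.9
        b.var[2] = 0.01
        for _ in range(2000):
            b = kalman_update(b, 1, 1.0, self.PARAMS)
        assert b.mu[2] == pytest.approx(0.5, abs=1e-6)
        assert b.var[2] == pytest.approx(0.1 / (1 - 0.99**2), rel=1e-6)

    def test_initial_prior_is_stationary(self):
        params = KalmanParams(phi=0.0, omega=0.0, beta=1.0)
        b = initial_kalman_belief(params)
        assert np.allclose(b.mu, 0.5)
        assert np.allclose(b.var, params.stationary_var)
        assert params.stationary_var == pytest.approx(5.025125628140697)

    def test_invalid_choice(self):
        with pytest.raises(ValueError):
            kalman_update(belief((0.5,) * 3, (1.0,) * 3), 4, 1.0, self.PARAMS)


class TestRLCK:
    def test_alpha_zero_q_unchanged(self):
        s = RLCKState(q=np.array([0.4, 0.5, 0.6]), ck=np.zeros(3))
        p = RLCKParams(alpha=0.0, alpha_c=0.5, tau=0.5, beta=1.0)
        out = rlck_update(s, 1, 1.0, p)
        assert np.array_equal(out.q, s.q)

    def test_delta_rule(self):
        s = RLCKState(q=np.array([0.5, 0.5, 0.5]), ck=np.zeros(3))
        p = RLCKParams(alpha=0.2, alpha_c=0.0, tau=1.0, beta=1.0)
        out = rlck_update(s, 1, 1.0, p)
        assert out.q[0] == pytest.approx(0.6)
        assert out.q[1] == out.q[2] == 0.5

    def test_full_kernel_update_is_one_hot(self):
        s = RLCKState(q=np.zeros(3), ck=np.array([0.3, 0.3, 0.4]))
        p = RLCKParams(alpha=0.1, alpha_c=1.0, tau=0.5, beta=1.0)
        out = rlck_update(s, 2, 0.0, p)
        assert np.allclose(out.ck, [0.0, 1.0, 0.0])

    def test_dual_state_scales_rate_on_exploit(self):
        p = RLCKParams(alpha=0.2, alpha_c=0.0, tau=1.0, beta=1.0, gamma=0.5)
        s = RLCKState(q=np.array([0.5, 0.5, 0.5]), ck=np.zeros(3))
        explore = rlck_update(s.copy(), 1, 1.0, p, hmm_label=0)
        exploit = rlck_update(s.copy(), 1, 1.0, p, hmm_label=1)
        assert explore.q[0] == pytest.approx(0.6)
        assert exploit.q[0] == pytest.approx(0.55)

    def test_dual_state_requires_label(self):
        p = RLCKParams(alpha=0.2, alpha_c=0.1, tau=0.5, beta=1.0, gamma=0.5)
        s = initial_rlck_state()
        with pytest.raises(ValueError):
            rlck_update(s, 1, 1.0, p)

    def test_tau_one_ignores_kernel(self):
        q = np.array([0.7, 0.2, 0.1])
        p = RLCKParams(alpha=0.1, alpha_c=0.1, tau=1.0, beta=3.0)
        with_ck = rlck_choice_probs(RLCKState(q=q, ck=np.array([0.0, 5.0, 0.0])), p)
        no_ck = rlck_choice_probs(RLCKState(q=q, ck=np.zeros(3)), p)
        assert np.allclose(with_ck, no_ck)

    def test_tau_zero_large_beta_limit(self):
        p = RLCKParams(alpha=0.1, alpha_c=0.1, tau=0.0, beta=50.0)
        s = RLCKState(q=np.array([0.0, 1.0, 1.0]), ck=np.array([1.0, 0.0, 0.0]))
        probs = rlck_choice_probs(s, p)
        assert probs[0] > 0.999

    def test_hand_softmax(self):
        # beta*(tau*Q + (1-tau)*CK) = (1.6, 0.5, 0.5);
        # softmax = (0.600333, 0.199833, 0.199833)
        s = RLCKState(q=np.array([0.6, 0.5, 0.5]), ck=np.array([1.0, 0.0, 0.0]))
        p = RLCKParams(alpha=0.1, alpha_c=0.1, tau=0.5, beta=2.0)
        probs = rlck_choice_probs(s, p)
        assert probs == pytest.approx((0.600333, 0.199833, 0.199833), abs=1e-6)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            RLCKParams(alpha=1.5, alpha_c=0.1, tau=0.5, beta=1.0)


class TestSimulateSession:
    def test_determinism(self, default_walk):
        p = KalmanParams(phi=0.3, omega=0.1, beta=4.0)
        s1 = simulate_session("kalman", p, default_walk, seed=9)
        s2 = simulate_session("kalman", p, default_walk, seed=9)
        assert np.array_equal(s1.choices, s2.choices)
        assert np.array_equal(s1.rewards, s2.rewards)

    def test_zero_beta_matches_chance(self, walk_pool):
        p = KalmanParams(phi=0.5, omega=0.5, beta=0.0)
        rates, chances = [], []
        for i, w in enumerate(walk_pool):
            s = simulate_session("kalman", p, w, seed=100 + i)
            rates.append(s.rewards.mean())
            chances.append(chance_level(w))
        # ~1800 Bernoulli(0.5) trials: 3-sigma ~ 0.035
        assert abs(np.mean(rates) - np.mean(chances)) < 0.04

    def test_greedy_limit_on_fixed_best_arm(self):
        from banditexplore.task_env import RewardWalk, WalkConfig

        probs = np.tile([0.9, 0.1, 0.1], (200, 1))
        walk = RewardWalk(
            probs=probs,
            config=WalkConfig(n_trials=200, initial_probs=(0.9, 0.1, 0.1)),
        )
        p = KalmanParams(phi=0.0, omega=0.0, beta=40.0)
        s = simulate_session("kalman", p, walk, seed=2)
        assert (s.choices == 1).mean() > 0.8

    def test_walk_too_short(self, default_walk):
        p = KalmanParams(phi=0.1, omega=0.0, beta=1.0)
        with pytest.raises(ValueError):
            simulate_session("kalman", p, default_walk, seed=0, n_trials=301)

    def test_latents_recorded(self, kalman_session):
        lat = kalman_session.latents
        assert len(lat) == kalman_session.n_trials
        assert {"mu1", "var1", "p_choice"} <= set(lat.columns)

    def test_rlck_and_random_kinds(self, default_walk):
        p = RLCKParams(alpha=0.3, alpha_c=0.2, tau=0.7, beta=3.0)
        s = simulate_session("rlck", p, default_walk, seed=5)
        assert set(np.unique(s.choices)) <= {1, 2, 3}
        r = simulate_session("random", None, default_walk, seed=5)
        assert abs((r.choices == 1).mean() - 1 / 3) < 0.1
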
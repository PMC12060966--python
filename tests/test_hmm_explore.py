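from itertools import product

import numpy as np
import pytest

from banditexplore._kernels import hmm_em, hmm_forward_backward, hmm_forward_loglik
from banditexplore.hmm_explore import (
    EXPLORE,
    EXPLOIT,
    EnergyLandscape,
    ExploreHMM,
    HMMFitConfig,
    decode_states,
    energy_landscape,
    fit_hmm,
    hmm_loglik,
    simulate_hmm_choices,
    strategy_metrics,
)


def enumeration_loglik(model: ExploreHMM, choices) -> float:
    """Brute-force oracle: sum the probability of every state path.

    Exploit state k has zero emission probability unless choice == k, so
    legal paths at trial t visit only state 0 or state choices[t]; still a
    full enumeration over those."""
    P = model.transition_matrix()
    E = model.emission_matrix()
    ch = np.asarray(choices) - 1
    total = 0.0
    for path in product(*[(0, c + 1) for c in ch]):
        if path[0] != 0:  # forced initial explore
            continue
        pr = E[path[0], ch[0]]
        for t in range(1, len(ch)):
            pr *= P[path[t - 1], path[t]] * E[path[t], ch[t]]
        total += pr
    return float(np.log(total))


class TestLoglik:
    def test_single_trial(self):
        m = ExploreHMM(0.2, 0.1)
        for c in (1, 2, 3):
            assert hmm_loglik(m, [c]) == pytest.approx(np.log(1 / 3))

    def test_two_trial_hand_computation(self):
        # (1,1), a=.2, b=.1: (1/3) * (0.7*(1/3) + 0.1*1) = 1/9
        m = ExploreHMM(0.2, 0.1)
        assert hmm_loglik(m, [1, 1]) == pytest.approx(np.log(1 / 9))

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            T = int(rng.integers(1, 9))
            choices = rng.integers(1, 4, T)
            m = ExploreHMM(float(rng.uniform(0.01, 0.99)),
                           float(rng.uniform(0.005, 0.33)))
            oracle = enumeration_loglik(m, choices)
            assert hmm_loglik(m, choices) == pytest.approx(oracle, abs=1e-10)
            assert hmm_forward_loglik(choices - 1, m.a, m.b) == pytest.approx(
                oracle, abs=1e-10
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            hmm_loglik(ExploreHMM(0.1, 0.1), [])

    def test_transition_matrix_structure(self):
        m = ExploreHMM(0.25, 0.08)
        P = m.transition_matrix()
        assert np.allclose(P.sum(axis=1), 1.0)
        # no direct exploit -> other-exploit transitions
        for i in range(1, 4):
            for j in range(1, 4):
                if i != j:
                    assert P[i, j] == 0.0
        assert P[0, 0] == pytest.approx(1 - 3 * 0.08)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ExploreHMM(1.2, 0.1)
        with pytest.raises(ValueError):
            ExploreHMM(0.1, 0.4)


class TestFit:
    def test_loglik_nondecreasing_over_iterations(self):
        choices, _ = simulate_hmm_choices(ExploreHMM(0.15, 0.12), 200, seed=3)
        flat = choices - 1
        offsets = np.array([0, len(flat)], dtype=np.int64)
        lls = []
        for k in range(1, 15):
            _, _, ll, _, _ = hmm_em(flat, offsets, 0.4, 0.3, -1.0, k)
            lls.append(ll)
        assert np.all(np.diff(lls) >= -1e-9)

    def test_parameter_recovery_pooled(self):
        seqs = [
            simulate_hmm_choices(ExploreHMM(0.1, 0.15), 300, seed=100 + i)[0]
            for i in range(50)
        ]
        fit = fit_hmm(seqs, HMMFitConfig(n_restarts=3, seed=0))
        assert fit.model.a == pytest.approx(0.1, abs=0.03)
        assert fit.model.b == pytest.approx(0.15, abs=0.03)
        assert fit.converged

    def test_constant_sequence_mostly_exploit(self):
        fit = fit_hmm(np.ones(100, dtype=int), HMMFitConfig(n_restarts=4, seed=0))
        labels = decode_states(fit)
        assert (labels == EXPLORE).mean() < 0.1

    def test_alternating_sequence_all_explore(self):
        choices = np.tile([1, 2, 3], 20)
        fit = fit_hmm(choices, HMMFitConfig(n_restarts=4, seed=0))
        labels = decode_states(fit)
        assert (labels == EXPLORE).all()

    def test_relabeling_invariance(self):
        choices, _ = simulate_hmm_choices(ExploreHMM(0.2, 0.1), 250, seed=9)
        perm = {1: 2, 2: 3, 3: 1}
        permuted = np.array([perm[c] for c in choices])
        cfg = HMMFitConfig(n_restarts=4, seed=0)
        f1, f2 = fit_hmm(choices, cfg), fit_hmm(permuted, cfg)
        assert f1.model.a == pytest.approx(f2.model.a, abs=1e-6)
        assert f1.model.b == pytest.approx(f2.model.b, abs=1e-6)

    def test_posteriors_normalized(self):
        choices, _ = simulate_hmm_choices(ExploreHMM(0.2, 0.1), 150, seed=4)
        fit = fit_hmm(choices, HMMFitConfig(n_restarts=2, seed=0))
        gamma = fit.posteriors[0]
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
        assert (gamma >= 0).all()

    def test_decoding_accuracy_on_simulated_states(self):
        correct, total = 0, 0
        for i in range(10):
            choices, states = simulate_hmm_choices(
                ExploreHMM(0.1, 0.15), 300, seed=40 + i
            )
            fit = fit_hmm(choices, HMMFitConfig(n_restarts=3, seed=0))
            labels = decode_states(fit)
            truth = (states != 0).astype(int)
            correct += (labels == truth).sum()
            total += len(labels)
        assert correct / total >= 0.85

    def test_fit_loglik_matches_forward(self):
        choices, _ = simulate_hmm_choices(ExploreHMM(0.15, 0.1), 200, seed=6)
        fit = fit_hmm(choices, HMMFitConfig(n_restarts=3, seed=0))
        assert fit.loglik == pytest.approx(
            hmm_loglik(fit.model, choices), abs=1e-8
        )


class TestStrategyMetrics:
    def _session(self, choices, rewards):
        from banditexplore.agents import SessionData
        from banditexplore.task_env import RewardWalk, WalkConfig

        T = len(choices)
        return SessionData(
            choices=np.asarray(choices),
            rewards=np.asarray(rewards),
            walk=RewardWalk(np.full((T, 3), 0.5), WalkConfig(n_trials=T)),
        )

    def test_all_explore(self):
        s = self._session([1, 2, 3, 1], [1, 0, 1, 0])
        m = strategy_metrics([0, 0, 0, 0], s)
        assert m.p_explore == 1.0
        assert np.isnan(m.p_switch_given_exploit)

    def test_no_switches_in_exploit(self):
        s = self._session([1, 1, 1, 1], [1, 1, 0, 1])
        m = strategy_metrics([1, 1, 1, 1], s)
        assert m.p_switch_given_exploit == 0.0
        assert np.isnan(m.p_switch_given_explore)

    def test_hand_counted_transition_rate(self):
        # 10 trials; exploit trials with a successor: t in {0,2,3,4,5};
        # the label at t+1 is explore for t=0 and t=5 -> 2/5
        labels = [1, 0, 1, 1, 1, 1, 0, 0, 0, 0]
        choices = [1] * 10
        rewards = [1] * 10
        m = strategy_metrics(labels, self._session(choices, rewards))
        assert m.p_transition_to_explore_given_reward == pytest.approx(2 / 5)
        assert np.isnan(m.p_transition_to_explore_given_omission)

    def test_win_stay_counting(self):
        labels = [1, 1, 1, 1]
        choices = [1, 1, 2, 2]
        rewards = [1, 1, 0, 1]
        m = strategy_metrics(labels, self._session(choices, rewards))
        # rewarded exploit trials with successor: t=0 (stay), t=1 (switch)
        assert m.win_stay_by_state["exploit"] == pytest.approx(0.5)
        # omission exploit trials: t=2 (stay) -> lose_shift = 0
        assert m.lose_shift_by_state["exploit"] == 0.0

    def test_misaligned_labels_rejected(self):
        s = self._session([1, 2], [1, 0])
        with pytest.raises(ValueError):
            strategy_metrics([0], s)


class TestEnergyLandscape:
    def test_symmetric_case(self):
        el = energy_landscape(ExploreHMM(0.3, 0.1))  # a = 3b
        assert el.stationary_dist["explore"] == pytest.approx(0.5)
        assert el.state_energies["explore"] == pytest.approx(
            el.state_energies["exploit"]
        )

    def test_closed_form_stationary(self):
        el = energy_landscape(ExploreHMM(0.3, 0.1 / 3))
        assert el.stationary_dist["explore"] == pytest.approx(0.75)
        assert el.stationary_dist["exploit"] == pytest.approx(0.25)

    def test_deeper_state_has_lower_energy(self, rng):
        for _ in range(20):
            m = ExploreHMM(float(rng.uniform(0.01, 0.99)),
                           float(rng.uniform(0.005, 0.33)))
            el = energy_landscape(m)
            pi = el.stationary_dist
            e = el.state_energies
            deeper = max(pi, key=pi.get)
            shallower = min(pi, key=pi.get)
            if pi[deeper] != pi[shallower]:
                assert e[deeper] < e[shallower]

    def test_barriers_are_exit_rates(self):
        el = energy_landscape(ExploreHMM(0.2, 0.05))
        assert el.barrier_heights["exploit_to_explore"] == pytest.approx(
            -np.log(0.2)
        )
        assert el.barrier_heights["explore_to_exploit"] == pytest.approx(
            -np.log(0.15)
        )

    def test_degenerate_chain_flagged(self):
        el = energy_landscape(ExploreHMM(0.0, 0.1))
        assert el.degenerate
        assert np.isinf(el.barrier_heights["exploit_to_explore"])
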
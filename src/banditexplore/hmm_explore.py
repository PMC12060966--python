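"""Structurally constrained explore/exploit hidden Markov model.

Four hidden states: one explore state (uniform emission over the three
choices) and three exploit states (each deterministically emits its own
choice). Transitions are tied: every exploit state leaves for explore with
the same probability ``a``, and explore enters each specific exploit state
with the same probability ``b``; direct exploit-to-exploit transitions are
forbidden. Sessions start in the explore state. Only (a, b) are free and
they are estimated by Baum-Welch with the tying built into the M-step.

The fitted transition structure is further summarized as an energy
landscape: stationary occupancies map to Boltzmann state depths (-ln pi)
and exit probabilities to Arrhenius barrier heights (-ln P(leave)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from banditexplore._kernels import hmm_em, hmm_forward_backward
from banditexplore.agents import SessionData

__all__ = [
    "EXPLORE",
    "EXPLOIT",
    "ExploreHMM",
    "HMMFitConfig",
    "HMMFit",
    "StrategyMetrics",
    "EnergyLandscape",
    "hmm_loglik",
    "fit_hmm",
    "decode_states",
    "strategy_metrics",
    "simulate_hmm_choices",
    "energy_landscape",
]

EXPLORE, EXPLOIT = 0, 1


@dataclass(frozen=True)
class ExploreHMM:
    """Tied transition parameters of the 4-state explore/exploit HMM.

    ``p_exploit_to_explore`` (a): probability of leaving any exploit state
    for explore. ``p_explore_to_exploit`` (b): probability of entering each
    specific exploit state from explore, so P(explore stays) = 1 - 3b.
    """

    p_exploit_to_explore: float
    p_explore_to_exploit: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_exploit_to_explore <= 1.0:
            raise ValueError("p_exploit_to_explore must lie in [0, 1]")
        if not 0.0 <= self.p_explore_to_exploit <= 1.0 / 3.0 + 1e-12:
            raise ValueError("p_explore_to_exploit must lie in [0, 1/3]")

    @property
    def a(self) -> float:
        return self.p_exploit_to_explore

    @property
    def b(self) -> float:
        return self.p_explore_to_exploit

    def transition_matrix(self) -> np.ndarray:
        """4x4 row-stochastic matrix; state 0 = explore, 1-3 = exploit arm."""
        a, b = self.a, self.b
        P = np.zeros((4, 4))
        P[0] = [1.0 - 3.0 * b, b, b, b]
        for k in range(1, 4):
            P[k, 0] = a
            P[k, k] = 1.0 - a
        return P

    def emission_matrix(self) -> np.ndarray:
        """4x3 emission probabilities: state x choice."""
        E = np.zeros((4, 3))
        E[0] = 1.0 / 3.0
        for k in range(3):
            E[k + 1, k] = 1.0
        return E


@dataclass(frozen=True)
class HMMFitConfig:
    n_restarts: int = 10
    tol: float = 1e-6
    max_iter: int = 1000
    seed: int = 0
    init_a_range: tuple[float, float] = (0.02, 0.5)
    init_b_range: tuple[float, float] = (0.02, 0.33)


@dataclass
class HMMFit:
    model: ExploreHMM
    loglik: float
    posteriors: list[np.ndarray]
    labels: list[np.ndarray]
    n_iterations: int
    converged: bool
    config: HMMFitConfig
    _single: bool = True


@dataclass
class StrategyMetrics:
    """Model-based strategy summaries; NaN marks undefined conditionals."""

    p_explore: float
    p_switch_given_explore: float
    p_switch_given_exploit: float
    win_stay_by_state: dict[str, float]
    lose_shift_by_state: dict[str, float]
    p_transition_to_explore_given_reward: float
    p_transition_to_explore_given_omission: float
    a: float = np.nan
    b: float = np.nan


@dataclass(frozen=True)
class EnergyLandscape:
    stationary_dist: dict[str, float]
    state_energies: dict[str, float]
    barrier_heights: dict[str, float]
    degenerate: bool = False


def _as_choice_array(choices: Sequence[int]) -> np.ndarray:
    arr = np.asarray(choices, dtype=np.int64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("choices must be a non-empty 1-D sequence")
    if not np.isin(arr, (1, 2, 3)).all():
        raise ValueError("choices must be coded 1, 2 or 3")
    return arr


def hmm_loglik(model: ExploreHMM, choices: Sequence[int]) -> float:
    """Log-likelihood of a choice sequence via the forward recursion in
    log space, with trial 1 forced into the explore state."""
    y = _as_choice_array(choices) - 1
    with np.errstate(divide="ignore"):
        logP = np.log(model.transition_matrix())
        logE = np.log(model.emission_matrix())
    log_alpha = np.full(4, -np.inf)
    log_alpha[0] = logE[0, y[0]]
    for t in range(1, y.size):
        log_alpha = logsumexp(log_alpha[:, None] + logP, axis=0) + logE[:, y[t]]
    return float(logsumexp(log_alpha))


def _normalize_sequences(
    choices: Sequence[int] | Sequence[Sequence[int]],
) -> tuple[list[np.ndarray], bool]:
    first = choices[0] if len(choices) else None
    if np.isscalar(first) or isinstance(first, (int, np.integer)):
        return [_as_choice_array(choices)], True
    return [_as_choice_array(c) for c in choices], False


def fit_hmm(
    choices: Sequence[int] | Sequence[Sequence[int]],
    config: HMMFitConfig | None = None,
) -> HMMFit:
    """Estimate (a, b) by Baum-Welch, best of random (a, b) initializations.

    Accepts one choice sequence or a list of sequences (expected transition
    counts are pooled across sequences in the M-step). Emissions and the
    initial explore state are fixed, never re-estimated.
    """
    config = config or HMMFitConfig()
    seqs, single = _normalize_sequences(choices)
    if min(len(s) for s in seqs) < 10:
        import warnings

        warnings.warn("fitting an HMM to fewer than 10 trials is unreliable")
    flat = np.concatenate(seqs) - 1
    offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in seqs], out=offsets[1:])

    rng = np.random.default_rng(config.seed)
    best = None
    for _ in range(config.n_restarts):
        a0 = rng.uniform(*config.init_a_range)
        b0 = rng.uniform(*config.init_b_range)
        a, b, ll, n_iter, conv = hmm_em(
            flat, offsets, a0, b0, config.tol, config.max_iter
        )
        if best is None or ll > best[2]:
            best = (a, b, ll, n_iter, conv)
    a, b, ll, n_iter, conv = best
    model = ExploreHMM(p_exploit_to_explore=a, p_explore_to_exploit=b)
    posteriors, labels = [], []
    for s in range(len(seqs)):
        _, gamma, *_ = hmm_forward_backward(flat[offsets[s]: offsets[s + 1]], a, b)
        posteriors.append(gamma)
        labels.append(_labels_from_posteriors(gamma))
    return HMMFit(
        model=model,
        loglik=float(ll),
        posteriors=posteriors,
        labels=labels,
        n_iterations=n_iter,
        converged=conv,
        config=config,
        _single=single,
    )


def _labels_from_posteriors(gamma: np.ndarray) -> np.ndarray:
    p_explore = gamma[:, 0]
    p_exploit = gamma[:, 1:].sum(axis=1)
    # ties break toward explore, the maximum-entropy state
    return np.where(p_exploit > p_explore, EXPLOIT, EXPLORE).astype(np.int64)


def decode_states(fit: HMMFit) -> np.ndarray | list[np.ndarray]:
    """Per-trial explore(0)/exploit(1) labels from the smoothed posterior,
    exploit states collapsed."""
    return fit.labels[0] if fit._single else fit.labels


def explore_probability(fit: HMMFit) -> float:
    """Fraction of trials labeled explore, pooled over sequences."""
    labs = np.concatenate(fit.labels)
    return float((labs == EXPLORE).mean())


def strategy_metrics(labels: Sequence[int], session: SessionData) -> StrategyMetrics:
    """Per-session strategy summaries from the decoded state labels.

    Conditional rates use only trials on which the conditioning event
    occurs; an empty conditioning set yields NaN, never 0.
    """
    labels = np.asarray(labels, dtype=np.int64)
    choices = np.asarray(session.choices)
    rewards = np.asarray(session.rewards)
    if not (len(labels) == len(choices) == len(rewards)):
        raise ValueError("labels must align with the session's trials")
    T = len(labels)
    switch = choices[1:] != choices[:-1]  # switch[t] = choice t+1 differs from t
    lab = labels[:-1]
    rew = rewards[:-1]

    def _rate(mask: np.ndarray, events: np.ndarray) -> float:
        return float(events[mask].mean()) if mask.any() else float("nan")

    win_stay = {
        "explore": _rate((lab == EXPLORE) & (rew == 1), ~switch),
        "exploit": _rate((lab == EXPLOIT) & (rew == 1), ~switch),
    }
    lose_shift = {
        "explore": _rate((lab == EXPLORE) & (rew == 0), switch),
        "exploit": _rate((lab == EXPLOIT) & (rew == 0), switch),
    }
    to_explore = labels[1:] == EXPLORE
    from_exploit = lab == EXPLOIT
    return StrategyMetrics(
        p_explore=float((labels == EXPLORE).mean()),
        p_switch_given_explore=_rate(lab == EXPLORE, switch),
        p_switch_given_exploit=_rate(lab == EXPLOIT, switch),
        win_stay_by_state=win_stay,
        lose_shift_by_state=lose_shift,
        p_transition_to_explore_given_reward=_rate(
            from_exploit & (rew == 1), to_explore
        ),
        p_transition_to_explore_given_omission=_rate(
            from_exploit & (rew == 0), to_explore
        ),
    )


def simulate_hmm_choices(
    model: ExploreHMM, n_trials: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a choice sequence from the generative HMM.

    Returns (choices coded 1-3, hidden states coded 0-3 with 0 = explore).
    """
    rng = np.random.default_rng(seed)
    P = model.transition_matrix()
    E = model.emission_matrix()
    states = np.empty(n_trials, dtype=np.int64)
    choices = np.empty(n_trials, dtype=np.int64)
    s = 0  # sessions start in explore
    for t in range(n_trials):
        states[t] = s
        choices[t] = rng.choice(3, p=E[s]) + 1
        s = rng.choice(4, p=P[s])
    return choices, states


def energy_landscape(model: ExploreHMM) -> EnergyLandscape:
    """Boltzmann/Arrhenius summary of the aggregated two-state chain.

    The three exploit states pool into one: P(explore->exploit) = 3b and
    P(exploit->explore) = a, giving stationary occupancies
    pi_explore = a / (a + 3b). State energy is -ln(pi) and the barrier for
    leaving a state is -ln P(leave it), both at unit temperature.
    """
    a, b3 = model.a, 3.0 * model.b
    degenerate = a <= 0.0 or b3 <= 0.0
    if degenerate:
        pi_explore = 1.0 if b3 <= 0.0 else 0.0
        pi_exploit = 1.0 - pi_explore
    else:
        pi_explore = a / (a + b3)
        pi_exploit = b3 / (a + b3)
    with np.errstate(divide="ignore"):
        energies = {
            "explore": float(-np.log(pi_explore)) if pi_explore > 0 else np.inf,
            "exploit": float(-np.log(pi_exploit)) if pi_exploit > 0 else np.inf,
        }
        barriers = {
            "explore_to_exploit": float(-np.log(b3)) if b3 > 0 else np.inf,
            "exploit_to_explore": float(-np.log(a)) if a > 0 else np.inf,
        }
    return EnergyLandscape(
        stationary_dist={"explore": pi_explore, "exploit": pi_exploit},
        state_energies=energies,
        barrier_heights=barriers,
        degenerate=degenerate,
    )
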
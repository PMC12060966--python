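"""Generative choice agents for the restless three-armed bandit.

Three learning models are implemented as explicit per-trial recursions:

* a Bayesian learner that tracks a Gaussian belief per arm and updates it
  with a Kalman gain, choosing by softmax over value + an uncertainty bonus
  + a perseveration bonus;
* a delta-rule learner with an additional choice kernel (RLCK), choosing
  by softmax over a convex combination of value and kernel;
* a dual-state variant of RLCK whose learning rate is rescaled on trials
  labeled "exploit" by an externally fitted HMM.

A uniform-random reference agent is the beta -> 0 limit of any model.
These recursions are the readable reference implementation; the fitting
module re-implements the same likelihoods as compiled kernels and the test
suite checks the two routes agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from banditexplore.task_env import RewardWalk

__all__ = [
    "ModelKind",
    "KalmanParams",
    "KalmanBelief",
    "RLCKParams",
    "RLCKState",
    "SessionData",
    "initial_kalman_belief",
    "initial_rlck_state",
    "kalman_choice_probs",
    "kalman_update",
    "rlck_choice_probs",
    "rlck_update",
    "simulate_session",
]

ModelKind = Literal["kalman", "rlck", "dual", "random"]

EXPLORE, EXPLOIT = 0, 1  # state-label codes shared with hmm_explore


@dataclass(frozen=True)
class KalmanParams:
    """Free and fixed parameters of the Bayesian (Kalman-filter) learner.

    Free: ``phi`` (uncertainty weight), ``omega`` (perseveration weight),
    ``beta`` (softmax inverse temperature). Fixed: decay ``lambda_decay``
    toward ``theta_center``, observation-noise variance ``obs_noise_var``
    and diffusion-noise variance ``diff_noise_var``.
    """

    phi: float
    omega: float
    beta: float
    lambda_decay: float = 0.99
    theta_center: float = 0.5
    obs_noise_var: float = 0.25
    diff_noise_var: float = 0.1

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not 0.0 <= self.lambda_decay <= 1.0:
            raise ValueError("lambda_decay must lie in [0, 1]")
        if self.obs_noise_var <= 0 or self.diff_noise_var <= 0:
            raise ValueError("noise variances must be positive")

    @property
    def stationary_var(self) -> float:
        """Fixed point of the variance decay recursion, used as the
        agnostic initial prior variance."""
        return self.diff_noise_var / (1.0 - self.lambda_decay**2)


@dataclass
class KalmanBelief:
    """Per-arm Gaussian belief state of the Bayesian learner."""

    mu: np.ndarray
    var: np.ndarray
    prev_choice: int | None = None
    last_gain: float = np.nan
    last_pe: float = np.nan

    def copy(self) -> "KalmanBelief":
        return KalmanBelief(
            mu=self.mu.copy(),
            var=self.var.copy(),
            prev_choice=self.prev_choice,
            last_gain=self.last_gain,
            last_pe=self.last_pe,
        )


@dataclass(frozen=True)
class RLCKParams:
    """Parameters of the RL + choice-kernel learner.

    ``gamma`` (exploit-state learning-rate scaler) is only meaningful for
    the dual-state variant and is None otherwise.
    """

    alpha: float
    alpha_c: float
    tau: float
    beta: float
    gamma: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "alpha_c", "tau"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.gamma is not None and self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass
class RLCKState:
    q: np.ndarray
    ck: np.ndarray
    prev_choice: int | None = None

    def copy(self) -> "RLCKState":
        return RLCKState(q=self.q.copy(), ck=self.ck.copy(), prev_choice=self.prev_choice)


@dataclass
class SessionData:
    """One simulated (or observed) session: choices coded 1-3, binary
    rewards, the walk that produced them, and optional latent trajectories."""

    choices: np.ndarray
    rewards: np.ndarray
    walk: RewardWalk
    participant_id: str = "sim"
    session: int = 1
    latents: pd.DataFrame | None = None
    seed: int = -1

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "session": self.session,
                "trial": np.arange(1, self.n_trials + 1),
                "choice": self.choices,
                "reward": self.rewards,
                "p1": self.walk.probs[: self.n_trials, 0],
                "p2": self.walk.probs[: self.n_trials, 1],
                "p3": self.walk.probs[: self.n_trials, 2],
            }
        )


def initial_kalman_belief(params: KalmanParams) -> KalmanBelief:
    """Agnostic prior: means at the decay center, variances at the
    stationary point of the decay recursion."""
    return KalmanBelief(
        mu=np.full(3, params.theta_center),
        var=np.full(3, params.stationary_var),
    )


def initial_rlck_state() -> RLCKState:
    """Values start at the chance reward rate, kernels at zero."""
    return RLCKState(q=np.full(3, 0.5), ck=np.zeros(3))


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


def kalman_choice_probs(belief: KalmanBelief, params: KalmanParams) -> np.ndarray:
    """Softmax over beta * (EV + phi * var + omega * perseveration)."""
    if not (np.isfinite(belief.mu).all() and np.isfinite(belief.var).all()):
        raise ValueError("belief contains non-finite values")
    drive = belief.mu + params.phi * belief.var
    if belief.prev_choice is not None:
        drive = drive.copy()
        drive[belief.prev_choice - 1] += params.omega
    return _softmax(params.beta * drive)


def kalman_update(
    belief: KalmanBelief, choice: int, reward: float, params: KalmanParams
) -> KalmanBelief:
    """Kalman update of the chosen arm, then decay of all arms.

    The chosen arm's mean moves by gain * prediction-error and its variance
    shrinks by (1 - gain); afterwards every arm's mean decays toward the
    center and every variance inflates by the diffusion noise.
    """
    if choice not in (1, 2, 3):
        raise ValueError(f"choice must be 1, 2 or 3, got {choice}")
    new = belief.copy()
    c = choice - 1
    gain = new.var[c] / (new.var[c] + params.obs_noise_var)
    pe = reward - new.mu[c]
    new.mu[c] += gain * pe
    new.var[c] *= 1.0 - gain
    lam = params.lambda_decay
    new.mu = lam * new.mu + (1.0 - lam) * params.theta_center
    new.var = lam**2 * new.var + params.diff_noise_var
    new.prev_choice = choice
    new.last_gain = float(gain)
    new.last_pe = float(pe)
    return new


def rlck_choice_probs(state: RLCKState, params: RLCKParams) -> np.ndarray:
    """Softmax over beta * (tau * Q + (1 - tau) * CK)."""
    drive = params.tau * state.q + (1.0 - params.tau) * state.ck
    if not np.isfinite(drive).all():
        raise ValueError("state contains non-finite values")
    return _softmax(params.beta * drive)


def rlck_update(
    state: RLCKState,
    choice: int,
    reward: float,
    params: RLCKParams,
    hmm_label: int | None = None,
) -> RLCKState:
    """Delta-rule value update of the chosen arm plus kernel updates of all
    arms toward their chosen-indicator.

    For the dual-state variant (``params.gamma`` set) the value learning
    rate is multiplied by gamma on trials labeled exploit; ``hmm_label``
    must then be supplied (0 = explore, 1 = exploit).
    """
    if choice not in (1, 2, 3):
        raise ValueError(f"choice must be 1, 2 or 3, got {choice}")
    rate = params.alpha
    if params.gamma is not None:
        if hmm_label is None:
            raise ValueError("dual-state update requires an hmm_label")
        if hmm_label == EXPLOIT:
            rate = params.gamma * params.alpha
    new = state.copy()
    c = choice - 1
    new.q[c] += rate * (reward - new.q[c])
    indicator = np.zeros(3)
    indicator[c] = 1.0
    new.ck += params.alpha_c * (indicator - new.ck)
    new.prev_choice = choice
    return new


def simulate_session(
    model: ModelKind,
    params: KalmanParams | RLCKParams | None,
    walk: RewardWalk,
    seed: int = 0,
    n_trials: int | None = None,
    labels: Sequence[int] | None = None,
    participant_id: str = "sim",
    session: int = 1,
) -> SessionData:
    """Roll a full session: per trial compute choice probabilities from the
    current latent state, sample a choice, sample a Bernoulli reward from
    the walk, update the state. Reproducible given the seed.

    Parameters
    ----------
    model : "kalman", "rlck", "dual" or "random".
    labels : per-trial explore/exploit labels, required for "dual".
    """
    T = walk.n_trials if n_trials is None else n_trials
    if T > walk.n_trials:
        raise ValueError(f"walk has only {walk.n_trials} trials, requested {T}")
    if model == "dual":
        if not isinstance(params, RLCKParams) or params.gamma is None:
            raise ValueError("dual-state simulation needs RLCKParams with gamma")
        if labels is None:
            raise ValueError("dual-state simulation needs explore/exploit labels")
    rng = np.random.default_rng(seed)
    choices = np.empty(T, dtype=np.int64)
    rewards = np.empty(T, dtype=np.int64)
    records: list[dict] = []

    if model == "kalman":
        belief = initial_kalman_belief(params)
        for t in range(T):
            p = kalman_choice_probs(belief, params)
            c = int(rng.choice(3, p=p)) + 1
            r = int(rng.random() < walk.probs[t, c - 1])
            records.append(
                {
                    "trial": t + 1,
                    "mu1": belief.mu[0], "mu2": belief.mu[1], "mu3": belief.mu[2],
                    "var1": belief.var[0], "var2": belief.var[1], "var3": belief.var[2],
                    "p_choice": p[c - 1],
                }
            )
            belief = kalman_update(belief, c, r, params)
            choices[t], rewards[t] = c, r
    elif model in ("rlck", "dual"):
        state = initial_rlck_state()
        for t in range(T):
            p = rlck_choice_probs(state, params)
            c = int(rng.choice(3, p=p)) + 1
            r = int(rng.random() < walk.probs[t, c - 1])
            records.append(
                {
                    "trial": t + 1,
                    "q1": state.q[0], "q2": state.q[1], "q3": state.q[2],
                    "ck1": state.ck[0], "ck2": state.ck[1], "ck3": state.ck[2],
                    "p_choice": p[c - 1],
                }
            )
            label = labels[t] if model == "dual" else None
            state = rlck_update(state, c, r, params, hmm_label=label)
            choices[t], rewards[t] = c, r
    elif model == "random":
        for t in range(T):
            c = int(rng.choice(3)) + 1
            r = int(rng.random() < walk.probs[t, c - 1])
            records.append({"trial": t + 1, "p_choice": 1.0 / 3.0})
            choices[t], rewards[t] = c, r
    else:
        raise ValueError(f"unknown model kind: {model!r}")

    return SessionData(
        choices=choices,
        rewards=rewards,
        walk=walk,
        participant_id=participant_id,
        session=session,
        latents=pd.DataFrame.from_records(records),
        seed=seed,
    )
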
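"""Model-free per-session behavioral metrics.

Covers reward acquisition relative to chance, optimal-choice rate, the
switching family (overall, win-switch, lose-switch, incorrect switch) and
the reward-sensitivity index
(P(stay | reward) - P(stay | no reward)) / P(stay).
Conditional rates are NaN when their conditioning event never occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from banditexplore.agents import SessionData
from banditexplore.task_env import RewardWalk, chance_level

__all__ = ["MetricsRow", "session_metrics", "reward_sensitivity"]


@dataclass
class MetricsRow:
    reward_rate: float
    chance_level: float
    reward_vs_chance: float
    reward_vs_chance_realized: float
    reward_vs_chance_ratio: float
    p_optimal: float
    p_switch: float
    p_win_switch: float
    p_lose_switch: float
    p_incorrect_switch: float
    reward_sensitivity: float
    n_trials: int

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def _cond_rate(events: np.ndarray, mask: np.ndarray) -> float:
    return float(events[mask].mean()) if mask.any() else float("nan")


def session_metrics(session: SessionData, walk: RewardWalk | None = None) -> MetricsRow:
    """Compute the full model-free metric row for one session.

    ``reward_vs_chance`` is the expected-reward form (mean walk probability
    of the chosen arm minus the walk's chance level, in probability
    points); the realized-reward form and the ratio form are also emitted.
    """
    walk = walk or session.walk
    choices = np.asarray(session.choices)
    rewards = np.asarray(session.rewards)
    T = len(choices)
    probs = walk.probs[:T]
    if len(probs) < T:
        raise ValueError("walk shorter than the session")

    chance = chance_level(probs)
    chosen_probs = probs[np.arange(T), choices - 1]
    reward_rate = float(rewards.mean())
    # ties: any argmax arm counts as optimal
    optimal = np.isclose(chosen_probs, probs.max(axis=1))
    switch = choices[1:] != choices[:-1]
    prev_rew = rewards[:-1]
    prev_optimal = optimal[:-1]
    return MetricsRow(
        reward_rate=reward_rate,
        chance_level=chance,
        reward_vs_chance=float(chosen_probs.mean() - chance),
        reward_vs_chance_realized=float(reward_rate - chance),
        reward_vs_chance_ratio=float(chosen_probs.mean() / chance),
        p_optimal=float(optimal.mean()),
        p_switch=float(switch.mean()) if T > 1 else float("nan"),
        p_win_switch=_cond_rate(switch, prev_rew == 1),
        p_lose_switch=_cond_rate(switch, prev_rew == 0),
        p_incorrect_switch=_cond_rate(switch, prev_optimal),
        reward_sensitivity=reward_sensitivity(session),
        n_trials=T,
    )


def reward_sensitivity(session: SessionData) -> float:
    """Outcome dependence of staying, normalized by the overall stay rate.

    Returns (P(stay | previous reward) - P(stay | previous omission))
    / P(stay), estimated from consecutive-trial pairs; NaN when P(stay)
    is 0 or either conditioning class is absent.
    """
    choices = np.asarray(session.choices)
    rewards = np.asarray(session.rewards)
    if len(choices) < 2:
        return float("nan")
    stay = choices[1:] == choices[:-1]
    prev_rew = rewards[:-1]
    p_stay = stay.mean()
    if p_stay == 0 or not (prev_rew == 1).any() or not (prev_rew == 0).any():
        return float("nan")
    p_stay_win = stay[prev_rew == 1].mean()
    p_stay_lose = stay[prev_rew == 0].mean()
    return float((p_stay_win - p_stay_lose) / p_stay)


def metrics_table(sessions: list[SessionData]) -> pd.DataFrame:
    """Stack per-session metric rows into a tidy table."""
    rows = []
    for s in sessions:
        row = session_metrics(s).to_dict()
        row["participant_id"] = s.participant_id
        row["session"] = s.session
        rows.append(row)
    df = pd.DataFrame(rows)
    lead = ["participant_id", "session"]
    return df[lead + [c for c in df.columns if c not in lead]]
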
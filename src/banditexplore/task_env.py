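"""Restless-bandit reward contingencies ("walks") and the practice-phase gate.

Each arm's reward probability performs a bounded random walk on a 0.1 grid:
on every trial each arm independently has a fixed chance of stepping up or
down by one increment, with steps that would exit the bounds cancelled.
Whole walks are rejection-sampled until per-arm and grand time-means fall
inside a band around 0.5, so no arm is persistently rich or poor and all
sessions have comparable chance levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WalkConfig",
    "RewardWalk",
    "PracticeConfig",
    "GateResult",
    "InfeasibleWalkError",
    "generate_walk",
    "generate_walks",
    "validate_walk",
    "chance_level",
    "practice_gate",
]


class InfeasibleWalkError(RuntimeError):
    """Raised when rejection sampling exhausts its attempt budget."""


@dataclass(frozen=True)
class WalkConfig:
    """Configuration of the restless random walk over reward probabilities."""

    n_trials: int = 300
    n_arms: int = 3
    change_prob: float = 0.1
    step_size: float = 0.1
    lower_bound: float = 0.1
    upper_bound: float = 0.9
    per_arm_mean_band: float = 0.02
    grand_mean_band: float = 0.02
    initial_probs: tuple[float, float, float] = (0.9, 0.7, 0.3)
    max_rejections: int = 2_000_000

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")
        if self.n_arms != 3:
            raise ValueError("only the three-armed task is supported")
        if not 0.0 < self.change_prob < 1.0:
            raise ValueError("change_prob must lie in (0, 1)")
        if not 0.0 < self.lower_bound < self.upper_bound < 1.0:
            raise ValueError("bounds must satisfy 0 < lower < upper < 1")
        if len(self.initial_probs) != self.n_arms:
            raise ValueError("initial_probs must have one entry per arm")
        for p in self.initial_probs:
            if not self.lower_bound - 1e-12 <= p <= self.upper_bound + 1e-12:
                raise ValueError("initial_probs must lie within the bounds")


@dataclass(frozen=True)
class RewardWalk:
    """An accepted reward-probability trajectory for all three arms.

    Attributes
    ----------
    probs : (n_trials, 3) float array of per-trial reward probabilities.
    config : WalkConfig that generated (or is claimed to govern) the walk.
    seed : seed used for generation; -1 for walks built by hand.
    n_rejected : candidate walks discarded before this one was accepted.
    """

    probs: np.ndarray
    config: WalkConfig
    seed: int = -1
    n_rejected: int = 0

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Serialize as a tidy table with 1-based trial index."""
        df = pd.DataFrame(self.probs, columns=["p1", "p2", "p3"])
        df.insert(0, "trial", np.arange(1, self.n_trials + 1))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, config: WalkConfig | None = None) -> "RewardWalk":
        probs = df[["p1", "p2", "p3"]].to_numpy(dtype=float)
        return cls(probs=probs, config=config or WalkConfig(n_trials=len(probs)))


@dataclass(frozen=True)
class PracticeConfig:
    """Thresholds for the 25-trial practice phase gate."""

    n_trials: int = 25
    fixed_probs: tuple[float, float, float] = (0.7, 0.3, 0.2)
    min_points: int = 11
    min_switches: int = 2

    def __post_init__(self) -> None:
        if self.min_points > self.n_trials:
            raise ValueError("min_points cannot exceed n_trials")


@dataclass(frozen=True)
class GateResult:
    points: int
    n_switches: int
    passed: bool


def _candidate_batch(
    config: WalkConfig, rng: np.random.Generator, batch: int
) -> np.ndarray:
    """Simulate `batch` candidate walks at once; returns (batch, T, 3)."""
    T, A = config.n_trials, config.n_arms
    lo, hi = config.lower_bound, config.upper_bound
    probs = np.empty((batch, T, A))
    probs[:, 0, :] = config.initial_probs
    change = rng.random((batch, T - 1, A)) < config.change_prob
    sign = np.where(rng.random((batch, T - 1, A)) < 0.5, 1.0, -1.0)
    steps = np.where(change, sign * config.step_size, 0.0)
    cur = np.broadcast_to(
        np.asarray(config.initial_probs, dtype=float), (batch, A)
    ).copy()
    for t in range(1, T):
        proposed = cur + steps[:, t - 1, :]
        # steps that would exit the bounds are cancelled, not reflected
        in_bounds = (proposed >= lo - 1e-9) & (proposed <= hi + 1e-9)
        cur = np.where(in_bounds, proposed, cur)
        probs[:, t, :] = cur
    return probs


def _acceptable(probs: np.ndarray, config: WalkConfig) -> np.ndarray:
    """Boolean mask of candidates meeting the two time-mean constraints."""
    arm_means = probs.mean(axis=1)
    grand_means = arm_means.mean(axis=1)
    per_arm_ok = (np.abs(arm_means - 0.5) <= config.per_arm_mean_band).all(axis=1)
    grand_ok = np.abs(grand_means - 0.5) <= config.grand_mean_band
    return per_arm_ok & grand_ok


def generate_walk(config: WalkConfig | None = None, seed: int = 0) -> RewardWalk:
    """Rejection-sample a single accepted walk.

    Whole candidate walks are regenerated until the per-arm and grand
    time-mean constraints hold; the number of rejected candidates is
    recorded on the returned walk. Deterministic given (config, seed).

    Raises
    ------
    InfeasibleWalkError
        If `config.max_rejections` candidates are discarded without an
        acceptance.
    """
    config = config or WalkConfig()
    rng = np.random.default_rng(seed)
    n_rejected = 0
    batch = 256
    while n_rejected < config.max_rejections:
        cands = _candidate_batch(config, rng, batch)
        ok = _acceptable(cands, config)
        idx = np.flatnonzero(ok)
        if idx.size:
            first = int(idx[0])
            n_rejected += first
            walk = RewardWalk(
                probs=np.round(cands[first], 10),
                config=config,
                seed=seed,
                n_rejected=n_rejected,
            )
            validate_walk(walk)
            return walk
        n_rejected += batch
        batch = min(2 * batch, 4096)
    raise InfeasibleWalkError(
        f"no acceptable walk after {n_rejected} candidates; "
        "the mean constraints are likely infeasible for this configuration"
    )


def generate_walks(
    n: int, config: WalkConfig | None = None, seed: int = 0
) -> list[RewardWalk]:
    """Generate `n` independent accepted walks from one master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    out = []
    for child in children:
        # each child seed sequence yields an independent 64-bit walk seed
        walk_seed = int(child.generate_state(1, np.uint64)[0])
        out.append(generate_walk(config, seed=walk_seed))
    return out


def validate_walk(walk: RewardWalk) -> None:
    """Independently re-check every structural constraint of a walk.

    Raises ``ValueError`` on the first violated constraint.
    """
    cfg = walk.config
    p = walk.probs
    if p.shape != (cfg.n_trials, cfg.n_arms):
        raise ValueError("walk shape does not match its configuration")
    if not np.allclose(p[0], cfg.initial_probs):
        raise ValueError("trial 1 must equal the configured initial probabilities")
    if (p < cfg.lower_bound - 1e-9).any() or (p > cfg.upper_bound + 1e-9).any():
        raise ValueError("probabilities exit the configured bounds")
    diffs = np.abs(np.diff(p, axis=0))
    on_grid = np.isclose(diffs, 0.0) | np.isclose(diffs, cfg.step_size)
    if not on_grid.all():
        raise ValueError("consecutive probabilities must differ by 0 or one step")
    arm_means = p.mean(axis=0)
    if (np.abs(arm_means - 0.5) > cfg.per_arm_mean_band + 1e-12).any():
        raise ValueError("per-arm time-mean outside the allowed band")
    if abs(p.mean() - 0.5) > cfg.grand_mean_band + 1e-12:
        raise ValueError("grand time-mean outside the allowed band")


def chance_level(walk: RewardWalk | np.ndarray) -> float:
    """Expected reward rate of a uniformly random chooser: the grand mean
    of the walk's probabilities over arms and trials."""
    probs = walk.probs if isinstance(walk, RewardWalk) else np.asarray(walk, float)
    return float(probs.mean())


def practice_gate(
    choices: Sequence[int],
    rewards: Sequence[int],
    config: PracticeConfig | None = None,
) -> GateResult:
    """Apply the two practice-phase criteria: score above chance and
    demonstrate willingness to switch."""
    config = config or PracticeConfig()
    choices = np.asarray(choices)
    rewards = np.asarray(rewards)
    if len(choices) != config.n_trials or len(rewards) != config.n_trials:
        raise ValueError(
            f"expected {config.n_trials} practice trials, got "
            f"{len(choices)} choices / {len(rewards)} rewards"
        )
    points = int(rewards.sum())
    n_switches = int((choices[1:] != choices[:-1]).sum())
    passed = points >= config.min_points and n_switches >= config.min_switches
    return GateResult(points=points, n_switches=n_switches, passed=passed)
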
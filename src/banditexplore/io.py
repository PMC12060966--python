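"""Tidy CSV I/O for trial-level data.

Schema (one row per trial): participant_id, group (optional), session,
trial (1-based), choice in {1,2,3}, reward in {0,1}, p1, p2, p3 (the
walk's reward probabilities, optional when the contingency is unknown).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from banditexplore.agents import SessionData
from banditexplore.task_env import RewardWalk, WalkConfig

__all__ = ["read_trials", "write_trials", "sessions_from_frame", "SchemaError"]

REQUIRED_COLUMNS = ["participant_id", "session", "trial", "choice", "reward"]
PROB_COLUMNS = ["p1", "p2", "p3"]


class SchemaError(ValueError):
    """A trials table violates the documented schema."""


def _validate_frame(df: pd.DataFrame) -> None:
    if df.empty:
        raise SchemaError("trials table is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    bad_choice = ~df["choice"].isin([1, 2, 3])
    if bad_choice.any():
        rows = (df.index[bad_choice] + 2).tolist()[:5]  # 1-based + header
        raise SchemaError(f"choice outside 1-3 at file row(s) {rows}")
    bad_reward = ~df["reward"].isin([0, 1])
    if bad_reward.any():
        rows = (df.index[bad_reward] + 2).tolist()[:5]
        raise SchemaError(f"reward outside 0/1 at file row(s) {rows}")
    for key, grp in df.groupby(["participant_id", "session"]):
        trials = grp["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(1, len(trials) + 1)):
            raise SchemaError(
                f"trial indices for {key} must run 1..T without gaps"
            )


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trials CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty trials file: {path}") from exc
    _validate_frame(df)
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Validate and write a trials CSV (lossless round trip)."""
    _validate_frame(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def sessions_from_frame(df: pd.DataFrame) -> list[SessionData]:
    """Split a validated trials table into SessionData objects."""
    _validate_frame(df)
    have_probs = all(c in df.columns for c in PROB_COLUMNS)
    out = []
    for (pid, sess), grp in df.groupby(["participant_id", "session"], sort=True):
        grp = grp.sort_values("trial")
        if have_probs:
            probs = grp[PROB_COLUMNS].to_numpy(dtype=float)
            walk = RewardWalk(probs=probs, config=WalkConfig(n_trials=len(grp)))
        else:
            walk = RewardWalk(
                probs=np.full((len(grp), 3), np.nan),
                config=WalkConfig(n_trials=len(grp)),
            )
        out.append(
            SessionData(
                choices=grp["choice"].to_numpy(dtype=np.int64),
                rewards=grp["reward"].to_numpy(dtype=np.int64),
                walk=walk,
                participant_id=str(pid),
                session=int(sess),
            )
        )
    return out
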
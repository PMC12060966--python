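"""Synthetic cohort generator.

Stands in for the (non-deposited) participant data: participants are
simulated Bayesian-learner agents playing freshly generated restless
walks. Two groups differ in their generative parameter distributions (the
"EP-like" group draws higher uncertainty weights and lower inverse
temperatures than the control-like group), and three cognitive features
are drawn with a latent factor correlated with inverse temperature to
emulate a general-cognition component. An optional three-subtype mixture
(normative / high uncertainty weight with slowed processing / noisy and
globally impaired) supports the subtyping analyses.

Default group means were calibrated by simulation so that HMM-labeled
exploration lands near 0.27 (control-like) and 0.37 (EP-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from banditexplore.agents import KalmanParams, SessionData, simulate_session
from banditexplore.task_env import RewardWalk, WalkConfig, generate_walk

__all__ = [
    "GroupConfig",
    "SubtypeConfig",
    "CohortConfig",
    "CohortData",
    "DEFAULT_SUBTYPES",
    "default_subtype_cohort_config",
    "simulate_cohort",
    "cohort_feature_table",
]

COGNITIVE_FEATURES = ["processing_speed", "verbal_memory", "executive_function"]


@dataclass(frozen=True)
class GroupConfig:
    """Generative parameter distributions for one participant group.

    phi and beta are log-normal (means/sds on the log scale), omega is
    normal. Cognitive features are normal around ``cognitive_means`` with a
    shared latent factor correlated with log-beta at
    ``cognition_beta_loading`` (emulating a general-cognition component).
    """

    n: int = 30
    log_phi_mean: float = np.log(0.2)
    log_phi_sd: float = 0.35
    log_beta_mean: float = np.log(6.0)
    log_beta_sd: float = 0.30
    omega_mean: float = 0.15
    omega_sd: float = 0.05
    cognitive_means: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cognitive_sds: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cognition_beta_loading: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for sd in (self.log_phi_sd, self.log_beta_sd, self.omega_sd,
                   *self.cognitive_sds):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class SubtypeConfig:
    """Additive shifts applied on top of a group's distributions."""

    name: str
    weight: float
    log_phi_shift: float = 0.0
    log_beta_shift: float = 0.0
    cognitive_shifts: tuple[float, float, float] = (0.0, 0.0, 0.0)


# default three-subtype structure: a normative majority, a high-uncertainty-
# weight subtype with slowed processing, and a noisy globally impaired one
DEFAULT_SUBTYPES = (
    SubtypeConfig("normative", weight=0.4),
    SubtypeConfig(
        "high_uncertainty",
        weight=0.3,
        log_phi_shift=2.0,
        cognitive_shifts=(-3.0, 0.0, 0.0),
    ),
    SubtypeConfig(
        "noisy_impaired",
        weight=0.3,
        log_beta_shift=-2.2,
        cognitive_shifts=(-1.5, -3.0, -3.0),
    ),
)


def default_subtype_cohort_config(n: int = 90, seed: int = 0) -> "CohortConfig":
    """Single-group three-subtype cohort for the subtyping analyses.

    Within-subtype parameter spread is kept tighter than the group
    defaults so the planted structure is recoverable at modest n.
    """
    return CohortConfig(
        groups={"all": GroupConfig(n=n, log_phi_sd=0.25, log_beta_sd=0.25)},
        session_lengths=(200,),
        subtypes=DEFAULT_SUBTYPES,
        share_walks=True,
        seed=seed,
    )


def default_groups() -> dict[str, GroupConfig]:
    """Calibrated control-like and EP-like group configurations."""
    return {
        "control": GroupConfig(),
        "ep": GroupConfig(
            log_phi_mean=np.log(0.3),
            log_beta_mean=np.log(4.0),
            cognitive_means=(-0.5, -0.5, -0.5),
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    groups: dict[str, GroupConfig] = field(default_factory=default_groups)
    session_lengths: tuple[int, ...] = (200, 300)
    walk_config: WalkConfig | None = None
    subtypes: tuple[SubtypeConfig, ...] | None = None
    # reuse one accepted walk per session index across participants
    # (cheap mode for tests; the default mirrors the study's fresh
    # random assignment per participant)
    share_walks: bool = False
    seed: int = 0


@dataclass
class CohortData:
    """Trials, generating-parameter truth, and cognitive features."""

    trials: pd.DataFrame
    truth: pd.DataFrame
    cognitive: pd.DataFrame
    sessions: list[SessionData]
    config: CohortConfig


def _draw_participant(
    group: GroupConfig,
    subtype: SubtypeConfig | None,
    rng: np.random.Generator,
) -> tuple[KalmanParams, np.ndarray]:
    lpm = group.log_phi_mean + (subtype.log_phi_shift if subtype else 0.0)
    lbm = group.log_beta_mean + (subtype.log_beta_shift if subtype else 0.0)
    log_phi = rng.normal(lpm, group.log_phi_sd)
    log_beta = rng.normal(lbm, group.log_beta_sd)
    omega = rng.normal(group.omega_mean, group.omega_sd)
    params = KalmanParams(
        phi=float(np.exp(log_phi)),
        omega=float(omega),
        beta=float(np.exp(log_beta)),
    )
    # latent general-cognition factor partially driven by log-beta
    lam = group.cognition_beta_loading
    z_beta = (log_beta - lbm) / max(group.log_beta_sd, 1e-12)
    g = lam * z_beta + np.sqrt(max(0.0, 1.0 - lam**2)) * rng.normal()
    cog = np.empty(3)
    for j in range(3):
        mean_j = group.cognitive_means[j] + (
            subtype.cognitive_shifts[j] if subtype else 0.0
        )
        cog[j] = mean_j + group.cognitive_sds[j] * (
            0.6 * g + 0.8 * rng.normal()
        )
    return params, cog


def simulate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> CohortData:
    """Simulate a full cohort: parameters, walks, sessions, cognition.

    One fresh accepted walk is generated per participant-session.
    Byte-reproducible given (config, seed); ``seed`` overrides
    ``config.seed`` when given.
    """
    config = config or CohortConfig()
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    rng = np.random.default_rng(ss)
    walk_seeder = np.random.default_rng(ss.spawn(1)[0])

    truth_rows, cog_rows, trial_frames, sessions = [], [], [], []
    shared_walks: dict[int, RewardWalk] = {}
    pid = 0
    for group_name in sorted(config.groups):
        group = config.groups[group_name]
        weights = None
        if config.subtypes:
            weights = np.array([s.weight for s in config.subtypes], float)
            weights /= weights.sum()
        for _ in range(group.n):
            pid += 1
            participant = f"p{pid:04d}"
            subtype = None
            if config.subtypes:
                subtype = config.subtypes[rng.choice(len(config.subtypes), p=weights)]
            params, cog = _draw_participant(group, subtype, rng)
            truth_rows.append(
                {
                    "participant_id": participant,
                    "group": group_name,
                    "subtype": subtype.name if subtype else "none",
                    "phi": params.phi,
                    "beta": params.beta,
                    "omega": params.omega,
                }
            )
            cog_rows.append(
                {"participant_id": participant, "group": group_name}
                | dict(zip(COGNITIVE_FEATURES, cog))
            )
            for sess_idx, n_trials in enumerate(config.session_lengths, start=1):
                base = config.walk_config or WalkConfig(n_trials=n_trials)
                wc = replace(base, n_trials=n_trials)
                if config.share_walks:
                    if sess_idx not in shared_walks:
                        shared_walks[sess_idx] = generate_walk(
                            wc, seed=int(walk_seeder.integers(0, 2**63 - 1))
                        )
                    walk = shared_walks[sess_idx]
                else:
                    walk = generate_walk(
                        wc, seed=int(walk_seeder.integers(0, 2**63 - 1))
                    )
                sess = simulate_session(
                    "kalman",
                    params,
                    walk,
                    seed=int(rng.integers(0, 2**63 - 1)),
                    participant_id=participant,
                    session=sess_idx,
                )
                sessions.append(sess)
                frame = sess.to_frame()
                frame.insert(1, "group", group_name)
                trial_frames.append(frame)

    return CohortData(
        trials=pd.concat(trial_frames, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        cognitive=pd.DataFrame(cog_rows),
        sessions=sessions,
        config=config,
    )


def cohort_feature_table(
    cohort: CohortData,
    fitted: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the five-feature table for the subtyping stage.

    By default the computational columns come from the generating truth
    (phi -> uncertainty_intolerance, beta -> decision_noise, stored as the
    raw inverse temperature); pass ``fitted`` (participant_id, phi, beta)
    to use fitted parameters instead.
    """
    comp = fitted if fitted is not None else cohort.truth
    comp = comp[["participant_id", "phi", "beta"]].rename(
        columns={"phi": "uncertainty_intolerance", "beta": "decision_noise"}
    )
    table = cohort.cognitive.merge(comp, on="participant_id")
    meta = cohort.truth[["participant_id", "group", "subtype"]]
    return table.merge(meta, on="participant_id")
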
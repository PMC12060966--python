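"""End-to-end analysis pipeline.

Runs, in order: model-free session metrics, per-participant explore/exploit
HMM fits with strategy metrics and energy landscapes, pooled run-length
mixture analysis per group, generative-model fitting with AIC comparison,
and (when cognitive features are available) the cohort PCA/clustering
stage. Every stage logs its seed and the configuration hash so reruns are
verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from banditexplore import __version__
from banditexplore.agents import SessionData
from banditexplore.behavior_metrics import metrics_table
from banditexplore.cohort_analysis import (
    FEATURES,
    pca_with_permutation,
    ward_cluster,
)
from banditexplore.hmm_explore import (
    HMMFitConfig,
    decode_states,
    energy_landscape,
    fit_hmm,
    strategy_metrics,
)
from banditexplore.model_fitting import FitConfig, compare_models, fit_model
from banditexplore.switch_dynamics import (
    MixtureFitConfig,
    fit_geo_mixture,
    run_lengths,
    select_components,
)

log = logging.getLogger("banditexplore.pipeline")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "explore_exploit_grid",
]


def explore_exploit_grid(
    phi_values: np.ndarray,
    beta_values: np.ndarray,
    walks,
    seed: int = 0,
    omega: float = 0.0,
    agents_per_cell: int = 1,
    hmm_restarts: int = 3,
) -> pd.DataFrame:
    """Mean HMM-labeled exploration of simulated Bayesian-learner agents
    over a (phi, beta) grid.

    Each cell simulates ``agents_per_cell`` agents (omega fixed) on walks
    cycled from ``walks``, fits the explore/exploit HMM to each simulated
    choice sequence, and records the fraction of trials decoded as
    explore. Returns a tidy frame with columns phi, beta, p_explore.
    """
    from banditexplore.agents import KalmanParams, simulate_session
    from banditexplore.hmm_explore import HMMFitConfig, decode_states, fit_hmm

    rows = []
    hmm_cfg = HMMFitConfig(n_restarts=hmm_restarts, seed=seed)
    counter = 0
    for phi in phi_values:
        for beta in beta_values:
            p_explore = []
            for rep in range(agents_per_cell):
                # common random numbers across cells: walk keyed by rep so
                # marginal comparisons are paired
                walk = walks[rep % len(walks)]
                params = KalmanParams(phi=float(phi), omega=omega, beta=float(beta))
                sess = simulate_session(
                    "kalman", params, walk, seed=seed * 1_000_003 + counter
                )
                fit = fit_hmm(sess.choices, hmm_cfg)
                p_explore.append(float((decode_states(fit) == 0).mean()))
                counter += 1
            rows.append(
                {"phi": float(phi), "beta": float(beta),
                 "p_explore": float(np.mean(p_explore))}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    fit_models: bool = True
    models: tuple[str, ...] = ("kalman", "rlck", "dual")
    fit_restarts: int = 10
    hmm_restarts: int = 10
    max_mixture_components: int = 4
    run_cohort_stage: bool = True
    n_permutations: int = 1000
    out_dir: str | None = None

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    per_session: pd.DataFrame
    per_participant: pd.DataFrame
    group_summary: pd.DataFrame
    mixture_selection: dict[str, dict]
    comparison: pd.DataFrame | None
    pca: object | None
    clustering: object | None
    report: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _groups_of(sessions: list[SessionData], trials: pd.DataFrame) -> dict[str, str]:
    if "group" not in trials.columns:
        return {s.participant_id: "all" for s in sessions}
    lookup = trials.drop_duplicates("participant_id").set_index("participant_id")
    return {
        s.participant_id: str(lookup.loc[s.participant_id, "group"])
        for s in sessions
    }


def run_pipeline(
    sessions: list[SessionData],
    trials: pd.DataFrame,
    cognitive: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every analysis stage on a set of sessions.

    A stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages are written before the error propagates when an
    output directory is configured.
    """
    config = config or PipelineConfig()
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "stages": [],
    }
    group_of = _groups_of(sessions, trials)

    stage = "metrics"
    try:
        log.info("stage %s: %d sessions", stage, len(sessions))
        per_session = metrics_table(sessions)
        per_session["group"] = per_session["participant_id"].map(group_of)
        report["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "hmm"
    try:
        hmm_rows = []
        labels_by_session: dict[tuple[str, int], np.ndarray] = {}
        hmm_cfg = HMMFitConfig(n_restarts=config.hmm_restarts, seed=config.seed)
        for s in sessions:
            fit = fit_hmm(s.choices, hmm_cfg)
            labels = decode_states(fit)
            labels_by_session[(s.participant_id, s.session)] = labels
            sm = strategy_metrics(labels, s)
            el = energy_landscape(fit.model)
            hmm_rows.append(
                {
                    "participant_id": s.participant_id,
                    "session": s.session,
                    "group": group_of[s.participant_id],
                    "a_exploit_to_explore": fit.model.a,
                    "b_explore_to_exploit": fit.model.b,
                    "hmm_loglik": fit.loglik,
                    "p_explore": sm.p_explore,
                    "p_switch_given_explore": sm.p_switch_given_explore,
                    "p_switch_given_exploit": sm.p_switch_given_exploit,
                    "win_stay_exploit": sm.win_stay_by_state["exploit"],
                    "lose_shift_exploit": sm.lose_shift_by_state["exploit"],
                    "p_to_explore_given_reward":
                        sm.p_transition_to_explore_given_reward,
                    "p_to_explore_given_omission":
                        sm.p_transition_to_explore_given_omission,
                    "pi_explore": el.stationary_dist["explore"],
                    "energy_explore": el.state_energies["explore"],
                    "barrier_exploit_to_explore":
                        el.barrier_heights["exploit_to_explore"],
                }
            )
        hmm_df = pd.DataFrame(hmm_rows)
        report["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "mixture"
    try:
        mixture_selection = {}
        mix_cfg = MixtureFitConfig(seed=config.seed)
        for group in sorted(set(group_of.values())):
            pooled = np.concatenate(
                [
                    run_lengths(s.choices).intervals
                    for s in sessions
                    if group_of[s.participant_id] == group
                ]
            )
            fits = [
                fit_geo_mixture(pooled, n, mix_cfg)
                for n in range(1, config.max_mixture_components + 1)
            ]
            sel = select_components(fits)
            mixture_selection[group] = {
                "selected": sel.selected,
                "logliks": sel.logliks,
                "aics": sel.aics,
                "weights": fits[sel.selected - 1].weights.tolist(),
                "means": fits[sel.selected - 1].means.tolist(),
            }
        report["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    comparison_df = None
    fitted_rows = []
    if config.fit_models:
        stage = "model_fitting"
        try:
            fit_cfg = FitConfig(n_restarts=config.fit_restarts, seed=config.seed)
            fits_per_model: dict[str, list] = {m: [] for m in config.models}
            for s in sessions:
                labels = labels_by_session[(s.participant_id, s.session)]
                row = {
                    "participant_id": s.participant_id,
                    "session": s.session,
                    "group": group_of[s.participant_id],
                }
                for m in config.models:
                    fit = fit_model(
                        s, m, fit_cfg, labels=labels if m == "dual" else None
                    )
                    fits_per_model[m].append(fit)
                    row[f"aic_{m}"] = fit.aic
                    for pname, pval in fit.params_dict().items():
                        row[f"{m}_{pname}"] = pval
                fitted_rows.append(row)
            comparison_df = compare_models(fits_per_model).table
            report["stages"].append(stage)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # per-participant: average HMM quantities over sessions, join fits
    per_participant = (
        hmm_df.groupby(["participant_id", "group"], as_index=False)
        .mean(numeric_only=True)
        .drop(columns=["session"])
    )
    if fitted_rows:
        fits_df = (
            pd.DataFrame(fitted_rows)
            .groupby(["participant_id", "group"], as_index=False)
            .mean(numeric_only=True)
            .drop(columns=["session"])
        )
        per_participant = per_participant.merge(
            fits_df, on=["participant_id", "group"]
        )

    group_summary = (
        per_participant.drop(columns=["participant_id"])
        .groupby("group")
        .agg(["mean", "std"])
    )
    group_summary.columns = ["_".join(c) for c in group_summary.columns]
    group_summary = group_summary.reset_index()

    pca_res = cluster_res = None
    if config.run_cohort_stage and cognitive is not None:
        stage = "cohort"
        try:
            feat = per_participant[["participant_id"]].copy()
            if config.fit_models and "kalman_phi" in per_participant:
                feat["uncertainty_intolerance"] = per_participant["kalman_phi"]
                feat["decision_noise"] = per_participant["kalman_beta"]
            else:
                raise ValueError(
                    "cohort stage needs fitted parameters; enable fit_models"
                )
            feat = feat.merge(cognitive, on="participant_id")
            pca_res = pca_with_permutation(
                feat, n_perm=config.n_permutations, seed=config.seed
            )
            cluster_res = ward_cluster(feat)
            report["stages"].append(stage)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    report["mixture_selection"] = mixture_selection
    report["n_participants"] = int(per_participant["participant_id"].nunique())
    report["group_p_explore"] = (
        per_participant.groupby("group")["p_explore"].mean().to_dict()
    )
    if comparison_df is not None:
        report["model_comparison"] = comparison_df.to_dict(orient="records")
    if cluster_res is not None:
        report["selected_k"] = cluster_res.selected_k
        report["silhouette"] = cluster_res.silhouette

    result = PipelineResult(
        per_session=per_session,
        per_participant=per_participant,
        group_summary=group_summary,
        mixture_selection=mixture_selection,
        comparison=comparison_df,
        pca=pca_res,
        clustering=cluster_res,
        report=report,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_session.to_csv(out / "per_session_metrics.csv", index=False)
        per_participant.to_csv(out / "per_participant.csv", index=False)
        group_summary.to_csv(out / "group_summary.csv", index=False)
        if comparison_df is not None:
            comparison_df.to_csv(out / "model_comparison.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return result
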
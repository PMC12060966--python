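"""Maximum-likelihood fitting of the generative choice models and
AIC-based model comparison.

The per-trial likelihood recursions are identical to the simulation
recursions in :mod:`banditexplore.agents` (the test suite verifies the two
implementations agree to 1e-10); here they run as compiled kernels so that
multi-start optimization over hundreds of sessions stays cheap.

Parameters are optimized in a transformed space (log for beta, logit for
the unit-interval rates, identity with a wide box for the additive
weights) by derivative-free local search from random restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from banditexplore._kernels import kalman_nll_kernel, rlck_nll_kernel
from banditexplore.agents import KalmanParams, RLCKParams, SessionData

__all__ = [
    "N_PARAMS",
    "FitConfig",
    "FitResult",
    "ComparisonTable",
    "nll",
    "fit_model",
    "compare_models",
]

N_PARAMS = {"kalman": 3, "rlck": 4, "dual": 5}

# transformed-space boxes: log-beta in [log 1e-3, log 50]; phi and omega on
# the identity scale with wide boxes (phi may be negative: uncertainty
# aversion); logit-rates in [-7, 7]
_BOUNDS = {
    "kalman": [(-20.0, 20.0), (-5.0, 5.0), (np.log(1e-3), np.log(50.0))],
    "rlck": [(-7.0, 7.0), (-7.0, 7.0), (-7.0, 7.0), (np.log(1e-3), np.log(50.0))],
    "dual": [
        (-7.0, 7.0),
        (-7.0, 7.0),
        (-7.0, 7.0),
        (np.log(1e-3), np.log(50.0)),
        (np.log(1e-3), np.log(20.0)),
    ],
}


@dataclass(frozen=True)
class FitConfig:
    n_restarts: int = 20
    seed: int = 0
    maxiter: int = 2000
    xatol: float = 1e-6
    fatol: float = 1e-8


@dataclass
class FitResult:
    model_kind: str
    params: KalmanParams | RLCKParams
    nll: float
    aic: float
    n_params: int
    converged: bool
    n_restarts: int
    seed: int

    def params_dict(self) -> dict[str, float]:
        if self.model_kind == "kalman":
            p: KalmanParams = self.params
            return {"phi": p.phi, "omega": p.omega, "beta": p.beta}
        p: RLCKParams = self.params
        out = {"alpha": p.alpha, "alpha_c": p.alpha_c, "tau": p.tau, "beta": p.beta}
        if p.gamma is not None:
            out["gamma"] = p.gamma
        return out


@dataclass
class ComparisonTable:
    """Summed AIC per model over a compared unit, with AIC weights."""

    table: pd.DataFrame  # columns: model, aic, delta_aic, weight
    best_model: str


def _session_arrays(session: SessionData) -> tuple[np.ndarray, np.ndarray]:
    choices = np.asarray(session.choices, dtype=np.int64) - 1
    rewards = np.asarray(session.rewards, dtype=np.float64)
    if choices.min() < 0 or choices.max() > 2:
        raise ValueError("choices must be coded 1-3")
    return choices, rewards


def nll(
    model_kind: str,
    params: KalmanParams | RLCKParams,
    session: SessionData,
    labels: Sequence[int] | None = None,
) -> float:
    """Negative log-likelihood of the observed choices under a model.

    The latent state is advanced with the observed (choice, reward) pairs
    using the same recursions as the simulator. For the dual-state model,
    ``labels`` supplies the per-trial explore(0)/exploit(1) labels.
    """
    choices, rewards = _session_arrays(session)
    if model_kind == "kalman":
        value, n_floored = kalman_nll_kernel(
            choices,
            rewards,
            params.phi,
            params.omega,
            params.beta,
            params.lambda_decay,
            params.theta_center,
            params.obs_noise_var,
            params.diff_noise_var,
        )
    elif model_kind in ("rlck", "dual"):
        if model_kind == "dual":
            if labels is None:
                raise ValueError("dual-state likelihood requires labels")
            if params.gamma is None:
                raise ValueError("dual-state likelihood requires gamma")
            gamma = params.gamma
            lab = np.asarray(labels, dtype=np.int64)
        else:
            gamma = -1.0
            lab = np.zeros(len(choices), dtype=np.int64)
        value, n_floored = rlck_nll_kernel(
            choices, rewards, params.alpha, params.alpha_c, params.tau,
            params.beta, gamma, lab,
        )
    elif model_kind == "random":
        return len(choices) * np.log(3.0)
    else:
        raise ValueError(f"unknown model kind: {model_kind!r}")
    if n_floored:
        warnings.warn(f"{n_floored} per-trial probabilities floored at 1e-300")
    return float(value)


def _unpack(model_kind: str, x: np.ndarray) -> KalmanParams | RLCKParams:
    if model_kind == "kalman":
        return KalmanParams(phi=x[0], omega=x[1], beta=float(np.exp(x[2])))
    if model_kind == "rlck":
        return RLCKParams(
            alpha=float(expit(x[0])),
            alpha_c=float(expit(x[1])),
            tau=float(expit(x[2])),
            beta=float(np.exp(x[3])),
        )
    return RLCKParams(
        alpha=float(expit(x[0])),
        alpha_c=float(expit(x[1])),
        tau=float(expit(x[2])),
        beta=float(np.exp(x[3])),
        gamma=float(np.exp(x[4])),
    )


def fit_model(
    session: SessionData,
    model_kind: str,
    config: FitConfig | None = None,
    labels: Sequence[int] | None = None,
) -> FitResult:
    """Best-of-restarts Nelder-Mead fit in transformed parameter space.

    Deterministic given ``config.seed``. A fit where no restart reports
    convergence is returned with ``converged=False`` rather than raising.
    """
    if model_kind not in N_PARAMS:
        raise ValueError(f"unknown model kind: {model_kind!r}")
    config = config or FitConfig()
    choices, rewards = _session_arrays(session)
    if len(choices) < 50:
        warnings.warn("fitting to fewer than 50 trials is unreliable")
    lab = None
    if model_kind == "dual":
        if labels is None:
            raise ValueError("dual-state fitting requires explore/exploit labels")
        lab = np.asarray(labels, dtype=np.int64)

    bounds = _BOUNDS[model_kind]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    if model_kind == "kalman":
        def objective(x: np.ndarray) -> float:
            v, _ = kalman_nll_kernel(
                choices, rewards, x[0], x[1], np.exp(x[2]),
                0.99, 0.5, 0.25, 0.1,
            )
            return v
    else:
        dual = model_kind == "dual"
        lab_arr = lab if dual else np.zeros(len(choices), dtype=np.int64)

        def objective(x: np.ndarray) -> float:
            g = np.exp(x[4]) if dual else -1.0
            v, _ = rlck_nll_kernel(
                choices, rewards, expit(x[0]), expit(x[1]), expit(x[2]),
                np.exp(x[3]), g, lab_arr,
            )
            return v

    rng = np.random.default_rng(config.seed)
    best_x, best_f, any_conv = None, np.inf, False
    for _ in range(config.n_restarts):
        x0 = rng.uniform(lo, hi)
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxiter": config.maxiter,
                "xatol": config.xatol,
                "fatol": config.fatol,
            },
        )
        any_conv = any_conv or bool(res.success)
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    params = _unpack(model_kind, best_x)
    k = N_PARAMS[model_kind]
    return FitResult(
        model_kind=model_kind,
        params=params,
        nll=float(best_f),
        aic=2.0 * k + 2.0 * float(best_f),
        n_params=k,
        converged=any_conv,
        n_restarts=config.n_restarts,
        seed=config.seed,
    )


def aic_weights(aics: Sequence[float]) -> np.ndarray:
    """Relative likelihoods exp(-delta/2) normalized over the model set."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def compare_models(fits_per_model: dict[str, Sequence[FitResult]]) -> ComparisonTable:
    """Sum AIC over the compared unit per model and form AIC weights.

    Every model must be fit to the same set of sessions (checked by count).
    """
    counts = {m: len(fits) for m, fits in fits_per_model.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"models were fit to different session sets: {counts}")
    models = list(fits_per_model)
    aics = [float(sum(f.aic for f in fits_per_model[m])) for m in models]
    weights = aic_weights(aics)
    delta = np.asarray(aics) - min(aics)
    table = pd.DataFrame(
        {"model": models, "aic": aics, "delta_aic": delta, "weight": weights}
    )
    best = models[int(np.argmin(aics))]
    return ComparisonTable(table=table, best_model=best)
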
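"""Inter-switch run lengths and mixture-of-geometrics analysis.

A run is a maximal block of consecutive identical choices; run lengths are
the discrete analogue of inter-event waiting times. If switching were
governed by a single per-trial hazard the run lengths would be geometric;
multiple switching regimes show up as a mixture of geometrics with
distinct mean run lengths. Mixtures of 1-4 components are fit by EM and
the component count is chosen by an explicit elbow rule on the per-step
log-likelihood gains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RunLengths",
    "GeoMixtureFit",
    "MixtureFitConfig",
    "ComponentSelection",
    "run_lengths",
    "geometric_sample",
    "fit_geo_mixture",
    "select_components",
]


@dataclass(frozen=True)
class RunLengths:
    """Lengths of maximal constant-choice runs; the final censored run is
    included uncorrected."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        if (self.intervals < 1).any():
            raise ValueError("run lengths must be positive")


@dataclass(frozen=True)
class MixtureFitConfig:
    n_restarts: int = 20
    tol: float = 1e-8
    max_iter: int = 2000
    seed: int = 0


@dataclass
class GeoMixtureFit:
    """EM fit of a mixture of geometrics on support {1, 2, ...}.

    ``success_probs`` are the per-component switch hazards p_i; mean run
    length of component i is 1/p_i (the discrete scale parameter).
    Components are sorted by increasing mean.
    """

    n_components: int
    weights: np.ndarray
    success_probs: np.ndarray
    loglik: float
    aic: float
    n_iterations: int
    seed: int
    converged: bool = True

    @property
    def means(self) -> np.ndarray:
        return 1.0 / self.success_probs


@dataclass
class ComponentSelection:
    selected: int
    logliks: dict[int, float]
    aics: dict[int, float]
    gains: dict[int, float]
    elbow_fraction: float
    min_gain: float


def run_lengths(choices: Sequence[int]) -> RunLengths:
    """Extract maximal runs of identical consecutive choices."""
    arr = np.asarray(choices)
    if arr.size == 0:
        raise ValueError("choices must be non-empty")
    boundaries = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    edges = np.concatenate(([0], boundaries, [arr.size]))
    return RunLengths(intervals=np.diff(edges))


def geometric_sample(
    weights: Sequence[float], means: Sequence[float], n: int, seed: int = 0
) -> np.ndarray:
    """Sample run lengths from a mixture of geometrics given mean lengths."""
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, float)
    probs = 1.0 / np.asarray(means, float)
    comp = rng.choice(len(weights), size=n, p=weights / weights.sum())
    return rng.geometric(probs[comp])


def _mixture_loglik(x: np.ndarray, w: np.ndarray, p: np.ndarray) -> float:
    # pmf: p (1-p)^(x-1) on {1, 2, ...}
    log_pmf = np.log(p)[None, :] + (x[:, None] - 1) * np.log1p(-p)[None, :]
    m = log_pmf.max(axis=1, keepdims=True)
    return float(
        (m.ravel() + np.log(np.exp(log_pmf - m) @ w)).sum()
    )


def fit_geo_mixture(
    intervals: RunLengths | Sequence[int],
    n_components: int,
    config: MixtureFitConfig | None = None,
) -> GeoMixtureFit:
    """EM for a mixture of 1-4 geometric distributions.

    The M-step is closed form: p_i = (sum of responsibilities) / (sum of
    responsibility-weighted run lengths). Best of ``n_restarts`` random
    initializations is returned; deterministic given the config seed.
    """
    if not 1 <= n_components <= 4:
        raise ValueError("n_components must be in 1..4")
    config = config or MixtureFitConfig()
    x = np.asarray(
        intervals.intervals if isinstance(intervals, RunLengths) else intervals,
        dtype=float,
    )
    if x.size < 10 * n_components:
        warnings.warn(
            f"only {x.size} intervals for {n_components} components; "
            "estimates will be noisy"
        )
    # collapse to unique values with counts: run lengths are small integers
    vals, counts = np.unique(x, return_counts=True)
    cnt = counts.astype(float)

    rng = np.random.default_rng(config.seed)
    best = None
    for restart in range(config.n_restarts):
        if restart == 0:
            # deterministic spread init: component means at data quantiles
            w = np.full(n_components, 1.0 / n_components)
            q = np.quantile(x, (np.arange(n_components) + 0.5) / n_components)
            p = np.clip(1.0 / np.maximum(q, 1.0), 1e-10, 1.0 - 1e-9)
        else:
            w = rng.dirichlet(np.ones(n_components))
            p = 1.0 / rng.uniform(1.0, max(2.0, 2.0 * x.mean()), n_components)
        prev_ll = -np.inf
        n_iter = 0
        converged = False
        for it in range(config.max_iter):
            n_iter = it + 1
            log_pmf = (
                np.log(p)[None, :]
                + (vals[:, None] - 1.0) * np.log1p(-p)[None, :]
                + np.log(w)[None, :]
            )
            m = log_pmf.max(axis=1, keepdims=True)
            norm = np.exp(log_pmf - m)
            denom = norm.sum(axis=1, keepdims=True)
            resp = norm / denom
            ll = float((cnt * (m.ravel() + np.log(denom.ravel()))).sum())
            if ll - prev_ll < config.tol and it > 0:
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
            r = resp * cnt[:, None]
            n_i = r.sum(axis=0)
            w = n_i / n_i.sum()
            p = np.clip(n_i / (r * vals[:, None]).sum(axis=0), 1e-10, 1.0 - 1e-12)
        if best is None or prev_ll > best[0]:
            best = (prev_ll, w, p, n_iter, converged)
    ll, w, p, n_iter, converged = best
    order = np.argsort(1.0 / p)  # sort by increasing mean
    k_free = 2 * n_components - 1
    return GeoMixtureFit(
        n_components=n_components,
        weights=w[order],
        success_probs=p[order],
        loglik=ll,
        aic=2.0 * k_free + 2.0 * (-ll),
        n_iterations=n_iter,
        seed=config.seed,
        converged=converged,
    )


def select_components(
    fits: Sequence[GeoMixtureFit],
    elbow_fraction: float = 0.10,
    min_gain: float = 2.0,
) -> ComponentSelection:
    """Choose the component count at the elbow of the log-likelihood curve.

    Scanning n = 2, 3, 4 in order, a component is accepted while its
    incremental log-likelihood gain both clears ``min_gain`` (the AIC
    break-even for two extra parameters) and is at least
    ``elbow_fraction`` of the largest single-step gain; the scan stops at
    the first failure. With no acceptable gains the selection is 1.
    """
    by_n = {f.n_components: f for f in fits}
    ns = sorted(by_n)
    if ns != list(range(1, len(ns) + 1)):
        raise ValueError("fits must cover consecutive component counts from 1")
    logliks = {n: by_n[n].loglik for n in ns}
    aics = {n: by_n[n].aic for n in ns}
    gains = {n: logliks[n] - logliks[n - 1] for n in ns[1:]}
    for n, g in gains.items():
        if g < -1e-6:
            warnings.warn(
                f"log-likelihood decreased from {n - 1} to {n} components; "
                "EM may not have converged"
            )
    max_gain = max(gains.values()) if gains else 0.0
    selected = 1
    for n in ns[1:]:
        if gains[n] >= min_gain and gains[n] >= elbow_fraction * max_gain:
            selected = n
        else:
            break
    return ComponentSelection(
        selected=selected,
        logliks=logliks,
        aics=aics,
        gains=gains,
        elbow_fraction=elbow_fraction,
        min_gain=min_gain,
    )
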
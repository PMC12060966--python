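"""Cohort-level computational subtyping.

Five per-participant features (two task-derived computational parameters
plus three cognitive measures) are z-scored and passed through PCA with a
permutation test on the loadings, then Ward hierarchical clustering with
three cluster-quality indices over k = 2..6. Reliability across sessions
is quantified by a two-way consistency intraclass correlation, and subtype
x group contingency tables by adjusted Pearson residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = [
    "FEATURES",
    "PCAResult",
    "ClusterResult",
    "zscore_features",
    "pca_with_permutation",
    "ward_cluster",
    "icc_consistency",
    "adjusted_residuals",
    "subtype_profiles",
]

FEATURES = [
    "uncertainty_intolerance",
    "decision_noise",
    "processing_speed",
    "verbal_memory",
    "executive_function",
]

# radar-plot convention: these two are sign-inverted for display so that
# larger always reads as "more impaired"
INVERTED_FOR_DISPLAY = ("uncertainty_intolerance", "decision_noise")


@dataclass
class PCAResult:
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x components
    scores: np.ndarray
    p_values: pd.DataFrame  # features x components
    n_permutations: int
    n_dropped: int
    seed: int


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels_by_k: dict[int, np.ndarray]
    silhouette: dict[int, float]
    calinski_harabasz: dict[int, float]
    davies_bouldin: dict[int, float]
    selected_k: int
    profiles: pd.DataFrame


def zscore_features(
    table: pd.DataFrame, features: list[str] | None = None
) -> pd.DataFrame:
    """Z-score the feature columns (population sd, ddof=0)."""
    features = features or FEATURES
    X = table[features].astype(float)
    sd = X.std(ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant feature column(s): {bad}")
    return (X - X.mean()) / sd


def pca_with_permutation(
    table: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    features: list[str] | None = None,
) -> PCAResult:
    """PCA on z-scored features with permutation p-values on the loadings.

    Null loadings come from independently shuffling each feature column
    (destroying inter-feature correlation while preserving marginals) and
    re-running the PCA. Because eigenvector order and sign are arbitrary,
    each permuted component is matched to the observed component with
    maximal absolute congruence before its loading enters the null
    distribution. p-values are two-sided on |loading|.
    """
    features = features or FEATURES
    clean = table.dropna(subset=features)
    n_dropped = len(table) - len(clean)
    if len(clean) < 10:
        raise ValueError("need at least 10 complete rows for PCA")
    Z = zscore_features(clean, features).to_numpy()
    n, d = Z.shape

    pca = PCA(n_components=d)
    scores = pca.fit_transform(Z)
    obs_loadings = pca.components_.T  # features x components

    rng = np.random.default_rng(seed)
    exceed = np.zeros((d, d))
    for _ in range(n_perm):
        perm = np.empty_like(Z)
        for j in range(d):
            perm[:, j] = Z[rng.permutation(n), j]
        null_load = PCA(n_components=d).fit(perm).components_.T
        # greedy match: for each observed component pick the most congruent
        # permuted component (absolute cosine of loading vectors)
        congruence = np.abs(obs_loadings.T @ null_load)
        matched = congruence.argmax(axis=1)
        exceed += np.abs(null_load[:, matched]) >= np.abs(obs_loadings)
    p_values = (exceed + 1.0) / (n_perm + 1.0)

    cols = [f"PC{i + 1}" for i in range(d)]
    return PCAResult(
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(obs_loadings, index=features, columns=cols),
        scores=scores,
        p_values=pd.DataFrame(p_values, index=features, columns=cols),
        n_permutations=n_perm,
        n_dropped=n_dropped,
        seed=seed,
    )


def ward_cluster(
    table: pd.DataFrame,
    k_range: range | tuple[int, int] = (2, 6),
    features: list[str] | None = None,
) -> ClusterResult:
    """Ward minimum-variance clustering of z-scored features.

    Evaluates every k in the range with silhouette, Calinski-Harabasz and
    Davies-Bouldin indices; the selected k maximizes silhouette, with ties
    broken by Calinski-Harabasz.
    """
    features = features or FEATURES
    if isinstance(k_range, tuple):
        ks = list(range(k_range[0], k_range[1] + 1))
    else:
        ks = list(k_range)
    Z = zscore_features(table.dropna(subset=features), features)
    X = Z.to_numpy()
    if len(X) <= max(ks):
        raise ValueError("not enough rows for the requested cluster counts")
    tree = linkage(X, method="ward")
    labels_by_k, sil, ch, db = {}, {}, {}, {}
    for k in ks:
        labels = fcluster(tree, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        sil[k] = float(silhouette_score(X, labels))
        ch[k] = float(calinski_harabasz_score(X, labels))
        db[k] = float(davies_bouldin_score(X, labels))
    best_sil = max(sil.values())
    tied = [k for k in ks if np.isclose(sil[k], best_sil)]
    selected = max(tied, key=lambda k: ch[k]) if len(tied) > 1 else tied[0]
    profiles = subtype_profiles(Z, labels_by_k[selected], features=features,
                                already_scaled=True)
    return ClusterResult(
        linkage=tree,
        labels_by_k=labels_by_k,
        silhouette=sil,
        calinski_harabasz=ch,
        davies_bouldin=db,
        selected_k=selected,
        profiles=profiles,
    )


def icc_consistency(values_session1, values_session2) -> float:
    """Two-way mixed, single-measure, consistency ICC across two sessions.

    Computed from the participants x sessions ANOVA decomposition as
    (MS_rows - MS_error) / (MS_rows + MS_error); additive session offsets
    do not affect it.
    """
    y1 = np.asarray(values_session1, dtype=float)
    y2 = np.asarray(values_session2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("sessions must be paired 1-D arrays")
    n = y1.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    Y = np.column_stack([y1, y2])
    k = 2
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows + ms_err == 0:
        raise ValueError("zero between-participant variance")
    return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))


def adjusted_residuals(table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Adjusted Pearson residuals of a two-way count table:
    (O - E) / sqrt(E (1 - row_total/N) (1 - col_total/N))."""
    df = pd.DataFrame(table)
    O = df.to_numpy(dtype=float)
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    N = O.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("contingency table has a zero margin")
    E = row * col / N
    denom = np.sqrt(E * (1.0 - row / N) * (1.0 - col / N))
    return pd.DataFrame((O - E) / denom, index=df.index, columns=df.columns)


def subtype_profiles(
    table: pd.DataFrame,
    labels,
    features: list[str] | None = None,
    invert_for_display: bool = False,
    already_scaled: bool = False,
) -> pd.DataFrame:
    """Per-cluster mean feature vectors on the z-scored scale (radar data).

    With ``invert_for_display`` the two computational parameters are
    sign-flipped, following the radar convention where larger means more
    impaired.
    """
    features = features or FEATURES
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValueError("labels must align with the table rows")
    Z = table[features] if already_scaled else zscore_features(table, features)
    prof = Z.groupby(labels).mean()
    if prof.isna().any().any():
        raise ValueError("empty cluster encountered")
    if invert_for_display:
        for f in INVERTED_FOR_DISPLAY:
            if f in prof.columns:
                prof[f] = -prof[f]
    prof.index.name = "cluster"
    return prof
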
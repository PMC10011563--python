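"""Unsupervised sorting and discriminant ordination.

PCA and K-means act on the preprocessed specimens x wavenumber matrix;
features are mean-centered but not variance-scaled (the spectra are already
min-max normalized, and per-wavenumber scaling would inflate noise in
low-signal regions).  The compositional sanity check asks whether apparent
clustering merely tracks total organic abundance relative to silica — if
both organic/silica ratios rise along the same component, the axis reflects
abundance, not composition.

The discriminant ordination is canonical variates analysis (multi-class
LDA): eigenvectors of pooled-within^-1 x between-group covariance of the
band-intensity matrix, with passive specimens (e.g. fossils of unknown
affinity) projected onto the axes but excluded from fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA as _SkPCA
from sklearn.metrics import silhouette_score


@dataclass
class PCAResult:
    scores: pd.DataFrame            # specimens x components
    loadings: pd.DataFrame          # components x wavenumbers, rows orthonormal
    explained_variance_fraction: np.ndarray
    n_components: int
    mean: np.ndarray = field(repr=False, default=None)


def pca(matrix: pd.DataFrame, n_components: int = 6) -> PCAResult:
    """Principal component analysis of the feature matrix.

    Mean-centered, unscaled.  Deterministic sign convention: within each
    loading vector the largest-magnitude element is positive.  A matrix of
    identical rows has zero total variance and is an error.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least n_components+1={n_components + 1} rows, got {X.shape[0]}"
        )
    if np.allclose(X, X[0], atol=0, rtol=0) or np.isclose(
        ((X - X.mean(axis=0)) ** 2).sum(), 0.0
    ):
        raise ValueError("zero total variance: all rows identical")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_
    # sign convention
    for j in range(loadings.shape[0]):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=comp_names, columns=matrix.columns),
        explained_variance_fraction=model.explained_variance_ratio_.copy(),
        n_components=n_components,
        mean=model.mean_,
    )


@dataclass
class ClusterResult:
    assignments: pd.Series
    k: int
    centroids: np.ndarray
    inertia: float
    seed: int | None
    n_iter: int
    silhouette_by_k: dict[int, float] | None = None


def kmeans(
    matrix: pd.DataFrame,
    k: int = 2,
    n_iter_max: int = 300,
    seed: int | None = 0,
    n_restarts: int = 10,
    silhouette_scan: tuple[int, int] | None = (2, 6),
) -> ClusterResult:
    """K-means clustering: Lloyd's algorithm, random data-row initialisation,
    best of `n_restarts` by inertia; fully reproducible given `seed`.

    Because no selection rule fixes k a priori, a silhouette scan over
    k = 2..6 is reported alongside the chosen clustering.
    """
    X = matrix.to_numpy(dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of specimens {X.shape[0]}")
    model = KMeans(
        n_clusters=k, init="random", n_init=n_restarts,
        max_iter=n_iter_max, random_state=seed,
    ).fit(X)
    scan = None
    if silhouette_scan is not None and X.shape[0] > 3:
        lo, hi = silhouette_scan
        scan = {}
        for kk in range(lo, min(hi, X.shape[0] - 1) + 1):
            labels = KMeans(
                n_clusters=kk, init="random", n_init=n_restarts,
                max_iter=n_iter_max, random_state=seed,
            ).fit_predict(X)
            if len(set(labels)) > 1:
                scan[kk] = float(silhouette_score(X, labels))
    return ClusterResult(
        assignments=pd.Series(model.labels_, index=matrix.index, name="cluster"),
        k=k,
        centroids=model.cluster_centers_,
        inertia=float(model.inertia_),
        seed=seed,
        n_iter=int(model.n_iter_),
        silhouette_by_k=scan,
    )


def cluster_vs_truth(
    assignments: Sequence[int] | pd.Series, truth_labels: Sequence
) -> tuple[float, list]:
    """Clustering accuracy maximized over cluster-label permutations.

    Returns (accuracy, misassigned specimen ids); ids are positions unless
    `assignments` is an indexed Series.
    """
    a = pd.Series(assignments)
    t = pd.Series(list(truth_labels), index=a.index)
    if len(a) != len(t):
        raise ValueError("assignments and truth labels differ in length")
    clusters = sorted(a.unique())
    labels = sorted(t.unique())
    conf = np.zeros((len(clusters), len(labels)))
    for i, c in enumerate(clusters):
        for j, l in enumerate(labels):
            conf[i, j] = ((a == c) & (t == l)).sum()
    rows, cols = linear_sum_assignment(-conf)
    mapping = {clusters[i]: labels[j] for i, j in zip(rows, cols)}
    predicted = a.map(mapping)
    correct = predicted == t
    return float(correct.mean()), list(a.index[~correct])


def abundance_sanity_check(
    pca_result: PCAResult,
    ratios: pd.DataFrame,
    components: Sequence[str] = ("PC1", "PC2"),
    strong: float = 0.7,
) -> dict:
    """Test whether PCA clustering is compositional or abundance-driven.

    For each component the Spearman correlation of scores with CH2/silica
    and with C=O/silica is computed.  If both ratios rise together along
    some component (same sign, both |rho| >= `strong`), that axis tracks
    total organic abundance and ``compositional`` is False; if no component
    shows such co-increase, the sorting is compositional.  The default
    `strong` of 0.7 (at least half the variance shared) marks an axis as
    abundance-driven only when both ratios genuinely track it, not when one
    merely co-varies incidentally.
    """
    missing = set(pca_result.scores.index) - set(ratios.index)
    if missing:
        raise ValueError(f"ratio values missing for specimens: {sorted(missing)}")
    r = ratios.loc[pca_result.scores.index]
    per_component = {}
    abundance_axes = []
    warning = None
    for comp in components:
        s = pca_result.scores[comp].to_numpy()
        cors = {}
        for name in ("CH2_silica", "CO_silica"):
            v = r[name].to_numpy(dtype=float)
            if np.allclose(v, v[0]):
                cors[name] = 0.0
                warning = f"{name} is constant; correlations degenerate"
            else:
                cors[name] = float(stats.spearmanr(s, v).statistic)
        per_component[comp] = cors
        both_strong = all(abs(c) >= strong for c in cors.values())
        same_sign = np.sign(cors["CH2_silica"]) == np.sign(cors["CO_silica"]) != 0
        if both_strong and same_sign:
            abundance_axes.append(comp)
    return {
        "per_component": per_component,
        "abundance_axes": abundance_axes,
        "compositional": len(abundance_axes) == 0 and warning is None,
        "warning": warning,
    }


@dataclass
class DiscriminantResult:
    scores: pd.DataFrame            # active specimens x axes
    passive_scores: pd.DataFrame    # passive specimens x axes
    group_centroids: pd.DataFrame   # groups x axes
    eigenvalues: np.ndarray
    coefficients: pd.DataFrame      # bands x axes (unit-norm axis vectors)
    axis1_top_bands: list[str]


def discriminant_analysis(
    band_matrix: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series | None = None,
    passive_ids: Sequence[str] = (),
    n_top: int = 3,
) -> DiscriminantResult:
    """Canonical variates analysis of the band-intensity matrix.

    Axes are eigenvectors of pooled-within^-1 x between-group covariance,
    fitted on active specimens only; `passive_ids` are projected onto the
    fitted axes without influencing them.  A singular pooled-within matrix
    is ridge-regularized with lambda = 1e-6 * trace and a warning.  Axis
    count = min(n_groups - 1, n_bands); axis orientation: the centroid of
    the alphabetically last group scores above the first group's on axis 1,
    higher axes take the largest-|coefficient| band positive.
    """
    import warnings as _w

    if groups is None:
        groups = band_matrix.attrs.get("groups")
    if groups is None:
        raise ValueError("group labels required (mapping specimen_id -> group)")
    g = pd.Series(dict(groups)).reindex(band_matrix.index)
    passive_ids = list(passive_ids)
    active = band_matrix.index.difference(passive_ids, sort=False)
    ga = g.loc[active].dropna()
    active = ga.index
    counts = ga.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError(
            f"need >= 2 groups with >= 2 active members each, got {counts.to_dict()}"
        )
    X = band_matrix.loc[active].to_numpy(dtype=float)
    p = X.shape[1]
    grand = X.mean(axis=0)
    group_names = sorted(counts.index)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for name in group_names:
        Xi = band_matrix.loc[active[np.asarray(ga == name)]].to_numpy(dtype=float)
        d = Xi - Xi.mean(axis=0)
        W += d.T @ d
        m = Xi.mean(axis=0) - grand
        B += len(Xi) * np.outer(m, m)
    W /= len(active) - len(group_names)
    if np.linalg.cond(W) > 1e12:
        _w.warn("pooled within-group covariance is singular; ridge-regularizing")
        W = W + 1e-6 * np.trace(W) * np.eye(p)
    evals, evecs = np.linalg.eig(np.linalg.solve(W, B))
    order = np.argsort(evals.real)[::-1]
    n_axes = min(len(group_names) - 1, p)
    evals = evals.real[order][:n_axes]
    V = evecs.real[:, order][:, :n_axes]
    V /= np.linalg.norm(V, axis=0)
    axes = [f"CV{j + 1}" for j in range(n_axes)]
    scores_a = (X - grand) @ V
    cent = {
        name: scores_a[np.asarray(ga == name)].mean(axis=0) for name in group_names
    }
    # orientation
    for j in range(n_axes):
        if j == 0 and len(group_names) >= 2:
            lo_g, hi_g = group_names[0], group_names[-1]
            if cent[hi_g][0] < cent[lo_g][0]:
                V[:, 0] *= -1
        else:
            i = int(np.argmax(np.abs(V[:, j])))
            if V[i, j] < 0:
                V[:, j] *= -1
    scores_a = (X - grand) @ V
    centroids = pd.DataFrame(
        [(band_matrix.loc[active[np.asarray(ga == n)]].to_numpy(dtype=float).mean(axis=0) - grand) @ V
         for n in group_names],
        index=group_names, columns=axes,
    )
    Xp = band_matrix.loc[passive_ids].to_numpy(dtype=float) if passive_ids else np.zeros((0, p))
    scores_p = (Xp - grand) @ V
    coef = pd.DataFrame(V, index=band_matrix.columns, columns=axes)
    top = list(coef["CV1"].abs().sort_values(ascending=False).index[:n_top])
    return DiscriminantResult(
        scores=pd.DataFrame(scores_a, index=active, columns=axes),
        passive_scores=pd.DataFrame(scores_p, index=pd.Index(passive_ids), columns=axes),
        group_centroids=centroids,
        eigenvalues=evals,
        coefficients=coef,
        axis1_top_bands=top,
    )
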
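"""Unsupervised grouping of cases from engineered symmetry features.

Simple k-means (Lloyd's algorithm with k-means++ seeding) and Gaussian
mixture EM, with optional PCA pre-reduction.  The default attribute set
mirrors the published screening combination: central 95% range in the
6.0 mm zone plus absolute mean, standard deviation and volume
difference in the central 3.0 mm zone, with k = 3.

The Lloyd loop is written out explicitly so the objective (total
within-cluster sum of squared errors) can be asserted non-increasing at
every iteration; scikit-learn supplies the k-means++ initialisation,
the mixture model and PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import kmeans_plusplus
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .zones import FEATURE_NAMES, zone_column

#: published screening attribute combination
TABLE1_FEATURES: tuple[str, ...] = (
    zone_column(6.0, "central95_range"),
    zone_column(3.0, "abs_mean"),
    zone_column(3.0, "sd"),
    zone_column(3.0, "volume_diff"),
)


class Algorithm(str, Enum):
    KMEANS = "kmeans"
    EM = "em"


@dataclass(frozen=True)
class ClusterConfig:
    algorithm: Algorithm = Algorithm.KMEANS
    k: int = 3
    selected_features: tuple[str, ...] = TABLE1_FEATURES
    standardize: bool = True
    pca_components: int | None = None
    seed: int = 0
    max_iter: int = 100


@dataclass
class ClusterResult:
    """Clustering outcome, clusters renumbered in descending size order.

    ``centroids`` are reported in original (unstandardized) feature
    units; ``within_ss`` is the objective in the model's fitting space
    (standardized / PCA-reduced when those options are on).
    """

    assignments: pd.Series  # case_id -> cluster index
    centroids: pd.DataFrame  # cluster x feature, original units
    sizes: np.ndarray
    within_ss: float
    iterations_run: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)
    config: ClusterConfig | None = None

    def __post_init__(self) -> None:
        if int(self.sizes.sum()) != len(self.assignments):
            raise ValueError("cluster sizes must sum to the number of cases")
        if self.within_ss < -1e-12:
            raise ValueError("within-cluster SSE must be non-negative")


def _lloyd_kmeans(
    X: np.ndarray, k: int, seed: int, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    """Lloyd iterations from a k-means++ start, tracking the objective."""
    rng = np.random.default_rng(seed)
    centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=seed)
    history: list[float] = []
    labels = np.zeros(len(X), dtype=int)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        obj = float(d2[np.arange(len(X)), labels].sum())
        if history and obj > history[-1] + 1e-9:
            raise AssertionError("k-means objective increased between iterations")
        history.append(obj)
        new_centers = centers.copy()
        for c in range(k):
            members = X[labels == c]
            if len(members):
                new_centers[c] = members.mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its center
                far = d2.min(axis=1).argmax()
                new_centers[c] = X[far]
        if np.allclose(new_centers, centers, atol=1e-12, rtol=0.0):
            converged = True
            break
        centers = new_centers
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    within = float(d2[np.arange(len(X)), labels].sum())
    return labels, centers, within, it, converged, history


def cluster_cases(table: pd.DataFrame, config: ClusterConfig = ClusterConfig()) -> ClusterResult:
    """Cluster the feature table; deterministic given ``config.seed``.

    Features are taken in the order listed in the config; zero-variance
    features are dropped with a warning before standardization.  Rows
    with missing values in the selected features are a caller error.
    """
    if table.empty:
        raise ValueError("feature table is empty")
    missing_cols = [c for c in config.selected_features if c not in table.columns]
    if missing_cols:
        raise KeyError(f"selected features not in table: {missing_cols}")
    if config.k < 1 or config.k > len(table):
        raise ValueError(f"k={config.k} invalid for {len(table)} cases")

    # deterministic row order regardless of input permutation
    table = table.sort_index()
    X_orig = table.loc[:, list(config.selected_features)].to_numpy(dtype=float)
    if not np.isfinite(X_orig).all():
        raise ValueError("selected features contain missing values; filter or impute first")

    feat_names = list(config.selected_features)
    keep = X_orig.std(axis=0) > 0
    standardize = config.standardize
    if not keep.any():
        # all features constant (e.g. a single case): keep them unscaled
        standardize = False
    elif not keep.all():
        dropped = [f for f, k_ in zip(feat_names, keep) if not k_]
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        X_orig = X_orig[:, keep]
        feat_names = [f for f, k_ in zip(feat_names, keep) if k_]

    if standardize:
        mu, sigma = X_orig.mean(axis=0), X_orig.std(axis=0, ddof=0)
        X = (X_orig - mu) / sigma
    else:
        X = X_orig.copy()

    if config.pca_components is not None:
        pca = PCA(n_components=config.pca_components, random_state=config.seed)
        X = pca.fit_transform(X)

    if config.algorithm is Algorithm.KMEANS:
        labels, _, within, iters, converged, history = _lloyd_kmeans(
            X, config.k, config.seed, config.max_iter
        )
    else:
        gmm = GaussianMixture(
            n_components=config.k,
            covariance_type="full",
            random_state=config.seed,
            max_iter=config.max_iter,
        )
        labels = gmm.fit_predict(X)
        means = gmm.means_[labels]
        within = float(((X - means) ** 2).sum())
        iters, converged, history = int(gmm.n_iter_), bool(gmm.converged_), []

    # canonical numbering: descending cluster size, ties by old index
    sizes_raw = np.bincount(labels, minlength=config.k)
    order = np.argsort(-sizes_raw, kind="stable")
    relabel = np.empty(config.k, dtype=int)
    relabel[order] = np.arange(config.k)
    labels = relabel[labels]
    sizes = np.bincount(labels, minlength=config.k)

    centroids = pd.DataFrame(
        [X_orig[labels == c].mean(axis=0) if sizes[c] else np.full(len(feat_names), np.nan)
         for c in range(config.k)],
        columns=feat_names,
    )
    centroids.index.name = "cluster"

    assignments = pd.Series(labels, index=table.index, name="cluster")
    return ClusterResult(
        assignments=assignments,
        centroids=centroids,
        sizes=sizes,
        within_ss=within,
        iterations_run=iters,
        converged=converged,
        objective_history=history,
        config=config,
    )


def summarize_clusters(
    table: pd.DataFrame, assignments: pd.Series
) -> pd.DataFrame:
    """Per-cluster mean +/- SD of every feature with one-way ANOVA across
    clusters.

    Returns one row per feature column with ``mean_<c>`` / ``sd_<c>``
    per cluster and ``anova_F`` / ``anova_p``.  SD is NaN for clusters
    of fewer than two cases; ANOVA is reported as degenerate (NaN with
    ``degenerate=True``) when every group has zero variance.
    """
    if not assignments.index.equals(table.index):
        assignments = assignments.reindex(table.index)
    if assignments.isna().any():
        raise ValueError("every case in the table must be assigned a cluster")
    clusters = sorted(assignments.unique())
    rows = []
    for col in table.columns:
        row: dict[str, float | bool | str] = {"feature": col}
        groups = []
        for c in clusters:
            g = table.loc[assignments == c, col].to_numpy(dtype=float)
            groups.append(g)
            row[f"mean_{c}"] = float(g.mean()) if len(g) else np.nan
            row[f"sd_{c}"] = float(g.std(ddof=1)) if len(g) >= 2 else np.nan
        degenerate = all(np.ptp(g) == 0 for g in groups if len(g))
        if len(clusters) >= 2 and not degenerate:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                F, p = stats.f_oneway(*groups)
            row["anova_F"], row["anova_p"] = float(F), float(p)
            row["degenerate"] = False
        else:
            row["anova_F"], row["anova_p"] = np.nan, np.nan
            row["degenerate"] = True
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def format_report(result: ClusterResult) -> str:
    """Text report mirroring a WEKA-style centroid table: attribute rows,
    one column per cluster plus the full-data column, then sizes and the
    objective."""
    cent = result.centroids
    n = int(result.sizes.sum())
    full = (cent.T * result.sizes).T.sum(axis=0) / n
    lines = [
        f"Clustering model: {result.config.algorithm.value if result.config else '?'}",
        f"Number of iterations: {result.iterations_run}",
        f"Within cluster sum of squared errors: {result.within_ss:.4f}",
        "",
        "Attribute\tFull Data\t" + "\t".join(f"Cluster {c + 1}" for c in cent.index),
    ]
    for feat in cent.columns:
        vals = "\t".join(f"{cent.loc[c, feat]:.4f}" for c in cent.index)
        lines.append(f"{feat}\t{full[feat]:.4f}\t{vals}")
    lines.append("")
    for c in cent.index:
        pct = 100.0 * result.sizes[c] / n
        lines.append(f"Cluster {c + 1}: {result.sizes[c]} cases ({pct:.1f}%)")
    return "\n".join(lines)
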
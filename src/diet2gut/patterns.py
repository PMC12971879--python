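"""Exploratory dietary-pattern structure: PCA and k-means with elbow k.

PCA is run on the (optionally z-scored) dietary index table to summarise how
the indices co-vary; k-means on the PCA scores partitions subjects into
dietary-behaviour clusters, with the number of clusters suggested by the
elbow (maximum curvature) of the within-cluster sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "PcaResult",
    "ClusterResult",
    "pca_decompose",
    "kmeans_fit",
    "kmeans_scan",
    "select_k_elbow",
    "pearson_corr",
    "top_correlated_items",
]


@dataclass
class PcaResult:
    loadings: pd.DataFrame        # variables x components
    scores: pd.DataFrame          # subjects x components
    variance_explained: np.ndarray


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series             # 1-based cluster ids per subject
    wss: float
    seed: int


def pca_decompose(table: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of a subjects x variables table via SVD.

    With ``standardize`` the variables are z-scored with sample SD so that
    the component variances sum to the number of variables (correlation-matrix
    trace). Sign convention: the largest-magnitude loading of each component
    is made positive, so results are deterministic.
    """
    if table.isna().any().any():
        raise ValueError("PCA input contains missing values")
    if len(table) <= table.shape[1]:
        raise ValueError("PCA needs more subjects than variables")
    X = table.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = table.columns[sd == 0].tolist()
            raise ValueError(f"constant column(s): {bad}")
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)

    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # variables x components

    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=table.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        variance_explained=pca.explained_variance_,
    )


def kmeans_fit(
    scores: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10
) -> ClusterResult:
    """K-means (k-means++ seeding, best of ``n_init`` starts) on PCA scores."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(scores)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(scores.to_numpy(dtype=float))
    return ClusterResult(
        k=k,
        labels=pd.Series(labels + 1, index=scores.index, name="cluster"),
        wss=float(km.inertia_),
        seed=seed,
    )


def kmeans_scan(
    scores: pd.DataFrame, k_range=range(1, 11), seed: int = 0, n_init: int = 10
) -> dict[int, float]:
    """Within-cluster sum of squares over a range of k (default 1..10)."""
    return {k: kmeans_fit(scores, k, seed=seed, n_init=n_init).wss for k in k_range}


def select_k_elbow(wss_by_k: dict[int, float]) -> int:
    """Elbow k: the interior k maximising the WSS second difference.

    ``WSS(k-1) - 2*WSS(k) + WSS(k+1)`` is evaluated over consecutive k; ties
    resolve to the smaller k. Requires at least 3 consecutive k values; a
    non-monotone WSS profile triggers a warning (k-means found a worse local
    optimum at larger k) but is still scored.
    """
    ks = sorted(wss_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive k values")
    wss = np.array([wss_by_k[k] for k in ks])
    if (np.diff(wss) > 0).any():
        warnings.warn("WSS is not monotone nonincreasing in k", stacklevel=2)
    second_diff = wss[:-2] - 2 * wss[1:-1] + wss[2:]
    best = int(np.argmax(second_diff))  # argmax takes the first (smallest k) on ties
    return ks[best + 1]


def pearson_corr(x, y) -> float:
    """Sample Pearson correlation (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def top_correlated_items(
    scores: pd.DataFrame, items: pd.DataFrame, k: int = 8
) -> pd.DataFrame:
    """Per-index top-k most positively correlated food items (biplot table).

    Returns a tidy table (index, item, r) with the ``k`` items most
    positively Pearson-correlated with each dietary index.
    """
    shared = scores.index.intersection(items.index)
    rows = []
    for index_name in scores.columns:
        rs = {
            item: pearson_corr(scores.loc[shared, index_name], items.loc[shared, item])
            for item in items.columns
        }
        top = sorted(rs.items(), key=lambda kv: -kv[1])[:k]
        rows += [{"index": index_name, "item": it, "r": r} for it, r in top]
    return pd.DataFrame(rows)
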
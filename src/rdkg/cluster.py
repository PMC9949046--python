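"""k-means disease clustering, kneedle model selection, internal metrics.

The number of clusters K is chosen from the inertia-versus-K curve with the
kneedle knee detector: both axes are min-max normalized, the (decreasing,
convex) curve is compared with the straight chord joining its endpoints, and
the K with the maximal gap below the chord is the knee, provided the gap
exceeds a sensitivity threshold.  Internal metrics (silhouette,
Davies-Bouldin, Calinski-Harabasz) quantify clustering quality for the
hyperparameter sensitivity scan; no ground-truth labels are needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .embed import EmbeddingMatrix, EmbedParams, train_embedding
from .walks import WalkParams, generate_walks

__all__ = [
    "ClusterModel",
    "kmeans_fit",
    "kneedle_select",
    "internal_metrics",
    "select_k",
    "sensitivity_scan",
]


@dataclass
class ClusterModel:
    K: int
    labels: dict[str, int]
    centroids: np.ndarray
    inertia: float
    metrics: dict[str, float]

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["disease_id", "cluster"]
        )


def kmeans_fit(
    emb: EmbeddingMatrix, K: int, seed: int = 0, n_init: int = 10
) -> ClusterModel:
    """Best of ``n_init`` k-means++ runs by inertia (Euclidean distance)."""
    n = len(emb.disease_ids)
    if not 1 <= K <= n:
        raise ValueError(f"K={K} must lie in [1, {n}]")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    assignment = km.fit_predict(emb.vectors)
    labels = {d: int(c) for d, c in zip(emb.disease_ids, assignment)}
    metrics: dict[str, float] = {}
    if 2 <= K <= n - 1:
        metrics = internal_metrics(emb, labels)
    return ClusterModel(
        K=K,
        labels=labels,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        metrics=metrics,
    )


def internal_metrics(
    emb: EmbeddingMatrix, labels: Mapping[str, int]
) -> dict[str, float]:
    """Silhouette, Davies-Bouldin and Calinski-Harabasz (textbook forms,
    Euclidean).  Samples in singleton clusters contribute 0 to the mean
    silhouette.  Degenerate inputs (one cluster, or all points identical)
    raise."""
    X = emb.vectors
    y = np.array([labels[d] for d in emb.disease_ids])
    if len(set(y.tolist())) < 2:
        raise ValueError("internal metrics require at least two clusters")
    if np.allclose(X, X[0]):
        raise ValueError("all points identical: metrics are degenerate")
    return {
        "silhouette": float(silhouette_score(X, y)),
        "davies_bouldin": float(davies_bouldin_score(X, y)),
        "calinski_harabasz": float(calinski_harabasz_score(X, y)),
    }


def kneedle_select(
    xs: Sequence[float], ys: Sequence[float], sensitivity: float = 1.0
) -> int | None:
    """Knee of a decreasing convex curve (kneedle, offline).

    Min-max normalize both axes, take the difference between the chord and
    the normalized curve, and return the x at the maximal difference if it
    exceeds ``sensitivity / (n - 1)``; otherwise None (no knee — e.g. a
    perfectly linear curve).  Ties break toward the smallest x, favoring
    parsimony.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size or xs.size < 4:
        raise ValueError("need >= 4 (x, y) points")
    if np.any(np.diff(xs) <= 0):
        raise ValueError("xs must be strictly increasing")
    if np.any(np.diff(ys) > 0):
        raise ValueError("ys must be nonincreasing")
    if ys[0] == ys[-1]:
        return None
    xn = (xs - xs[0]) / (xs[-1] - xs[0])
    yn = (ys - ys[-1]) / (ys[0] - ys[-1])
    diff = (1.0 - xn) - yn  # gap below the chord
    threshold = sensitivity / (xs.size - 1)
    best = int(np.argmax(diff))  # argmax returns the first (smallest x) maximum
    if diff[best] <= threshold:
        return None
    return int(xs[best]) if float(xs[best]).is_integer() else xs[best]


def select_k(
    emb: EmbeddingMatrix,
    k_min: int = 2,
    k_max: int = 100,
    seed: int = 0,
    n_init: int = 10,
    sensitivity: float = 1.0,
) -> tuple[int | None, pd.DataFrame, dict[int, ClusterModel]]:
    """Scan K over [k_min, k_max], run kneedle on the inertia curve.

    k-means inertia can be locally non-monotone with finite ``n_init``; a
    running-minimum envelope is applied before kneedle, which requires a
    nonincreasing curve.  Returns (selected K or None, curve table, fitted
    models keyed by K).
    """
    n = len(emb.disease_ids)
    k_max = min(k_max, n)
    if k_max < k_min:
        raise ValueError("empty K range after clipping to the sample size")
    models: dict[int, ClusterModel] = {}
    ks, inertias = [], []
    for K in range(k_min, k_max + 1):
        model = kmeans_fit(emb, K, seed=seed, n_init=n_init)
        models[K] = model
        ks.append(K)
        inertias.append(model.inertia)
    envelope = np.minimum.accumulate(inertias)
    selected = (
        kneedle_select(ks, envelope, sensitivity) if len(ks) >= 4 else None
    )
    curve = pd.DataFrame({"K": ks, "inertia": inertias, "envelope": envelope})
    return selected, curve, models


def sensitivity_scan(
    kg,
    walk_grid: Sequence[WalkParams],
    embed_grid: Sequence[EmbedParams],
    k_min: int = 2,
    k_max: int = 20,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """One pipeline run per (walk params x embed params) grid cell.

    Each cell: walks -> embedding -> k-means over [k_min, k_max] -> internal
    metrics at the kneedle-selected K (silhouette-maximizing K when no knee
    is found).  Returns a tidy table, one row per cell.
    """
    rows = []
    for wp in walk_grid:
        corpus = generate_walks(kg, wp)
        for ep in embed_grid:
            emb = train_embedding(corpus, ep)
            selected, _, models = select_k(
                emb, k_min=k_min, k_max=k_max, seed=seed, n_init=n_init
            )
            if selected is None:
                scored = {
                    K: m.metrics.get("silhouette", -np.inf)
                    for K, m in models.items()
                    if m.metrics
                }
                selected = max(scored, key=scored.get)
            model = models[selected]
            rows.append(
                {
                    "walks": wp.walks_per_disease,
                    "length": wp.walk_length,
                    "window": ep.window,
                    "dimension": ep.dimension,
                    "selected_k": selected,
                    **model.metrics,
                }
            )
    return pd.DataFrame(rows)
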
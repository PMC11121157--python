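"""K-means subtyping of aggregated canonical scores, with cluster-count
diagnostics (elbow/WSS curve, silhouette, BSS/WSS ratio)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "SubtypeAssignment",
    "SubtypeKMeans",
    "kmeans_cluster",
    "wss_curve",
    "bss_wss_ratio",
    "select_k",
]


@dataclass
class SubtypeAssignment:
    """Per-sample subtype labels (1..k) plus clustering diagnostics."""

    sample_ids: list[str]
    labels: np.ndarray  # int, 1..k
    k: int
    wss: float  # total within-cluster sum of squares
    bss: float  # between-cluster sum of squares
    silhouette: float
    seed: int
    n_restarts: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subtype": self.labels}, index=self.sample_ids)


def _canonicalize_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by decreasing size, ties by first sample index."""
    uniq = np.unique(raw)
    order = sorted(
        uniq,
        key=lambda c: (-int((raw == c).sum()), int(np.flatnonzero(raw == c)[0])),
    )
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in raw], dtype=int)


class SubtypeKMeans(BaseEstimator, ClusterMixin):
    """K-means with k-means++ restarts and canonicalized labels.

    Thin wrapper over :class:`sklearn.cluster.KMeans` adding the label
    canonicalization (1..k by decreasing cluster size) and the WSS/BSS and
    silhouette diagnostics used for cluster-count selection.
    """

    def __init__(self, n_clusters: int = 2, n_restarts: int = 25, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("scores contain non-finite values")
        n = values.shape[0]
        if self.n_clusters < 2:
            raise ValueError("k must be at least 2")
        if self.n_clusters >= n:
            raise ValueError(f"k = {self.n_clusters} must be smaller than n = {n}")
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=self.n_restarts,
            random_state=self.random_state,
        )
        raw = km.fit_predict(values)
        self.labels_ = _canonicalize_labels(raw)
        self.wss_ = float(km.inertia_)
        grand = values.mean(axis=0)
        self.tss_ = float(((values - grand) ** 2).sum())
        self.bss_ = self.tss_ - self.wss_
        if len(np.unique(raw)) > 1:
            self.silhouette_ = float(silhouette_score(values, raw))
        else:  # pragma: no cover - sklearn re-seeds empty clusters itself
            self.silhouette_ = float("nan")
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def kmeans_cluster(
    scores, k: int, seed: int = 0, n_restarts: int = 25
) -> SubtypeAssignment:
    """Cluster score rows into k subtypes; best of ``n_restarts`` k-means++ runs."""
    if isinstance(scores, pd.DataFrame):
        ids = [str(s) for s in scores.index]
    else:
        ids = [str(i) for i in range(np.asarray(scores).shape[0])]
    est = SubtypeKMeans(n_clusters=k, n_restarts=n_restarts, random_state=seed).fit(
        np.asarray(scores, dtype=float)
    )
    return SubtypeAssignment(
        sample_ids=ids,
        labels=est.labels_,
        k=k,
        wss=est.wss_,
        bss=est.bss_,
        silhouette=est.silhouette_,
        seed=seed,
        n_restarts=n_restarts,
    )


def wss_curve(scores, k_range, seed: int = 0, n_restarts: int = 25):
    """Within-cluster sum of squares per k (elbow-plot input).

    WSS must be non-increasing in k; if a local-minimum violation appears,
    the offending k is re-run with more restarts.
    """
    k_range = list(k_range)
    out: list[tuple[int, float]] = []
    for k in sorted(k_range):
        assignment = kmeans_cluster(scores, k, seed=seed, n_restarts=n_restarts)
        wss = assignment.wss
        attempts = 0
        while out and wss > out[-1][1] + 1e-9 and attempts < 3:
            attempts += 1
            assignment = kmeans_cluster(
                scores, k, seed=seed + attempts, n_restarts=n_restarts * 2
            )
            wss = min(wss, assignment.wss)
        if out and wss > out[-1][1] + 1e-9:
            warnings.warn(f"WSS increased at k={k} despite restarts")
        out.append((k, wss))
    return out


def bss_wss_ratio(assignment: SubtypeAssignment) -> float:
    """Between-to-within sum-of-squares ratio of a clustering."""
    if assignment.wss <= 0:
        raise ValueError("degenerate perfect clustering (wss == 0)")
    return assignment.bss / assignment.wss


def select_k(scores, k_range, seed: int = 0, n_restarts: int = 25):
    """Pick the cluster count maximizing mean silhouette width.

    Returns ``(k_best, diagnostics)`` where the diagnostics table carries
    (k, wss, bss, silhouette, bss_wss) for every candidate so the
    elbow/silhouette/BSS-WSS criteria can also be inspected manually.
    """
    rows = []
    for k in sorted(set(k_range)):
        a = kmeans_cluster(scores, k, seed=seed, n_restarts=n_restarts)
        rows.append(
            {
                "k": k,
                "wss": a.wss,
                "bss": a.bss,
                "silhouette": a.silhouette,
                "bss_wss": a.bss / a.wss if a.wss > 0 else np.inf,
            }
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(["silhouette", "k"], ascending=[False, True]).iloc[0]
    return int(best["k"]), table
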
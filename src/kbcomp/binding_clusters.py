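"""Row z-scoring and k-means clustering of binding profiles.

Peaks are clustered on their z-scored RelA RPKM profile across the
genotype x time grid; the resulting clusters are renamed A, B, C, ... by
descending cluster-mean knockout/WT log2 fold change, which makes the
output invariant to the arbitrary label permutation of k-means
initialization.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import ValidationError


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score with population sd (ddof 0); zero-variance rows map
    to all-zeros."""
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValidationError("z-scoring needs at least 2 columns")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.repeat(sd == 0, x.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusterAssignment:
    """Feature -> cluster label, with the provenance needed to reproduce it."""

    labels: pd.Series            # feature_id -> cluster name
    k: int
    seed: int
    restarts: int
    feature_columns: list = field(default_factory=list)
    centroids: pd.DataFrame | None = None  # cluster name x feature column
    inertia: float = float("nan")

    @property
    def feature_ids(self) -> pd.Index:
        return self.labels.index

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def relabel(self, mapping: dict) -> "ClusterAssignment":
        labels = self.labels.map(mapping)
        centroids = self.centroids
        if centroids is not None:
            centroids = centroids.rename(index=mapping).sort_index()
        return ClusterAssignment(
            labels=labels, k=self.k, seed=self.seed, restarts=self.restarts,
            feature_columns=self.feature_columns, centroids=centroids,
            inertia=self.inertia,
        )


def kmeans_cluster(
    matrix: pd.DataFrame,
    k: int,
    seed: int = 0,
    restarts: int = 25,
    rank_fc: pd.Series | None = None,
) -> ClusterAssignment:
    """Euclidean k-means, best of ``restarts`` initializations, deterministic
    given ``seed``.

    If ``rank_fc`` (feature -> log2FC) is given, clusters are named
    A, B, C, ... by descending cluster-mean fold change; otherwise by
    descending cluster size.
    """
    if k > len(matrix):
        raise ValidationError(f"k={k} exceeds number of features ({len(matrix)})")
    if k < 1:
        raise ValidationError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(matrix.to_numpy(dtype=float))
    labels = pd.Series(raw, index=matrix.index)
    centroids = pd.DataFrame(km.cluster_centers_, columns=list(matrix.columns))
    if rank_fc is not None:
        missing = matrix.index.difference(rank_fc.index)
        if len(missing):
            raise ValidationError(f"rank_fc missing features: {list(missing[:5])}")
        order = (
            rank_fc.reindex(matrix.index).groupby(labels).mean().sort_values(ascending=False)
        )
    else:
        order = labels.value_counts().sort_values(ascending=False)
    names = dict(zip(order.index, string.ascii_uppercase))
    assignment = ClusterAssignment(
        labels=labels, k=k, seed=seed, restarts=restarts,
        feature_columns=list(matrix.columns),
        centroids=centroids, inertia=float(km.inertia_),
    )
    return assignment.relabel(names)


def cluster_summaries(
    assignment: ClusterAssignment, fc: pd.Series
) -> pd.DataFrame:
    """Per-cluster size and arithmetic mean log2FC (columns: cluster, n,
    mean_log2fc)."""
    missing = assignment.feature_ids.difference(fc.index)
    if len(missing):
        raise ValidationError(f"fold changes missing for features: {list(missing[:5])}")
    fc = fc.reindex(assignment.feature_ids)
    grouped = fc.groupby(assignment.labels)
    out = pd.DataFrame(
        {"n": grouped.size(), "mean_log2fc": grouped.mean()}
    ).reset_index(names="cluster")
    return out.sort_values("cluster", ignore_index=True)
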
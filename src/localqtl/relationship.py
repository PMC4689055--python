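"""Pedigree additive (numerator) relationship matrix and relatedness-based CV groups.

A is built with the tabular method: processing individuals in topological
order, A_jj = 1 + 0.5·A_{sire(j),dam(j)} and A_ij = 0.5·(A_{i,sire(j)} +
A_{i,dam(j)}), with an unknown parent contributing 0.  Cross-validation
groups are formed by K-means on the rows of A, which drives within-group
relationships up and between-group relationships down.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from .datatypes import UNKNOWN_PARENT, CVPartition, Pedigree


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix via the tabular recursion (float64, exact dyadics)."""
    n = len(pedigree)
    A = np.zeros((n, n))
    for j in range(n):
        s, d = pedigree.sire[j], pedigree.dam[j]
        if s != UNKNOWN_PARENT and d != UNKNOWN_PARENT:
            A[:j, j] = 0.5 * (A[:j, s] + A[:j, d])
            A[j, j] = 1.0 + 0.5 * A[s, d]
        elif s != UNKNOWN_PARENT or d != UNKNOWN_PARENT:
            k = s if s != UNKNOWN_PARENT else d
            A[:j, j] = 0.5 * A[:j, k]
            A[j, j] = 1.0
        else:
            A[j, j] = 1.0
        A[j, :j] = A[:j, j]
    return A


def kmeans_groups(A: np.ndarray, K: int = 6, n_restarts: int = 10, seed: int = 0) -> CVPartition:
    """Cluster individuals into K relatedness groups by K-means on the rows of A.

    Each individual's feature vector is its (unscaled) row of A, Euclidean
    distance; ``n_restarts`` random initialisations, the lowest
    within-cluster sum of squares wins.  Deterministic given ``seed``.
    """
    n = A.shape[0]
    if not (2 <= K <= n):
        raise ValueError("need 2 <= K <= n")
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(A)
    # sklearn relocates empty clusters internally; guard anyway
    if len(np.unique(labels)) != K:  # pragma: no cover
        raise RuntimeError("K-means produced an empty cluster")
    return CVPartition(labels + 1, K)


def partition_relatedness(A: np.ndarray, partition: CVPartition) -> tuple[float, float | None]:
    """(mean within-group, mean between-group) off-diagonal relationship.

    With a single group there are no between pairs and the second element is
    ``None``.
    """
    labels = partition.labels
    if len(labels) != A.shape[0]:
        raise ValueError("partition does not match A")
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    within = float(A[same & off].mean()) if (same & off).any() else 0.0
    between_mask = ~same
    between = float(A[between_mask].mean()) if between_mask.any() else None
    return within, between
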
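"""Average-linkage clustering of terms with a silhouette-chosen cut.

Terms are clustered on dissimilarity d = 1 - similarity using UPGMA
(average linkage). The dendrogram is cut at the number of clusters k that
maximizes the Average Silhouette Width, searched over k = 2 .. n-1 (for
n <= 3 the all-singletons partition is also evaluated). The UPGMA merge
order is fully deterministic: equal-distance candidate pairs are broken by
the lexicographically smallest member identifiers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """UPGMA merge history in scipy linkage-matrix layout."""

    linkage: np.ndarray  # (n-1, 4): idx_a, idx_b, height, size
    leaves: list[str]

    @property
    def n(self) -> int:
        return len(self.leaves)


@dataclass
class TermClustering:
    clusters: list[set[str]]
    k: int
    asw: float
    labels: dict[str, int]


def to_distance(matrix: SimilarityMatrix) -> np.ndarray:
    """Dissimilarity matrix d = 1 - similarity with a forced zero diagonal."""
    d = 1.0 - matrix.values
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage(dist: np.ndarray, leaves: list[str]) -> Dendrogram:
    """UPGMA with deterministic tie-breaking.

    At each step the pair of clusters with minimal mean inter-cluster
    distance merges; among equal distances the pair whose sorted member
    identifiers are lexicographically smallest wins.
    """
    n = len(leaves)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if np.isnan(dist).any():
        raise ValueError("NaN in distance matrix")

    # active cluster: scipy index -> (sorted member tuple, size)
    active: dict[int, tuple[tuple[str, ...], int]] = {
        i: ((leaves[i],), 1) for i in range(n)
    }
    d: dict[frozenset[int], float] = {
        frozenset((i, j)): float(dist[i, j])
        for i in range(n) for j in range(i + 1, n)
    }
    Z = np.zeros((n - 1, 4))
    next_idx = n
    for step in range(n - 1):
        pair = min(
            d,
            key=lambda p: (d[p],) + tuple(sorted(active[i][0] for i in sorted(p))),
        )
        i, j = sorted(pair)
        height = d[pair]
        (mi, si), (mj, sj) = active[i], active[j]
        Z[step] = [i, j, height, si + sj]
        del active[i], active[j], d[pair]
        merged = (tuple(sorted(mi + mj)), si + sj)
        for k in list(active):
            # Lance-Williams update for the unweighted average
            d_new = (si * d.pop(frozenset((i, k))) + sj * d.pop(frozenset((j, k)))) / (si + sj)
            d[frozenset((next_idx, k))] = d_new
        active[next_idx] = merged
        next_idx += 1
    return Dendrogram(linkage=Z, leaves=list(leaves))


def cut(dendro: Dendrogram, k: int) -> dict[str, int]:
    """Partition leaves into ``k`` clusters by undoing the last k-1 merges."""
    n = dendro.n
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _, _ = dendro.linkage[step]
        new = n + step
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots = sorted({find(i) for i in range(n)})
    relabel = {r: c for c, r in enumerate(roots)}
    return {leaf: relabel[find(i)] for i, leaf in enumerate(dendro.leaves)}


def cophenetic_correlation(dendro: Dendrogram, dist: np.ndarray) -> float:
    """Pearson correlation between original and cophenetic distances.

    A clustering fidelity diagnostic; NaN (with a warning) when the input
    distances are constant.
    """
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        logger.warning("constant distances: cophenetic correlation undefined")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c, _ = cophenet(dendro.linkage, condensed)
    return float(c)


def silhouette_samples(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-item silhouette s = (b - a)/max(a, b) on a precomputed matrix.

    ``a`` is the mean distance to the item's own cluster (0-convention for
    singletons), ``b`` the smallest mean distance to another cluster.
    """
    n = len(labels)
    uniq = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        if not own.any():
            continue  # singleton -> 0
        a = dist[i, own].mean()
        b = min(dist[i, labels == c].mean() for c in uniq if c != labels[i])
        m = max(a, b)
        s[i] = 0.0 if m == 0 else (b - a) / m
    return s


def silhouette_cut(dendro: Dendrogram, dist: np.ndarray) -> TermClustering:
    """Cut at the k with maximal Average Silhouette Width (ties: smallest k)."""
    n = dendro.n
    if n == 1:
        logger.warning("single term: trivial clustering, ASW undefined")
        return TermClustering(
            clusters=[set(dendro.leaves)], k=1, asw=float("nan"),
            labels={dendro.leaves[0]: 0},
        )
    ks = list(range(2, n))
    if n <= 3:
        ks = sorted(set(ks) | {n})
    best_k, best_asw, best_labels = None, -np.inf, None
    for k in ks:
        labels = cut(dendro, k)
        arr = np.array([labels[leaf] for leaf in dendro.leaves])
        asw = float(silhouette_samples(dist, arr).mean())
        if asw > best_asw:
            best_k, best_asw, best_labels = k, asw, labels
    assert best_labels is not None
    clusters: list[set[str]] = [set() for _ in range(best_k)]
    for leaf, c in best_labels.items():
        clusters[c].add(leaf)
    return TermClustering(clusters=clusters, k=best_k, asw=best_asw, labels=best_labels)
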
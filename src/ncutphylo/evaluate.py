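"""Baseline bipartitioners and the graph/cluster statistics used to compare
them: spectral bipartition, k-means and Ward adapters, NMI, transitivity,
the within-cluster squared-distance (k-means) criterion, and the mean
standardized bit score of a similarity matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import eigh
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score

from .ncut import DegenerateGraphError, ncut_value
from .records import InputError
from .similarity import SimilarityMatrix

__all__ = [
    "ClusteringComparison",
    "spectral_bipartition",
    "kmeans_bipartition",
    "ward_bipartition",
    "nmi",
    "transitivity",
    "kmeans_criterion",
    "mean_standardized_bitscore",
]


@dataclass(frozen=True)
class ClusteringComparison:
    """One method's bipartition with its quality scores."""

    method: str
    labels: np.ndarray
    ncut: float
    kmeans_criterion: float
    nmi_vs_reference: float


def _values(matrix: SimilarityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, SimilarityMatrix):
        return matrix.values.astype(float)
    return np.asarray(matrix, dtype=float)


def spectral_bipartition(
    matrix: SimilarityMatrix | np.ndarray, seed: int = 0
) -> np.ndarray:
    """Two-way spectral cut of the similarity (affinity) graph.

    Embeds the nodes with the Fiedler vector of the symmetric normalized
    Laplacian and thresholds it; of the sign split and the median split, the
    one with the lower Ncut is returned. Deterministic. On a disconnected
    graph the smallest component is split off (with a warning) since any
    cross-component cut already has Ncut contribution 0.
    """
    d = _values(matrix).copy()
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    if n < 2:
        raise InputError("need at least 2 nodes")
    if not d.any():
        raise DegenerateGraphError("all-zero similarity matrix")
    g = nx.from_numpy_array(d)
    g.remove_edges_from([(u, v) for u, v, w in g.edges(data="weight") if w == 0])
    if not nx.is_connected(g):
        warnings.warn("similarity graph is disconnected; splitting a component")
        comp = min(nx.connected_components(g), key=lambda s: (len(s), sorted(s)))
        labels = np.zeros(n, dtype=np.int8)
        labels[sorted(comp)] = 1
        return labels
    deg = d.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - d_isqrt[:, None] * d * d_isqrt[None, :]
    _, vecs = eigh(lap, subset_by_index=[0, 1])
    fiedler = d_isqrt * vecs[:, 1]
    candidates = []
    for threshold in (0.0, float(np.median(fiedler))):
        labels = (fiedler > threshold).astype(np.int8)
        if 0 < labels.sum() < n:
            candidates.append((ncut_value(labels, d), tuple(labels), labels))
    if not candidates:
        # perfectly symmetric embedding: fall back to a median split by rank
        order = np.argsort(fiedler, kind="stable")
        labels = np.zeros(n, dtype=np.int8)
        labels[order[: n // 2]] = 1
        candidates.append((ncut_value(labels, d), tuple(labels), labels))
    candidates.sort(key=lambda t: (t[0], t[1]))
    return candidates[0][2]


def kmeans_bipartition(
    matrix: SimilarityMatrix | np.ndarray, seed: int = 0, n_init: int = 100
) -> np.ndarray:
    """k-means (k=2, 100 restarts) on the rows of the similarity matrix."""
    v = _values(matrix)
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    return km.fit_predict(v).astype(np.int8)


def ward_bipartition(matrix: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Ward hierarchical clustering cut at two groups, on distances
    100 - similarity."""
    v = _values(matrix)
    dist = 100.0 - v
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    return (fcluster(z, t=2, criterion="maxclust") - 1).astype(np.int8)


def nmi(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise InputError("clusterings must have equal length")
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def transitivity(matrix: SimilarityMatrix | np.ndarray) -> float:
    """Fraction of connected triples that are closed, on the graph whose
    edges are the strictly positive off-diagonal similarities."""
    v = _values(matrix).copy()
    np.fill_diagonal(v, 0.0)
    n = v.shape[0]
    if n < 3:
        raise InputError("transitivity needs at least 3 nodes")
    g = nx.from_numpy_array((v > 0).astype(int))
    g.remove_edges_from([(u, w) for u, w, x in g.edges(data="weight") if x == 0])
    return float(nx.transitivity(g))


def kmeans_criterion(
    labels: Sequence[int], matrix: SimilarityMatrix | np.ndarray
) -> float:
    """Sum of squared pairwise distances (100 - similarity) within clusters."""
    v = _values(matrix)
    x = np.asarray(labels)
    if x.shape[0] != v.shape[0]:
        raise InputError("labels length does not match matrix")
    total = 0.0
    for value in np.unique(x):
        idx = np.flatnonzero(x == value)
        sub = 100.0 - v[np.ix_(idx, idx)]
        np.fill_diagonal(sub, 0.0)
        total += float((sub**2).sum()) / 2.0
    return total


def mean_standardized_bitscore(matrix: SimilarityMatrix | np.ndarray) -> float:
    """Mean of the off-diagonal entries of the similarity matrix."""
    v = _values(matrix)
    n = v.shape[0]
    if n < 2:
        raise InputError("need at least 2 sequences")
    return float((v.sum() - np.trace(v)) / (n * (n - 1)))
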
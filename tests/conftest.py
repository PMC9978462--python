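"""Shared fixtures: small graphs with known optimal cuts, and generators for
random and planted-structure similarity matrices."""

from __future__ import annotations

import numpy as np
import pytest

from ncutphylo import ncut_value


def random_symmetric_int_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Dense symmetric integer matrix, entries 0..100, zero diagonal."""
    d = rng.integers(0, 101, size=(n, n)).astype(float)
    d = np.floor((d + d.T) / 2)
    np.fill_diagonal(d, 0.0)
    return d


def planted_two_group_matrix(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Similarity-like matrix with two planted groups: high within, low
    between. Returns (matrix, planted binary labels)."""
    k = int(rng.integers(2, n - 1))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < k) == (j < k)
            v = rng.integers(60, 101) if same else rng.integers(0, 41)
            d[i, j] = d[j, i] = float(v)
    labels = (np.arange(n) < k).astype(np.int8)
    return d, labels


def brute_force_min_ncut(d: np.ndarray) -> tuple[float, np.ndarray]:
    """Independent oracle: global Ncut minimum over all nontrivial
    bipartitions, by full enumeration."""
    n = d.shape[0]
    best_v, best_x = np.inf, None
    for m in range(1, 2**n - 1):
        x = np.array([(m >> (n - 1 - i)) & 1 for i in range(n)])
        v = ncut_value(x, d)
        if v < best_v:
            best_v, best_x = v, x
    return best_v, best_x


def brute_force_min_cut_at_c(d: np.ndarray, c: int) -> float:
    """Independent oracle: minimum cut weight over bipartitions with exactly
    c nodes on side 1."""
    from itertools import combinations

    n = d.shape[0]
    best = np.inf
    for members in combinations(range(n), c):
        x = np.zeros(n)
        x[list(members)] = 1
        cross = x[:, None] != x[None, :]
        best = min(best, float((d * cross).sum() / 2))
    return best


@pytest.fixture
def k4() -> np.ndarray:
    """Complete graph on 4 nodes, unit weights."""
    d = np.ones((4, 4))
    np.fill_diagonal(d, 0.0)
    return d


@pytest.fixture
def bridged_cliques() -> tuple[np.ndarray, int]:
    """Two 4-cliques (intra weight 100) joined by a single weight-1 bridge.
    Returns (matrix, clique size)."""
    d = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    d[i, j] = 100.0
    d[3, 4] = d[4, 3] = 1.0
    return d, 4


@pytest.fixture
def weak_node_graph() -> tuple[np.ndarray, np.ndarray]:
    """Two planted groups of 5 where node 0 is weakly attached: the
    unconstrained minimum cut isolates node 0, but the best normalized cut is
    the group split. Returns (matrix, planted group labels)."""
    n = 10
    d = np.zeros((n, n))
    group = (np.arange(n) < 5).astype(np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            if group[i] == group[j]:
                v = 40.0 if 0 in (i, j) else 90.0
            else:
                v = 2.0 if 0 in (i, j) else 15.0
            d[i, j] = d[j, i] = v
    return d, group
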
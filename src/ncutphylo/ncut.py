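"""Normalized-cut scoring and selection of the best bipartition.

A plain minimum cut favours slicing off single weakly-connected nodes,
which is useless for building a tree. The normalized cut

    Ncut(A, B) = cut(A, B) / assoc(A, V) + cut(A, B) / assoc(B, V)

divides the cut weight by each side's total association with the whole
graph, so lopsided cuts are penalised. Ncut is not itself expressible as a
QUBO; instead the constrained minimum cut is solved once for every
admissible side-1 size c = 1 .. floor(n/2), each solution is scored by
Ncut, and the smallest wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .qubo import (
    ConvergenceError,
    CutSolution,
    QuboProblem,
    SolverConfig,
    _as_offdiag,
    mincut_energy,
    solve_with_alpha_adaptation,
)
from .records import InputError
from .similarity import SimilarityMatrix

__all__ = [
    "NcutResult",
    "DegenerateGraphError",
    "assoc",
    "ncut_value",
    "sweep_and_select",
    "min_cut_bipartition",
]


class DegenerateGraphError(RuntimeError):
    """A side of the cut has zero association — Ncut is undefined."""


@dataclass(frozen=True)
class NcutResult:
    """A bipartition (side A = label 1, side B = label 0) scored by Ncut.

    ``sweep_table`` records one row per candidate cut size:
    (c, mincut, alpha_used, ncut).
    """

    labels: np.ndarray
    cut_value: float
    assoc_a: float
    assoc_b: float
    ncut: float
    c: int
    sweep_table: tuple[tuple[int, float, int, float], ...] = field(
        default=(), repr=False
    )

    @property
    def side_a(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    @property
    def side_b(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)


def assoc(
    group: Sequence[int],
    d: np.ndarray,
    include_diagonal: bool = False,
) -> float:
    """Total similarity from nodes of ``group`` to every node of the graph.

    Self-similarity terms d_uu are excluded by default: the graph is a
    pairwise-similarity graph and a constant self-edge on every node would
    merely inflate both denominators of Ncut uniformly.
    """
    d = np.asarray(d, dtype=float)
    idx = np.asarray(group, dtype=int)
    if idx.size == 0:
        raise InputError("assoc of an empty group is undefined")
    total = float(d[idx, :].sum())
    if not include_diagonal:
        total -= float(np.diag(d)[idx].sum())
    return total


def ncut_value(
    labels: Sequence[int],
    d: np.ndarray,
    include_diagonal: bool = False,
) -> float:
    """Ncut of the bipartition given by binary ``labels``; swap-invariant."""
    x = np.asarray(labels)
    a = np.flatnonzero(x == 1)
    b = np.flatnonzero(x == 0)
    if a.size == 0 or b.size == 0:
        raise InputError("both sides of the cut must be non-empty")
    d_off = _as_offdiag(d)
    cut = mincut_energy(x, d_off)
    da = assoc(a, d, include_diagonal)
    db = assoc(b, d, include_diagonal)
    if da <= 0 or db <= 0:
        raise DegenerateGraphError(
            "a side of the cut has zero total association; Ncut undefined"
        )
    return cut / da + cut / db


def sweep_and_select(
    matrix: SimilarityMatrix | np.ndarray,
    cfg: SolverConfig | None = None,
    include_diagonal: bool = False,
) -> NcutResult:
    """Solve the constrained min-cut for every c in 1..floor(n/2) and return
    the bipartition with the smallest Ncut.

    Ties are broken toward smaller c (first seen wins; within one c the
    solver's lexicographic tie-break applies). Solver convergence failures
    are re-raised tagged with the failing c.
    """
    cfg = cfg or SolverConfig()
    if isinstance(matrix, SimilarityMatrix):
        d_full = matrix.values.astype(float)
    else:
        d_full = np.asarray(matrix, dtype=float)
    n = d_full.shape[0]
    if n < 2:
        raise InputError("need at least 2 nodes to cut")
    best: NcutResult | None = None
    rows: list[tuple[int, float, int, float]] = []
    for c in range(1, n // 2 + 1):
        problem = QuboProblem(d=d_full, c=c, alpha=cfg.alpha_init)
        try:
            sol: CutSolution = solve_with_alpha_adaptation(problem, cfg)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"solver did not converge at cut size c={c}: {err}",
                last_alpha=err.last_alpha,
            ) from err
        value = ncut_value(sol.labels, d_full, include_diagonal)
        rows.append((c, sol.mincut_energy, sol.alpha_used, value))
        if best is None or value < best.ncut:
            a = np.flatnonzero(sol.labels == 1)
            b = np.flatnonzero(sol.labels == 0)
            best = NcutResult(
                labels=sol.labels.copy(),
                cut_value=sol.mincut_energy,
                assoc_a=assoc(a, d_full, include_diagonal),
                assoc_b=assoc(b, d_full, include_diagonal),
                ncut=value,
                c=c,
            )
    assert best is not None
    return NcutResult(
        labels=best.labels,
        cut_value=best.cut_value,
        assoc_a=best.assoc_a,
        assoc_b=best.assoc_b,
        ncut=best.ncut,
        c=best.c,
        sweep_table=tuple(rows),
    )


def min_cut_bipartition(matrix: SimilarityMatrix | np.ndarray) -> tuple[np.ndarray, float]:
    """Unconstrained global minimum cut (the criterion Ncut replaces).

    Returns (binary labels, cut weight). Uses the Stoer–Wagner algorithm on
    connected graphs; on a disconnected graph the cut is 0, separating one
    connected component. Kept as the baseline that demonstrates why the
    normalization is needed: its optimum routinely isolates one node.
    """
    if isinstance(matrix, SimilarityMatrix):
        d = matrix.offdiagonal()
    else:
        d = _as_offdiag(np.asarray(matrix, dtype=float))
    n = d.shape[0]
    if n < 2:
        raise InputError("need at least 2 nodes to cut")
    g = nx.from_numpy_array(d)
    zero = [(u, v) for u, v, w in g.edges(data="weight") if w == 0]
    g.remove_edges_from(zero)
    labels = np.zeros(n, dtype=np.int8)
    if not nx.is_connected(g):
        comp = min(nx.connected_components(g), key=lambda s: (len(s), sorted(s)))
        labels[sorted(comp)] = 1
        return labels, 0.0
    cut_value, (side_a, _) = nx.stoer_wagner(g, weight="weight")
    labels[sorted(side_a)] = 1
    if labels[0] == 1:  # canonical orientation: node 0 on side 0
        labels = 1 - labels
    return labels, float(cut_value)
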
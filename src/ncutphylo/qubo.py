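"""Cardinality-constrained minimum cut as a QUBO, with interchangeable solvers.

The bipartition of a similarity graph is encoded in binary labels
``x_i in {0, 1}``. The objective is

    E(x) = sum_{i<j} d_ij (x_i - x_j)^2  +  alpha * (sum_i x_i - c)^2

whose first term is the weight of the cut and whose second term is a penalty
forcing exactly ``c`` nodes onto side 1. The penalty weight ``alpha`` starts
small and is escalated (alpha += 500) whenever the best solution found still
violates the cardinality constraint — mirroring how the objective is run on
annealing hardware, where the constraint cannot be imposed structurally.

Two backends satisfy the solver contract:

* ``exhaustive`` — enumerates all 2^n labelings (n capped, default 20) and
  returns the true optimum, ties broken by lexicographically smallest label
  vector.
* ``simulated_annealing`` — single-bit-flip Metropolis chains with geometric
  cooling, run as several independent replicas with seeds derived from one
  master seed; optional parallel-tempering exchange between replicas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .records import InputError

__all__ = [
    "QuboProblem",
    "CutSolution",
    "SolverConfig",
    "ConvergenceError",
    "mincut_energy",
    "penalty_energy",
    "solve_fixed_c",
    "solve_with_alpha_adaptation",
]

EXHAUSTIVE_LIMIT = 20


class ConvergenceError(RuntimeError):
    """Penalty could not be driven to zero within the alpha-escalation budget."""

    def __init__(self, message: str, last_alpha: int):
        super().__init__(message)
        self.last_alpha = last_alpha


def _as_offdiag(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("similarity matrix must be square")
    if not np.allclose(d, d.T):
        raise InputError("similarity matrix must be symmetric")
    if (d < 0).any():
        raise InputError("similarity values must be non-negative")
    d = d.copy()
    np.fill_diagonal(d, 0.0)  # diagonal never contributes to (x_i - x_j)^2
    return d


@dataclass(frozen=True)
class QuboProblem:
    """One constrained min-cut instance: weights ``d``, target size ``c``,
    penalty weight ``alpha``."""

    d: np.ndarray
    c: int
    alpha: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", _as_offdiag(self.d))
        n = self.d.shape[0]
        if not (1 <= self.c <= n // 2):
            raise InputError(f"c={self.c} outside the sweep range 1..{n // 2}")
        if self.alpha < 1:
            raise InputError("alpha must be >= 1")

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def energy(self, labels: Sequence[int]) -> float:
        return mincut_energy(labels, self.d) + penalty_energy(
            labels, self.c, self.alpha
        )


@dataclass(frozen=True)
class CutSolution:
    """A binary labeling with its cut and penalty energies."""

    labels: np.ndarray
    mincut_energy: float
    penalty_energy: float
    alpha_used: int
    replica_count: int
    seed: int | None = None
    replica_energies: tuple[float, ...] = field(default=(), repr=False)

    @property
    def total_energy(self) -> float:
        return self.mincut_energy + self.penalty_energy

    @property
    def ones_count(self) -> int:
        return int(np.sum(self.labels))


@dataclass(frozen=True)
class SolverConfig:
    """Backend selection and annealing schedule.

    ``replicas`` independent chains are run (12 by default, matching the
    convergence-verification protocol of running twelve parallel searches);
    the best labeling over all chains is returned. ``t_initial=None`` means
    "estimate the hot temperature as the largest |dE| seen over random
    single-bit flips".
    """

    backend: Literal["exhaustive", "simulated_annealing"] = "exhaustive"
    replicas: int = 12
    sweeps: int = 10_000
    t_initial: float | None = None
    t_final: float = 0.01
    seed: int = 0
    alpha_init: int = 100
    alpha_step: int = 500
    alpha_max_retries: int = 20
    replica_exchange: bool = False
    exhaustive_limit: int = EXHAUSTIVE_LIMIT

    def __post_init__(self) -> None:
        if self.replicas < 1:
            raise InputError("replicas must be >= 1")
        if self.t_final <= 0 or (self.t_initial is not None and self.t_initial <= 0):
            raise InputError("temperatures must be positive")
        if self.t_initial is not None and self.t_initial < self.t_final:
            raise InputError("initial temperature must be >= final temperature")


def mincut_energy(labels: Sequence[int], d: np.ndarray) -> float:
    """Cut weight: sum of d_ij over pairs split by the labeling.

    Invariant under complementing all labels.
    """
    d = _as_offdiag(d)
    x = np.asarray(labels)
    if x.shape != (d.shape[0],):
        raise InputError(
            f"labels length {x.shape} does not match matrix size {d.shape[0]}"
        )
    if not np.isin(x, (0, 1)).all():
        raise InputError("labels must be binary")
    cross = x[:, None] != x[None, :]
    return float((d * cross).sum() / 2.0)


def penalty_energy(labels: Sequence[int], c: int, alpha: int) -> float:
    """alpha * (number of 1-labels - c)^2 — zero iff exactly c nodes are on side 1."""
    if c < 1:
        raise InputError("c must be >= 1")
    x = np.asarray(labels)
    if not np.isin(x, (0, 1)).all():
        raise InputError("labels must be binary")
    return float(alpha) * float(int(x.sum()) - c) ** 2


# ---------------------------------------------------------------------------
# exhaustive backend

def _enumerate_bits(n: int, start: int, stop: int) -> np.ndarray:
    """Rows ``start..stop`` of the lexicographic enumeration of {0,1}^n
    (x_0 is the most significant bit, so row order == lexicographic order)."""
    idx = np.arange(start, stop, dtype=np.uint64)
    shifts = np.arange(n - 1, -1, -1, dtype=np.uint64)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def _solve_exhaustive(problem: QuboProblem, cfg: SolverConfig) -> CutSolution:
    n = problem.n
    if n > cfg.exhaustive_limit:
        raise InputError(
            f"exhaustive backend refuses n={n} > limit {cfg.exhaustive_limit}"
        )
    # cut(x) = x^T L x for binary x, with L the graph Laplacian of d
    lap = np.diag(problem.d.sum(axis=1)) - problem.d
    best_energy = np.inf
    best_cut = best_pen = 0.0
    best_labels: np.ndarray | None = None
    total = 1 << n
    chunk = min(total, 1 << 16)
    for start in range(0, total, chunk):
        x = _enumerate_bits(n, start, min(start + chunk, total)).astype(float)
        cut = np.einsum("ki,ij,kj->k", x, lap, x)
        ones = x.sum(axis=1)
        pen = problem.alpha * (ones - problem.c) ** 2
        energy = cut + pen
        k = int(np.argmin(energy))  # first occurrence == lexicographic tie-break
        if energy[k] < best_energy:
            best_energy = float(energy[k])
            best_cut, best_pen = float(cut[k]), float(pen[k])
            best_labels = x[k].astype(np.int8)
    assert best_labels is not None
    return CutSolution(
        labels=best_labels,
        mincut_energy=best_cut,
        penalty_energy=best_pen,
        alpha_used=problem.alpha,
        replica_count=1,
        seed=None,
    )


# ---------------------------------------------------------------------------
# simulated-annealing backend

def _estimate_t0(problem: QuboProblem, rng: np.random.Generator) -> float:
    """Hot temperature: max |dE| over random states and random single flips."""
    n = problem.n
    deg = problem.d.sum(axis=1)
    max_de = 0.0
    for _ in range(64):
        x = rng.integers(0, 2, size=n)
        i = int(rng.integers(n))
        s = float(problem.d[i] @ x)
        sign = 1 - 2 * int(x[i])
        de_cut = sign * (deg[i] - 2 * s)
        m = int(x.sum())
        de_pen = problem.alpha * (2 * (m - problem.c) * sign + 1)
        max_de = max(max_de, abs(de_cut + de_pen))
    return max(max_de, 1.0)


def _solve_sa(problem: QuboProblem, cfg: SolverConfig) -> CutSolution:
    n, d, alpha, c = problem.n, problem.d, problem.alpha, problem.c
    reps = cfg.replicas
    master = np.random.SeedSequence(cfg.seed)
    child_seqs = master.spawn(reps + 1)
    t0_rng = np.random.default_rng(child_seqs[-1])
    t0 = cfg.t_initial if cfg.t_initial is not None else _estimate_t0(problem, t0_rng)
    sweeps = cfg.sweeps
    steps = sweeps * n
    # temperature ladder only matters when replica exchange is on
    ladder = (
        np.geomspace(1.0, 3.0, reps) if cfg.replica_exchange and reps > 1 else np.ones(reps)
    )
    temp_per_sweep = np.geomspace(t0, cfg.t_final, sweeps)

    # per-replica random streams, pre-drawn so each chain is reproducible on its own
    rngs = [np.random.default_rng(s) for s in child_seqs[:reps]]
    sites = np.stack([r.integers(0, n, size=steps) for r in rngs], axis=1)
    unifs = np.stack([r.random(size=steps) for r in rngs], axis=1)
    init = np.stack([r.integers(0, 2, size=n) for r in rngs], axis=0).astype(np.int8)
    swap_unifs = [r.random(size=sweeps) for r in rngs[: max(reps - 1, 0)]]

    X = init.copy()
    deg = d.sum(axis=1)
    cross = (X[:, None, :] != X[:, :, None]).astype(float)
    cur_e = (d[None, :, :] * cross).sum(axis=(1, 2)) / 2.0
    m = X.sum(axis=1).astype(float)
    cur_e = cur_e + alpha * (m - c) ** 2
    best_e = cur_e.copy()
    best_X = X.copy()
    rep_idx = np.arange(reps)

    step = 0
    for sweep in range(sweeps):
        t = temp_per_sweep[sweep] * ladder
        for _ in range(n):
            site = sites[step]
            u = unifs[step]
            step += 1
            xi = X[rep_idx, site].astype(float)
            sign = 1.0 - 2.0 * xi
            s = (d[site] * X).sum(axis=1)
            de = sign * (deg[site] - 2.0 * s) + alpha * (2.0 * (m - c) * sign + 1.0)
            accept = (de <= 0) | (u < np.exp(-np.clip(de, 0, 700) / t))
            flip = rep_idx[accept]
            X[flip, site[accept]] ^= 1
            m[accept] += sign[accept]
            cur_e[accept] += de[accept]
            improved = cur_e < best_e
            if improved.any():
                best_e[improved] = cur_e[improved]
                best_X[improved] = X[improved]
        if cfg.replica_exchange and reps > 1:
            # adjacent-pair parallel tempering swap on the current ladder
            for r in range(reps - 1):
                beta_lo, beta_hi = 1.0 / t[r], 1.0 / t[r + 1]
                arg = (beta_lo - beta_hi) * (cur_e[r] - cur_e[r + 1])
                if arg >= 0 or swap_unifs[r][sweep] < np.exp(arg):
                    X[[r, r + 1]] = X[[r + 1, r]]
                    cur_e[[r, r + 1]] = cur_e[[r + 1, r]]
                    m[[r, r + 1]] = m[[r + 1, r]]

    # pick the best replica; break energy ties by lexicographic labels
    order = sorted(range(reps), key=lambda r: (best_e[r], tuple(best_X[r])))
    win = order[0]
    labels = best_X[win].astype(np.int8)
    cut = mincut_energy(labels, d)
    pen = penalty_energy(labels, c, alpha)
    return CutSolution(
        labels=labels,
        mincut_energy=cut,
        penalty_energy=pen,
        alpha_used=alpha,
        replica_count=reps,
        seed=cfg.seed,
        replica_energies=tuple(float(e) for e in best_e),
    )


def solve_fixed_c(problem: QuboProblem, cfg: SolverConfig) -> CutSolution:
    """Minimize the QUBO objective at fixed ``c`` and ``alpha``."""
    if cfg.backend == "exhaustive":
        return _solve_exhaustive(problem, cfg)
    if cfg.backend == "simulated_annealing":
        return _solve_sa(problem, cfg)
    raise InputError(f"unknown backend {cfg.backend!r}")


def solve_with_alpha_adaptation(
    problem: QuboProblem, cfg: SolverConfig
) -> CutSolution:
    """Escalate ``alpha`` by ``alpha_step`` until the penalty term vanishes.

    The accepted solution has exactly ``c`` nodes labeled 1; ``alpha_used``
    records the successful penalty weight.
    """
    for k in range(cfg.alpha_max_retries + 1):
        alpha = cfg.alpha_init + k * cfg.alpha_step
        sol = solve_fixed_c(replace(problem, alpha=alpha), cfg)
        if sol.penalty_energy == 0:
            return sol
    raise ConvergenceError(
        f"penalty energy never reached zero for c={problem.c} "
        f"(last alpha tried: {alpha})",
        last_alpha=alpha,
    )
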
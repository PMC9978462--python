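"""Energies, exhaustive and annealing solvers, and the alpha-escalation loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncutphylo import (
    ConvergenceError,
    InputError,
    QuboProblem,
    SolverConfig,
    mincut_energy,
    penalty_energy,
    solve_fixed_c,
    solve_with_alpha_adaptation,
)
from .conftest import random_symmetric_int_matrix


def brute_force_cut(labels, d):
    """Independent double-loop oracle for the cut weight."""
    total = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            total += d[i, j] * (labels[i] - labels[j]) ** 2
    return total


def test_uniform_labels_cut_nothing(k4):
    assert mincut_energy([0, 0, 0, 0], k4) == 0.0
    assert mincut_energy([1, 1, 1, 1], k4) == 0.0


def test_single_edge_cut():
    d = np.array([[0.0, 7.0], [7.0, 0.0]])
    assert mincut_energy([0, 1], d) == 7.0


def test_cut_matches_double_loop_oracle():
    rng = np.random.default_rng(11)
    for _ in range(10):
        d = random_symmetric_int_matrix(6, rng)
        labels = rng.integers(0, 2, size=6)
        assert mincut_energy(labels, d) == brute_force_cut(labels, d)


@pytest.mark.parametrize(
    "labels, c, alpha, expected",
    [
        ([1, 1, 1, 1, 1, 0], 5, 100, 0),  # count equals c
        ([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], 5, 100, 400),  # (3-5)^2 * 100
        ([0, 0, 0], 1, 100, 100),  # (0-1)^2 * 100
    ],
)
def test_penalty_energy(labels, c, alpha, expected):
    assert penalty_energy(labels, c, alpha) == expected


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_energy_decomposition_and_complement_symmetry(seed):
    """Eq-style identity: total objective = cut + penalty for any labeling;
    the cut is complement-invariant, the penalty generally is not."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    d = random_symmetric_int_matrix(n, rng)
    c = int(rng.integers(1, n // 2 + 1))
    problem = QuboProblem(d=d, c=c, alpha=int(rng.integers(1, 500)))
    x = rng.integers(0, 2, size=n)
    assert problem.energy(x) == mincut_energy(x, d) + penalty_energy(
        x, c, problem.alpha
    )
    assert mincut_energy(1 - x, d) == mincut_energy(x, d)
    if 2 * c != n and x.sum() == c:
        assert penalty_energy(1 - x, c, problem.alpha) > 0


def test_exhaustive_k4_balanced_split(k4):
    sol = solve_fixed_c(QuboProblem(d=k4, c=2, alpha=100), SolverConfig())
    assert sol.mincut_energy == 4.0
    assert sol.penalty_energy == 0.0
    assert sol.labels.sum() == 2


def test_exhaustive_two_cliques_cut_the_bridge():
    d = np.zeros((6, 6))
    for block in (range(3), range(3, 6)):
        for i in block:
            for j in block:
                if i != j:
                    d[i, j] = 100.0
    d[2, 3] = d[3, 2] = 1.0
    sol = solve_fixed_c(QuboProblem(d=d, c=3, alpha=100), SolverConfig())
    assert sol.mincut_energy == 1.0
    assert set(np.flatnonzero(sol.labels == sol.labels[0])) == {0, 1, 2}


def test_exhaustive_refuses_large_n():
    rng = np.random.default_rng(0)
    d = random_symmetric_int_matrix(8, rng)
    cfg = SolverConfig(exhaustive_limit=6)
    with pytest.raises(InputError):
        solve_fixed_c(QuboProblem(d=d, c=2, alpha=100), cfg)


def test_sa_matches_exhaustive_optimum():
    """Core solver test: annealing attains the enumerated optimum on
    20 random instances, n in 6..12."""
    rng = np.random.default_rng(20)
    for trial in range(20):
        n = int(rng.integers(6, 13))
        d = random_symmetric_int_matrix(n, rng)
        c = int(rng.integers(1, n // 2 + 1))
        problem = QuboProblem(d=d, c=c, alpha=600)
        exact = solve_fixed_c(problem, SolverConfig())
        sa = solve_fixed_c(
            problem,
            SolverConfig(backend="simulated_annealing", sweeps=500, seed=trial),
        )
        assert sa.total_energy == exact.total_energy


def test_sa_is_reproducible():
    rng = np.random.default_rng(3)
    d = random_symmetric_int_matrix(10, rng)
    problem = QuboProblem(d=d, c=4, alpha=300)
    cfg = SolverConfig(backend="simulated_annealing", sweeps=200, seed=99)
    a = solve_fixed_c(problem, cfg)
    b = solve_fixed_c(problem, cfg)
    assert np.array_equal(a.labels, b.labels)
    assert a.total_energy == b.total_energy
    assert a.replica_energies == b.replica_energies


def test_sa_with_replica_exchange_still_finds_optimum():
    rng = np.random.default_rng(8)
    d = random_symmetric_int_matrix(9, rng)
    problem = QuboProblem(d=d, c=3, alpha=600)
    exact = solve_fixed_c(problem, SolverConfig())
    sa = solve_fixed_c(
        problem,
        SolverConfig(
            backend="simulated_annealing", sweeps=500, seed=5, replica_exchange=True
        ),
    )
    assert sa.total_energy == exact.total_energy


def test_alpha_adaptation_accepts_initial_alpha_when_feasible(k4):
    sol = solve_with_alpha_adaptation(QuboProblem(d=k4, c=2), SolverConfig())
    assert sol.alpha_used == 100
    assert sol.penalty_energy == 0.0
    assert sol.ones_count == 2


def test_alpha_escalates_when_constraint_violation_pays():
    # single edge of weight 300: at alpha=100 the solver prefers to leave
    # both nodes on one side (penalty 100 < cut 300); one escalation fixes it
    d = np.array([[0.0, 300.0], [300.0, 0.0]])
    sol = solve_with_alpha_adaptation(QuboProblem(d=d, c=1), SolverConfig())
    assert sol.alpha_used == 600
    assert sol.penalty_energy == 0.0
    assert sol.ones_count == 1


def test_alpha_adaptation_convergence_error_on_overwhelming_edge():
    # a 10^6 edge exceeds the whole escalation budget (100 + 20*500)
    d = np.array([[0.0, 1e6], [1e6, 0.0]])
    with pytest.raises(ConvergenceError) as err:
        solve_with_alpha_adaptation(QuboProblem(d=d, c=1), SolverConfig())
    assert err.value.last_alpha == 100 + 20 * 500


def test_accepted_solutions_always_have_exactly_c_ones():
    rng = np.random.default_rng(17)
    for _ in range(5):
        n = int(rng.integers(5, 10))
        d = random_symmetric_int_matrix(n, rng)
        c = int(rng.integers(1, n // 2 + 1))
        sol = solve_with_alpha_adaptation(QuboProblem(d=d, c=c), SolverConfig())
        assert sol.ones_count == c
        assert sol.penalty_energy == 0.0
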
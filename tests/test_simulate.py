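"""Tree simulation, sequence evolution, indel statistics, and p-distance."""

import math

import dendropy
import numpy as np
import pytest
from scipy import stats

from ncutphylo import (
    ComputationError,
    SeqEvolConfig,
    SimTreeConfig,
    evolve_sequences,
    p_distance,
    power_law_mle,
    sample_indel_lengths,
    simulate_tree,
    true_p_distance,
    true_p_distance_matrix,
)
from ncutphylo.simulate import draw_branch_lengths
from ncutphylo.wag import discrete_gamma_rates, poisson_model, wag_model


def star_tree(n_leaves: int, branch_length: float) -> dendropy.Tree:
    labels = [f"t{i+1}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    for label in labels:
        leaf = dendropy.Node()
        leaf.taxon = tns.get_taxon(label)
        leaf.edge.length = branch_length
        tree.seed_node.add_child(leaf)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# trees


@pytest.mark.parametrize("shape", ["uniform_random", "yule"])
def test_simulated_tree_shape_and_branch_count(shape):
    tree = simulate_tree(SimTreeConfig(n_taxa=32, shape=shape, seed=1))
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    assert sorted(leaves) == sorted(f"t{i+1}" for i in range(32))
    edges = [
        e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    ]
    assert len(edges) == 2 * 32 - 2
    assert all(e.length > 0 for e in edges)


def test_branch_lengths_rescaled_to_exact_mean():
    for mean in (0.125, 0.5):
        tree = simulate_tree(
            SimTreeConfig(n_taxa=16, mean_branch_length=mean, seed=3)
        )
        lengths = [
            e.length
            for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
        ]
        assert np.mean(lengths) == pytest.approx(mean, rel=1e-12)


def test_normal_branch_draws_match_truncated_normal_expectation():
    """Negatives are resampled, so raw draws follow a left-truncated normal;
    the oracle expectation is mu + sigma*phi(a)/(1-Phi(a)), a = -mu/sigma."""
    mean = 0.5
    sigma = math.sqrt(mean / 2)
    a = -mean / sigma
    expected = mean + sigma * stats.norm.pdf(a) / (1 - stats.norm.cdf(a))
    rng = np.random.default_rng(21)
    draws = np.concatenate(
        [draw_branch_lengths(30, mean, "normal", rng) for _ in range(200)]
    )
    se = draws.std(ddof=1) / math.sqrt(draws.size)
    assert abs(draws.mean() - expected) < 3 * se
    assert draws.min() > 0


def test_exponential_branch_draws_have_unit_cv():
    rng = np.random.default_rng(22)
    draws = draw_branch_lengths(20_000, 0.25, "exponential", rng)
    cv2 = draws.var(ddof=1) / draws.mean() ** 2
    assert cv2 == pytest.approx(1.0, abs=0.05)


def test_tree_simulation_deterministic():
    a = simulate_tree(SimTreeConfig(n_taxa=10, seed=5))
    b = simulate_tree(SimTreeConfig(n_taxa=10, seed=5))
    assert a.as_string(schema="newick") == b.as_string(schema="newick")


# ---------------------------------------------------------------------------
# sequence evolution


def test_zero_branches_give_identical_sequences():
    tree = star_tree(6, 0.0)
    res = evolve_sequences(tree, SeqEvolConfig(root_length=200, seed=1))
    seqs = {r.residues for r in res.records}
    assert len(seqs) == 1
    ids, mat = true_p_distance_matrix(res)
    assert mat.max() == 0.0


def test_small_branch_p_distance_linearization():
    """On a star tree with tiny branches, E[p] ~ 2*t*(1 - p_inv) to first
    order in t (substitutions are rare and almost never reverted)."""
    t = 0.001
    tree = star_tree(6, t)
    cfg = SeqEvolConfig(
        root_length=10_000, indel_rate_ratio=0.0, seed=8, substitution_model="WAG"
    )
    res = evolve_sequences(tree, cfg)
    ids, mat = true_p_distance_matrix(res)
    pairs = mat[np.triu_indices(len(ids), 1)]
    expected = 2 * t * (1 - cfg.invariant_fraction)
    se = math.sqrt(expected * (1 - expected) / cfg.root_length)
    assert abs(pairs.mean() - expected) < 3 * se


def test_substitution_process_preserves_equilibrium():
    """Pushing 1e5 sites from a fixed state through a long branch lands on
    the model's equilibrium frequencies (3 SE per residue)."""
    from ncutphylo.simulate import _Evolver

    cfg = SeqEvolConfig(root_length=10, invariant_fraction=0.0, seed=4)
    ev = _Evolver(cfg)
    model = wag_model()
    n_sites = 100_000
    states = np.zeros(n_sites, dtype=int)  # all alanine
    rates = np.ones(n_sites)
    out = ev.substitute(states, rates, t=20.0)
    freqs = np.bincount(out, minlength=20) / n_sites
    for k in range(20):
        se = math.sqrt(model.frequencies[k] * (1 - model.frequencies[k]) / n_sites)
        assert abs(freqs[k] - model.frequencies[k]) < 3 * se + 1e-9


def test_discrete_gamma_rates_normalized_and_ordered():
    rates = discrete_gamma_rates(shape=1.0, categories=5)
    assert rates.mean() == pytest.approx(1.0)
    assert (np.diff(rates) > 0).all()
    assert discrete_gamma_rates(2.0, 1) == pytest.approx([1.0])


def test_poisson_model_is_uniform():
    model = poisson_model()
    assert np.allclose(model.frequencies, 1 / 20)
    off = model.rate_matrix[~np.eye(20, dtype=bool)]
    assert np.allclose(off, off[0])


def test_indel_events_tracked_and_homology_consistent():
    tree = star_tree(8, 0.5)
    res = evolve_sequences(tree, SeqEvolConfig(root_length=400, seed=10))
    assert res.n_insertions + res.n_deletions == len(res.indel_lengths)
    for rec in res.records:
        assert len(rec.residues) == len(res.homology[rec.id])


def test_evolution_requires_branch_lengths():
    tree = dendropy.Tree.get(data="((a,b),c);", schema="newick")
    from ncutphylo import InputError

    with pytest.raises(InputError):
        evolve_sequences(tree, SeqEvolConfig(seed=0))


def test_evolution_deterministic_for_fixed_seed():
    tree = star_tree(4, 0.3)
    a = evolve_sequences(tree, SeqEvolConfig(root_length=100, seed=42))
    b = evolve_sequences(tree, SeqEvolConfig(root_length=100, seed=42))
    assert [r.residues for r in a.records] == [r.residues for r in b.records]


# ---------------------------------------------------------------------------
# indel length distribution


def test_power_law_sampler_and_mle_round_trip():
    rng = np.random.default_rng(30)
    lengths = sample_indel_lengths(20_000, a=1.7, max_len=50, rng=rng)
    assert lengths.min() >= 1 and lengths.max() <= 50
    a_hat = power_law_mle(lengths, max_len=50)
    assert a_hat == pytest.approx(1.7, abs=0.05)


# ---------------------------------------------------------------------------
# p-distance


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("AAAA", "AAAA", 0.0),
        ("AAAA", "AAAT", 0.25),
        ("AAAA", "TTTT", 1.0),
    ],
)
def test_p_distance_equal_length(a, b, expected):
    assert p_distance(a, b) == expected


def test_p_distance_excludes_gap_columns():
    assert p_distance("AR-ND", "ARCND") == 0.0
    with pytest.raises(ComputationError):
        p_distance("----", "ARND")


def test_p_distance_monotone_in_branch_length():
    """Mean p-distance ranks with the branch-length grid (expectation trend;
    checked on per-level means over replicate simulations)."""
    grid = (0.125, 0.375, 0.750)
    means = []
    for level, bl in enumerate(grid):
        values = []
        for rep in range(6):
            tree = simulate_tree(
                SimTreeConfig(n_taxa=8, mean_branch_length=bl, seed=100 * level + rep)
            )
            res = evolve_sequences(
                tree, SeqEvolConfig(root_length=300, seed=500 + 100 * level + rep)
            )
            _, mat = true_p_distance_matrix(res)
            values.append(mat[np.triu_indices(8, 1)].mean())
        means.append(np.mean(values))
    assert means[0] < means[1] < means[2]


def test_true_p_distance_zero_only_for_identical_homologs():
    tree = star_tree(3, 0.2)
    res = evolve_sequences(tree, SeqEvolConfig(root_length=200, seed=2))
    ids = [r.id for r in res.records]
    assert true_p_distance(res, ids[0], ids[0]) == 0.0
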
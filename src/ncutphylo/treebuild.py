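"""Recursive bipartition of the similarity graph into a rooted cladogram.

Each accepted normalized cut becomes one internal node: the sequence set is
split in two, each side is split again, and so on until every cluster holds
one or two sequences. The result is a topology-only rooted binary tree
(no branch lengths), rooted at the first cut, written in newick.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

from .ncut import sweep_and_select
from .qubo import ConvergenceError, SolverConfig
from .records import InputError
from .similarity import SimilarityMatrix

__all__ = ["reconstruct_tree", "rf_distance", "read_newick", "write_newick"]


def read_newick(
    source: str, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Parse a newick string or file path into a dendropy tree."""
    kwargs = dict(schema="newick", preserve_underscores=True)
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    if "(" in source and ";" in source:  # newick text, not a path
        return dendropy.Tree.get(data=source, **kwargs)
    return dendropy.Tree.get(path=source, **kwargs)


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    text = tree.as_string(schema="newick", unquoted_underscores=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def _derive_cfg(cfg: SolverConfig, counter: int) -> SolverConfig:
    # each sub-problem gets its own deterministic child seed (< 2**31)
    child = int(np.random.SeedSequence((cfg.seed, counter)).generate_state(1)[0] % (2**31))
    return SolverConfig(
        backend=cfg.backend,
        replicas=cfg.replicas,
        sweeps=cfg.sweeps,
        t_initial=cfg.t_initial,
        t_final=cfg.t_final,
        seed=child,
        alpha_init=cfg.alpha_init,
        alpha_step=cfg.alpha_step,
        alpha_max_retries=cfg.alpha_max_retries,
        replica_exchange=cfg.replica_exchange,
        exhaustive_limit=cfg.exhaustive_limit,
    )


def reconstruct_tree(
    matrix: SimilarityMatrix,
    cfg: SolverConfig | None = None,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Build the rooted binary cladogram by recursive normalized cuts.

    Deterministic for a fixed solver seed: every sub-cluster's solve uses a
    seed derived from the master seed and the recursion order. Solver
    failures are re-raised with the offending sub-cluster's members attached.
    """
    cfg = cfg or SolverConfig()
    if matrix.n < 2:
        raise InputError("need at least 2 sequences to build a tree")
    tns = taxon_namespace or dendropy.TaxonNamespace(matrix.ids)
    taxa = {label: tns.get_taxon(label) for label in matrix.ids}
    if any(t is None for t in taxa.values()):
        missing = [k for k, v in taxa.items() if v is None]
        raise InputError(f"taxa missing from namespace: {missing}")
    counter = [0]

    def build(indices: list[int]) -> dendropy.Node:
        if len(indices) == 1:
            node = dendropy.Node()
            node.taxon = taxa[matrix.ids[indices[0]]]
            return node
        if len(indices) == 2:
            node = dendropy.Node()
            for i in indices:
                node.add_child(build([i]))
            return node
        sub = matrix.submatrix(indices)
        local_cfg = _derive_cfg(cfg, counter[0])
        counter[0] += 1
        try:
            result = sweep_and_select(sub, local_cfg)
        except ConvergenceError as err:
            members = [matrix.ids[i] for i in indices]
            raise ConvergenceError(
                f"solver failed on sub-cluster {members}: {err}",
                last_alpha=err.last_alpha,
            ) from err
        side_a = [indices[i] for i in result.side_a]
        side_b = [indices[i] for i in result.side_b]
        node = dendropy.Node()
        node.add_child(build(side_a))
        node.add_child(build(side_b))
        return node

    root = build(list(range(matrix.n)))
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds (symmetric-difference) distance, compared unrooted.

    Counts nontrivial bipartitions present in exactly one of the two trees;
    0 for identical topologies. The trees must share a leaf-label set.
    """
    labels1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    labels2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if labels1 != labels2:
        raise InputError(
            f"leaf sets differ: only-in-first={sorted(labels1 - labels2)}, "
            f"only-in-second={sorted(labels2 - labels1)}"
        )
    tns = dendropy.TaxonNamespace(sorted(labels1))
    a = read_newick(write_newick(t1), taxon_namespace=tns)
    b = read_newick(write_newick(t2), taxon_namespace=tns)
    for t in (a, b):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))
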
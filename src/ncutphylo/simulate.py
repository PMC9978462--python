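"""Simulation of random phylogenies and protein sequences evolved along them.

Trees come in two shapes: uniformly random topologies (recursive random
splits) and Yule pure-birth trees (birth rate 1). Branch lengths are drawn
from either a normal distribution (variance = mean/2, negatives resampled)
or an exponential distribution (rate 2), then rescaled multiplicatively so
the realized mean equals the configured target exactly.

Sequences evolve along the tree under a reversible amino-acid CTMC
(WAG by default) with discrete-gamma rate heterogeneity (k equal-probability
categories, category-mean representatives) plus a proportion of invariant
sites, and insertion/deletion events whose lengths follow a bounded discrete
power law (P(l) ~ l^-a, default a = 1.7) and whose expected count per branch
is a fixed fraction (default 2%) of the expected substitution count. The
simulator tracks true site homology, so p-distances can be computed without
re-alignment.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from typing import Literal, Sequence

import dendropy
import numpy as np
from scipy import optimize
from scipy.linalg import expm

from .records import InputError, SequenceRecord
from .similarity import ComputationError
from .wag import AA_ORDER, SubstitutionModel, discrete_gamma_rates, poisson_model, wag_model

__all__ = [
    "SimTreeConfig",
    "SeqEvolConfig",
    "EvolutionResult",
    "simulate_tree",
    "draw_branch_lengths",
    "evolve_sequences",
    "p_distance",
    "true_p_distance",
    "true_p_distance_matrix",
    "sample_indel_lengths",
    "power_law_mle",
]

BRANCH_LENGTH_GRID = (0.125, 0.250, 0.375, 0.500, 0.625, 0.750)
YULE_BRANCH_RATE = 2.0


@dataclass(frozen=True)
class SimTreeConfig:
    """Shape and branch-length model for one simulated tree.

    ``branch_distribution=None`` picks the conventional pairing: normal
    lengths for uniformly random topologies, exponential for Yule trees.
    """

    n_taxa: int
    shape: Literal["uniform_random", "yule"] = "uniform_random"
    mean_branch_length: float = 0.5
    branch_distribution: Literal["normal", "exponential"] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise InputError("need at least 3 taxa")
        if self.mean_branch_length <= 0:
            raise InputError("mean branch length must be positive")

    @property
    def distribution(self) -> str:
        if self.branch_distribution is not None:
            return self.branch_distribution
        return "exponential" if self.shape == "yule" else "normal"


@dataclass(frozen=True)
class SeqEvolConfig:
    """Substitution + indel model for sequence evolution.

    ``indel_rate_ratio`` is the expected number of indel events (insertions
    plus deletions) per expected substitution event; 0 turns indels off.
    """

    root_length: int = 500
    substitution_model: Literal["WAG", "poisson"] = "WAG"
    gamma_categories: int = 5
    gamma_shape: float = 1.0
    invariant_fraction: float = 0.01
    indel_power_a: float = 1.7
    indel_rate_ratio: float = 0.02
    max_indel_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise InputError("root_length must be >= 1")
        if not 0 <= self.invariant_fraction < 1:
            raise InputError("invariant_fraction must be in [0, 1)")
        if self.gamma_categories < 1:
            raise InputError("gamma_categories must be >= 1")
        if self.indel_power_a <= 1:
            raise InputError("indel_power_a must exceed 1")
        if self.indel_rate_ratio < 0:
            raise InputError("indel_rate_ratio must be non-negative")

    def model(self) -> SubstitutionModel:
        return wag_model() if self.substitution_model == "WAG" else poisson_model()


# ---------------------------------------------------------------------------
# trees

def draw_branch_lengths(
    k: int, mean: float, distribution: str, rng: np.random.Generator
) -> np.ndarray:
    """Raw (pre-rescaling) branch-length draws.

    normal: N(mean, variance = mean/2), negative draws resampled.
    exponential: rate 2 (the Yule convention), independent of the target
    mean — the caller rescales.
    """
    if distribution == "normal":
        sd = np.sqrt(mean / 2.0)
        out = rng.normal(mean, sd, size=k)
        while (bad := out <= 0).any():
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        return out
    if distribution == "exponential":
        return rng.exponential(scale=1.0 / YULE_BRANCH_RATE, size=k)
    raise InputError(f"unknown branch distribution {distribution!r}")


def _random_topology(labels: list[str], rng: np.random.Generator) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace(labels)

    def build(members: list[str]) -> dendropy.Node:
        node = dendropy.Node()
        if len(members) == 1:
            node.taxon = tns.get_taxon(members[0])
            return node
        k = int(rng.integers(1, len(members)))  # split size uniform on 1..m-1
        node.add_child(build(members[:k]))
        node.add_child(build(members[k:]))
        return node

    perm = [labels[i] for i in rng.permutation(len(labels))]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = build(perm)
    tree.is_rooted = True
    return tree


def _yule_topology(labels: list[str], seed: int) -> dendropy.Tree:
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(labels),
        rng=_pyrandom.Random(seed),
    )
    for leaf, label in zip(tree.leaf_node_iter(), labels):
        leaf.taxon.label = label
    tree.taxon_namespace = dendropy.TaxonNamespace(labels)
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tree.taxon_namespace.get_taxon(leaf.taxon.label)
    tree.is_rooted = True
    return tree


def balanced_tree(n_taxa: int, branch_length: float) -> dendropy.Tree:
    """A maximally balanced rooted binary tree with every branch the same
    length — the low-divergence fixture where clade structure is
    unambiguous and the reconstruction optimum is unique."""
    if n_taxa < 2:
        raise InputError("need at least 2 taxa")
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)

    def build(members: list[str]) -> dendropy.Node:
        node = dendropy.Node()
        if len(members) == 1:
            node.taxon = tns.get_taxon(members[0])
            return node
        half = len(members) // 2
        for part in (members[:half], members[half:]):
            child = build(part)
            child.edge.length = branch_length
            node.add_child(child)
        return node

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = build(labels)
    tree.is_rooted = True
    return tree


def simulate_tree(cfg: SimTreeConfig) -> dendropy.Tree:
    """A rooted binary tree with ``n_taxa`` leaves labeled t1..tn and branch
    lengths rescaled so their mean equals ``mean_branch_length`` exactly."""
    rng = np.random.default_rng(cfg.seed)
    labels = [f"t{i + 1}" for i in range(cfg.n_taxa)]
    if cfg.shape == "uniform_random":
        tree = _random_topology(labels, rng)
    elif cfg.shape == "yule":
        tree = _yule_topology(labels, int(rng.integers(2**31)))
    else:
        raise InputError(f"unknown tree shape {cfg.shape!r}")
    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    raw = draw_branch_lengths(len(edges), cfg.mean_branch_length, cfg.distribution, rng)
    scaled = raw * (cfg.mean_branch_length / raw.mean())
    for e, length in zip(edges, scaled):
        e.length = float(length)
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# sequences

def _indel_length_probs(a: float, max_len: int) -> np.ndarray:
    lengths = np.arange(1, max_len + 1, dtype=float)
    probs = lengths ** (-a)
    return probs / probs.sum()


def sample_indel_lengths(
    k: int, a: float, max_len: int, rng: np.random.Generator
) -> np.ndarray:
    """k draws from the bounded discrete power law P(l) ~ l^-a, l = 1..max_len."""
    probs = _indel_length_probs(a, max_len)
    return rng.choice(np.arange(1, max_len + 1), size=k, p=probs)


def power_law_mle(lengths: Sequence[int], max_len: int) -> float:
    """Maximum-likelihood exponent of the bounded discrete power law."""
    x = np.asarray(lengths, dtype=float)
    if x.size == 0:
        raise InputError("no lengths to fit")
    log_x_sum = np.log(x).sum()
    support = np.arange(1, max_len + 1, dtype=float)

    def nll(a: float) -> float:
        z = (support ** (-a)).sum()
        return a * log_x_sum + x.size * np.log(z)

    res = optimize.minimize_scalar(nll, bounds=(1.0001, 15.0), method="bounded")
    return float(res.x)


@dataclass
class EvolutionResult:
    """Leaf sequences plus the simulation truth needed for evaluation."""

    records: list[SequenceRecord]
    homology: dict[str, dict[int, str]] = field(repr=False)
    site_rates: dict[int, float] = field(repr=False)  # site id -> relative rate
    n_root_sites: int = 0
    n_invariant_root_sites: int = 0
    n_insertions: int = 0
    n_deletions: int = 0
    indel_lengths: list[int] = field(default_factory=list, repr=False)
    expected_substitutions: float = 0.0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def record(self, leaf_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == leaf_id:
                return r
        raise InputError(f"no leaf {leaf_id!r}")


class _Evolver:
    def __init__(self, cfg: SeqEvolConfig):
        self.cfg = cfg
        self.model = cfg.model()
        self.rates = discrete_gamma_rates(cfg.gamma_shape, cfg.gamma_categories)
        self.rng = np.random.default_rng(cfg.seed)
        self.next_id = 0
        self.result_sites: dict[int, float] = {}
        self._pmatrix_cache: dict[tuple[float, float], np.ndarray] = {}

    def new_sites(self, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fresh site ids with states from equilibrium and sampled rates."""
        ids = np.arange(self.next_id, self.next_id + k)
        self.next_id += k
        states = self.rng.choice(self.model.n_states, size=k, p=self.model.frequencies)
        invariant = self.rng.random(k) < self.cfg.invariant_fraction
        cats = self.rng.integers(0, self.cfg.gamma_categories, size=k)
        rates = np.where(invariant, 0.0, self.rates[cats])
        for sid, r in zip(ids, rates):
            self.result_sites[int(sid)] = float(r)
        return ids, states, rates

    def pmatrix(self, rate: float, t: float) -> np.ndarray:
        key = (round(rate, 12), round(t, 12))
        if key not in self._pmatrix_cache:
            self._pmatrix_cache[key] = expm(self.model.rate_matrix * rate * t)
        return self._pmatrix_cache[key]

    def substitute(self, states: np.ndarray, rates: np.ndarray, t: float) -> np.ndarray:
        out = states.copy()
        for rate in np.unique(rates):
            if rate == 0.0:
                continue
            idx = np.flatnonzero(rates == rate)
            p = self.pmatrix(float(rate), t)
            cum = np.cumsum(p[states[idx]], axis=1)
            u = self.rng.random(idx.size)
            out[idx] = (u[:, None] > cum).sum(axis=1)
        return out


def evolve_sequences(tree: dendropy.Tree, cfg: SeqEvolConfig) -> EvolutionResult:
    """Evolve one protein per leaf of ``tree`` (root to tips).

    Substitutions are applied over each branch via the rate-scaled transition
    matrix of the site's rate class; indel events are then placed on the
    branch with Poisson counts proportional to the branch's expected
    substitution load, uniform positions, and power-law lengths. Returns the
    leaf records together with the true homology map and event bookkeeping.
    """
    for e in tree.preorder_edge_iter():
        if e.head_node is tree.seed_node:
            continue
        if e.length is None:
            raise InputError("tree has branches without lengths")
    ev = _Evolver(cfg)
    ids0, states0, rates0 = ev.new_sites(cfg.root_length)
    result = EvolutionResult(
        records=[],
        homology={},
        site_rates=ev.result_sites,
        n_root_sites=cfg.root_length,
        n_invariant_root_sites=int((rates0 == 0.0).sum()),
    )

    def recurse(node: dendropy.Node, ids: np.ndarray, states: np.ndarray, rates: np.ndarray) -> None:
        if node.is_leaf():
            seq = "".join(AA_ORDER[s] for s in states)
            label = node.taxon.label
            result.records.append(SequenceRecord(id=label, residues=seq))
            result.homology[label] = {
                int(i): AA_ORDER[s] for i, s in zip(ids, states)
            }
            return
        for child in node.child_nodes():
            t = float(child.edge.length)
            c_ids, c_states, c_rates = ids.copy(), states.copy(), rates.copy()
            if t > 0 and c_ids.size:
                c_states = ev.substitute(c_states, c_rates, t)
                e_sub = t * float(c_rates.sum())
                result.expected_substitutions += e_sub
                if cfg.indel_rate_ratio > 0 and e_sub > 0:
                    lam = 0.5 * cfg.indel_rate_ratio * e_sub
                    n_ins = int(ev.rng.poisson(lam))
                    n_del = int(ev.rng.poisson(lam))
                    events = ["I"] * n_ins + ["D"] * n_del
                    ev.rng.shuffle(events)
                    for kind in events:
                        length = int(
                            sample_indel_lengths(
                                1, cfg.indel_power_a, cfg.max_indel_length, ev.rng
                            )[0]
                        )
                        if kind == "I":
                            pos = int(ev.rng.integers(0, c_ids.size + 1))
                            n_ids, n_states, n_rates = ev.new_sites(length)
                            c_ids = np.concatenate([c_ids[:pos], n_ids, c_ids[pos:]])
                            c_states = np.concatenate(
                                [c_states[:pos], n_states, c_states[pos:]]
                            )
                            c_rates = np.concatenate(
                                [c_rates[:pos], n_rates, c_rates[pos:]]
                            )
                            result.n_insertions += 1
                            result.indel_lengths.append(length)
                        else:
                            if c_ids.size == 0:
                                continue
                            start = int(ev.rng.integers(0, c_ids.size))
                            stop = min(start + length, c_ids.size)
                            keep = np.r_[0:start, stop:c_ids.size].astype(int)
                            c_ids, c_states, c_rates = (
                                c_ids[keep],
                                c_states[keep],
                                c_rates[keep],
                            )
                            result.n_deletions += 1
                            result.indel_lengths.append(length)
            recurse(child, c_ids, c_states, c_rates)

    recurse(tree.seed_node, ids0, states0, rates0)
    leaf_order = {leaf.taxon.label: i for i, leaf in enumerate(tree.leaf_node_iter())}
    result.records.sort(key=lambda r: leaf_order[r.id])
    return result


# ---------------------------------------------------------------------------
# p-distance

def _residues(x: SequenceRecord | str) -> str:
    return x.residues if isinstance(x, SequenceRecord) else x


def p_distance(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Proportion of differing homologous sites.

    Equal-length inputs are compared column-by-column (gap columns, ``-``,
    excluded); unequal-length inputs are first pairwise-aligned globally.
    """
    sa, sb = _residues(a), _residues(b)
    if len(sa) != len(sb):
        sa, sb = _global_align(sa, sb)
    pairs = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
    if not pairs:
        raise ComputationError("no comparable (gap-free) sites")
    diff = sum(1 for x, y in pairs if x != y)
    return diff / len(pairs)


def _global_align(sa: str, sb: str) -> tuple[str, str]:
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    aln = aligner.align(sa, sb)[0]
    return str(aln[0]), str(aln[1])


def true_p_distance(result: EvolutionResult, id_a: str, id_b: str) -> float:
    """p-distance on the simulator's true homology (shared site ids only)."""
    ha, hb = result.homology[id_a], result.homology[id_b]
    shared = ha.keys() & hb.keys()
    if not shared:
        raise ComputationError(f"no homologous sites shared by {id_a} and {id_b}")
    diff = sum(1 for s in shared if ha[s] != hb[s])
    return diff / len(shared)


def true_p_distance_matrix(result: EvolutionResult) -> tuple[list[str], np.ndarray]:
    ids = [r.id for r in result.records]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = true_p_distance(result, ids[i], ids[j])
    return ids, mat
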
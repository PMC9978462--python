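"""Normalized bit-score similarity matrices from all-against-all pairwise
local alignment.

The similarity between two proteins is the bit score of their optimal local
(Smith–Waterman, affine-gap) alignment, normalized by the mean of the two
self-alignment bit scores and rescaled to an integer in [0, 100]::

    normbit(i, j) = round( bit(i, j) / mean{bit(i, i), bit(j, j)} * 100 )

so identical sequences score 100. A pair whose alignment E-value exceeds the
cutoff (default 10) is assigned similarity 0. Raw alignment scores are
converted to bits with the Karlin–Altschul statistics

    bit = (lambda * S - ln K) / ln 2,      E = K * m * n * exp(-lambda * S)

using the standard gapped-BLOSUM62 constants lambda = 0.267, K = 0.041.
The integer matrix is the edge set of the similarity graph that the
normalized-cut partitioner consumes; integrality matters because annealing
hardware for this problem accepts integer couplings only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .records import InputError, SequenceRecord, check_unique_ids

__all__ = [
    "AlignmentParams",
    "SimilarityMatrix",
    "ComputationError",
    "pairwise_bitscore",
    "normbit",
    "build_similarity_matrix",
]

# Gapped BLOSUM62 statistics for gap cost 11 + L (BLAST convention).
GAPPED_BLOSUM62_LAMBDA = 0.267
GAPPED_BLOSUM62_K = 0.041


class ComputationError(RuntimeError):
    """A numerically degenerate input (e.g. non-positive self bit score)."""


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for pairwise local alignment and bits conversion.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of length
    L costs ``gap_open + L * gap_extend``. Residue ``X`` scores 0 against
    everything (it carries no information, so it neither rewards nor
    penalises an alignment).
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = GAPPED_BLOSUM62_LAMBDA
    k_const: float = GAPPED_BLOSUM62_K
    evalue_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise InputError("gap penalties must be positive")
        if self.lam <= 0 or self.k_const <= 0:
            raise InputError("Karlin-Altschul constants must be positive")
        if self.evalue_cutoff <= 0:
            raise InputError("evalue_cutoff must be positive")

    def make_aligner(self) -> Align.PairwiseAligner:
        matrix = substitution_matrices.load(self.substitution_matrix).copy()
        if "X" in matrix.alphabet:
            xi = matrix.alphabet.index("X")
            matrix[xi, :] = 0
            matrix[:, xi] = 0
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = matrix
        # Biopython charges open_gap_score on the first gap column and
        # extend_gap_score afterwards; shift to the BLAST open+L*extend form.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


def pairwise_bitscore(
    a: SequenceRecord,
    b: SequenceRecord,
    params: AlignmentParams | None = None,
    _aligner: Align.PairwiseAligner | None = None,
) -> tuple[float, float]:
    """Bit score and E-value of the optimal local alignment of ``a`` and ``b``.

    Returns
    -------
    (bit_score, evalue)
        ``bit_score = (lambda*S - ln K) / ln 2`` and
        ``evalue = K*m*n*exp(-lambda*S)`` for raw optimal score S and
        sequence lengths m, n. Symmetric in its sequence arguments.
    """
    params = params or AlignmentParams()
    if not a.residues or not b.residues:
        raise InputError("cannot align empty sequences")
    aligner = _aligner if _aligner is not None else params.make_aligner()
    raw = float(aligner.score(a.residues, b.residues))
    raw = max(raw, 0.0)  # local alignment score is never negative
    bit = (params.lam * raw - math.log(params.k_const)) / math.log(2.0)
    evalue = params.k_const * len(a) * len(b) * math.exp(-params.lam * raw)
    return bit, evalue


def normbit(
    bit_ij: float,
    bit_ii: float,
    bit_jj: float,
    evalue: float,
    cutoff: float = 10.0,
) -> int:
    """Normalize a pairwise bit score to an integer similarity in [0, 100].

    Pairs with ``evalue > cutoff`` get 0. Rounding is half-away-from-zero;
    ratios above 100 (possible when the cross score exceeds the mean self
    score) are clipped to 100.
    """
    if bit_ii <= 0 or bit_jj <= 0:
        raise ComputationError(
            f"non-positive self bit score ({bit_ii}, {bit_jj}): degenerate sequence"
        )
    if evalue > cutoff:
        return 0
    value = bit_ij / ((bit_ii + bit_jj) / 2.0) * 100.0
    rounded = math.floor(value + 0.5) if value >= 0 else math.ceil(value - 0.5)
    return int(min(100, max(0, rounded)))


@dataclass
class SimilarityMatrix:
    """Symmetric integer matrix of normalized bit scores (the graph edges).

    ``values[i, j]`` is the similarity of ``ids[i]`` and ``ids[j]``:
    an integer in [0, 100], with a diagonal of 100.
    """

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InputError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise InputError("duplicate ids in similarity matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise InputError("similarity values must be integers")
            self.values = np.round(self.values).astype(np.int64)
        else:
            self.values = self.values.astype(np.int64)
        if (self.values < 0).any() or (self.values > 100).any():
            raise InputError("similarity values must lie in [0, 100]")
        if not np.array_equal(self.values, self.values.T):
            raise InputError("similarity matrix must be symmetric")
        if not (np.diag(self.values) == 100).all():
            raise InputError("similarity matrix diagonal must be 100")

    @property
    def n(self) -> int:
        return len(self.ids)

    def offdiagonal(self) -> np.ndarray:
        """Float copy with a zero diagonal — the weighted adjacency matrix."""
        d = self.values.astype(float).copy()
        np.fill_diagonal(d, 0.0)
        return d

    def submatrix(self, indices: Sequence[int]) -> "SimilarityMatrix":
        idx = list(indices)
        return SimilarityMatrix(
            ids=[self.ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise InputError("similarity TSV must have matching row/column ids")
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy())


def build_similarity_matrix(
    seqs: Sequence[SequenceRecord],
    params: AlignmentParams | None = None,
) -> SimilarityMatrix:
    """All-against-all normalized bit-score matrix over ``seqs``.

    Self scores are computed first; every off-diagonal entry is the
    normalized cross bit score, zeroed when the E-value misses the cutoff.
    """
    params = params or AlignmentParams()
    seqs = list(seqs)
    if len(seqs) < 2:
        raise InputError("need at least 2 sequences")
    check_unique_ids(seqs)
    aligner = params.make_aligner()
    n = len(seqs)
    self_bits = np.empty(n)
    for i, s in enumerate(seqs):
        self_bits[i], _ = pairwise_bitscore(s, s, params, _aligner=aligner)
        if self_bits[i] <= 0:
            raise ComputationError(f"non-positive self bit score for {s.id!r}")
    values = np.full((n, n), 100, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            bit_ij, evalue = pairwise_bitscore(seqs[i], seqs[j], params, _aligner=aligner)
            values[i, j] = values[j, i] = normbit(
                bit_ij, self_bits[i], self_bits[j], evalue, params.evalue_cutoff
            )
    return SimilarityMatrix(ids=[s.id for s in seqs], values=values)
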
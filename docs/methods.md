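# Methods

## Similarity matrix

Pairwise local alignment uses Biopython's `PairwiseAligner` in local mode
with BLOSUM62 and BLAST-convention affine gaps (a gap of length L costs
11 + L). Residue `X` (unknown) scores 0 against every residue, so it neither
rewards nor penalizes an alignment. Raw scores convert to bits with the
standard gapped-BLOSUM62 Karlin–Altschul constants λ = 0.267, K = 0.041,
both exposed on `AlignmentParams`.

The E-value uses the plain `K·m·n·e^(−λS)` form without finite-length or
composition corrections. This has one practical consequence worth knowing:
for the *optimal* local alignment of two random unrelated sequences the
E-value is O(1) by construction (the Gumbel location of the best score is
where the expected hit count is about one), so entries of 0 arise only when
the best alignment is essentially empty and `K·m·n > cutoff` — i.e. for
compositionally disjoint sequences — rather than for every junk pair, and
similarity matrices from diverged data carry a small positive floor (~1–3)
where a corrected aligner would report 0. None of the partitioning logic
depends on exact zeros.

Normalization rounds half-away-from-zero to an integer (annealing hardware
for this objective takes integer couplings) and clips to [0, 100]; ratios
can exceed 100 when a cross-score beats the mean self-score, and the range
of the scale is defined as 0–100, hence the clip.

## Constrained min-cut QUBO

The objective `Σ_{i<j} d_ij (x_i − x_j)² + α(Σ x_i − c)²` is solved per
cut size `c`:

* **Exhaustive backend** (default, n ≤ 20): enumerates all 2^n labelings in
  lexicographic order, computing cut energies as `xᵀLx` with L the graph
  Laplacian, chunked at 2^16 rows; ties resolve to the lexicographically
  smallest labeling (node 0 prefers side 0), which makes every downstream
  result deterministic.
* **Simulated annealing backend**: single-bit-flip Metropolis with
  geometric cooling from T₀ (estimated as the largest |ΔE| over random
  single flips) down to T_f = 0.01, default 10⁴ sweeps of n flips. Twelve
  independent replicas run with seeds spawned from one master seed; the best
  replica wins, and per-replica best energies are retained so convergence
  (the same optimum reached by ≥ 2 chains) can be verified. Optional
  parallel tempering places the replicas on a 1×–3× temperature ladder and
  attempts adjacent swaps each sweep; it is off by default because the
  desk-scale problems here do not need it.

α-escalation starts at 100 and adds 500 per retry, capped at 20 retries
(the escalation is unbounded in principle; the cap converts a pathological
instance — e.g. a single edge so heavy that violating the constraint is
cheaper than any admissible cut — into an explicit convergence error that
reports the last α tried).

## Ncut selection and tree assembly

`assoc(A,V)` excludes the diagonal self-similarities by default (the graph
is a pairwise-similarity graph; a constant 100 self-edge per node would
inflate both denominators uniformly). A flag `include_diagonal` keeps the
other reading testable. The cut value entering Ncut is always the pure cut
term, never the penalty (which is zero for any accepted solution).

The sweep runs `c = 1 .. ⌊n/2⌋` (the upper half is redundant by complement
symmetry) and keeps the smallest Ncut, ties toward smaller `c`. An important
property, verified and documented in the tests: the sweep scores only the
*minimum-cut* bipartition of each cardinality class, so it is a
near-optimal — not exact — Ncut minimizer. Within a cardinality class the
minimum-cut and minimum-Ncut bipartitions usually coincide on matrices with
real cluster structure (we verify exact global optimality on planted-group
fixtures by full enumeration), but they can differ on unstructured dense
random matrices, where the sweep lands slightly above the global optimum.
This is inherent to computing Ncut by post-processing min-cuts; Ncut itself
has no exact quadratic binary encoding.

Trees are rooted at the first cut; three-member clusters are forced into a
1|2 split (the only admissible c = 1), so the output is always fully binary.
Reconstructed trees carry no branch lengths — the method infers topology
only. Robinson–Foulds comparison is performed unrooted so the arbitrary root
placement does not count as a difference. Every sub-cluster solve receives a
seed derived from the master seed and the recursion index, making whole-tree
reconstruction reproducible.

## Simulation protocol

* **Topologies**: `uniform_random` (recursive uniformly-random splits) or
  `yule` (pure birth, rate 1, via dendropy). `balanced_tree(n, b)` builds the
  maximally balanced tree with every branch equal — the low-divergence
  fixture where the reconstruction optimum is unambiguous.
* **Branch lengths**: normal with variance = mean/2 (negatives resampled,
  which makes the raw draws left-truncated — the tests check the mean against
  the truncated-normal expectation, not the nominal mean) or exponential
  with rate 2; either way all branches are rescaled multiplicatively so the
  realized mean equals the configured target exactly. Grid of interest:
  0.125–0.750 substitutions/site.
* **Substitutions**: WAG exchangeabilities and frequencies embedded as
  published constants; rate matrix normalized to one expected substitution
  per unit branch length at equilibrium. Rate heterogeneity is discrete
  gamma with k = 5 equal-probability categories represented by category
  means (shape defaults to 1.0; the shape is a free parameter of Γ models
  and is exposed as `gamma_shape`), plus 1% invariant sites with rate 0.
  Branch lengths therefore count substitutions per *variable* site; with 1%
  invariant sites the distinction is below the resolution of any test here.
  Transition matrices are `expm(Q·r·t)` per rate class, cached per branch.
  A uniform Poisson model is included as a fast closed-form test double.
* **Indels**: expected event count per branch is
  `ratio · t · Σ_site r_site` (2% of the expected substitution load), split
  evenly between insertions and deletions; positions uniform; lengths from
  the discrete power law P(ℓ) ∝ ℓ^(−1.7) truncated at 50. Substitutions are
  applied over the whole branch first, then indels — at a 2% event ratio the
  interleaving error is negligible. Inserted sites get fresh identities, so
  the simulator's homology map is exact and `true_p_distance` needs no
  realignment.

What the simulator does **not** emulate: among-lineage rate variation
(heterotachy), compositional drift, domain-level rearrangement, alignment
error in the similarity stage (sequences are compared by true local
alignment, not by a reconstructed MSA). Passing tests therefore demonstrate
correctness of the machinery and behaviour in the controlled regime, not
performance on hard real data.

## Evaluation stack

Spectral bipartition embeds nodes with the Fiedler vector of the symmetric
normalized Laplacian and chooses between the sign split and the median split
by lower Ncut — deterministic, unlike k-means-assigned spectral clustering,
and cross-checked against scikit-learn on easy fixtures. k-means (k = 2,
100 restarts, matrix rows as features) and Ward (on distances
100 − similarity) wrap scikit-learn/scipy. NMI uses the arithmetic-mean
normalization. Transitivity is computed on the graph thresholded at
similarity > 0. The k-means criterion sums squared within-cluster distances
with the transform distance = 100 − similarity.

## Numerical and design notes

* All integer energies are exact in float64 (values ≤ 100·n² ≪ 2⁵³).
* The cardinality count runs over all n nodes (one summation bound in the
  objective's usual statement is off by one; the count of 1-labels is over
  the full label vector).
* A worked prose example sometimes quoted for the penalty term ("c = 5,
  three 1-labels → excess 2α") contradicts the quadratic form, which gives
  (3−5)²α = 4α; the quadratic form is authoritative and is what the
  exhaustive enumeration tests pin down.
* Problem sizes in the test suite (n ≤ 16 end-to-end, n ≤ 12 for brute-force
  oracles, 500-sweep annealing runs) are chosen so every oracle is a full
  enumeration and the whole suite stays fast; they are desk-scale versions
  of the same algorithms, not modified algorithms.

## Known limitations

* Bit scores come from the package's own aligner with textbook constants,
  not from BLAST; matrices will differ in detail from BLAST-derived ones
  (gap parameters and λ/K were unstated in the protocol this follows, and
  exact score agreement is explicitly not a goal).
* The Ncut sweep is near-optimal, not exact, on unstructured matrices (see
  above).
* Topology recovery degrades sharply when branch lengths are highly
  variable: similarity clustering pairs taxa by overall divergence, so a
  short-branch taxon sister to a long-branch taxon is routinely misplaced —
  the classic failure mode shared by all similarity/distance clustering
  without rate correction. Recovery claims in the tests are made for the
  balanced equal-branch-length regime.
* The exhaustive backend is capped at n = 20; larger clusters require the
  annealing backend, whose solution quality then depends on sweeps/replicas.
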
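# Methods

## Model

A hetnet is a typed graph described by a metagraph (metanodes and
metaedges). Each metaedge is stored as one boolean biadjacency matrix; node
order within a metanode is lexicographic by identifier and fixed at store
creation, so matrix indices are reproducible. Self-loops and duplicate edges
are rejected on load because every repeat correction below assumes zero
adjacency diagonals.

The connectivity statistic is the degree-weighted path count. For metaedge
*e* with biadjacency A and degrees d (row/column sums of A), the damped
adjacency is Â_ij = A_ij (d_i d_j)^(−w). Entries where A_ij = 0 are defined
as zero, so isolated nodes never divide by zero, and w = 0 recovers A. This
entrywise form makes a product of damped matrices equal the sum of path
degree products over walks, which is what permits the path-level
decomposition used for ranking individual paths (the sum of PDPs over
enumerated simple paths reproduces the matrix entry to 1e-10).

### Walk-to-path corrections

Products of damped matrices count walks. Duplicate nodes can only arise
between two positions of the same metanode, so metapaths are analyzed by
their repeated-metanode pattern. Position spans of repeated metanodes are
merged when they overlap; each merged group is corrected independently and
groups are chained by ordinary multiplication (no metanode is shared across
groups by construction).

Within a group:

- **Single anchor metanode, 2–3 occurrences.** The sub-metapath between
  consecutive occurrences is evaluated recursively, its diagonal is
  subtracted (removing walks returning to the anchor), and partial products
  are re-corrected at each chaining step. The recursion makes the nested
  `BAAB` family a special case: the interior between the outer anchors is
  just another segment with its own repeat. When evaluating an interior
  whose endpoints are the already-corrected anchor pair, that pair is masked
  so it is not re-detected (otherwise `C(BABA)C` would recurse forever).
- **Exact `XYXY` interleaving.** Inclusion–exclusion over the two possible
  coincidences: full product, minus the two diagonal-projected terms, plus
  the Hadamard term for walks where both coincide.
- **Anything else** — four or more occurrences of one metanode, or three-way
  interleavings like `ABCABC` — has no closed form here and is evaluated by
  exhaustive simple-path DFS with damped edge weights. The same DFS,
  applied to whole metapaths, is the independent oracle the matrix routines
  are tested against (entrywise tolerance 1e-10, accumulation in float64).

The printed three-term corrections for the short, nested and overlapping
patterns are recovered exactly by this recursion; the triple-product-minus-
diagonal reading of the nested case is the only one consistent with
excluding equal outer endpoints, and is validated against the oracle.

An *approximate* variant replaces the enumeration fallback by correcting
only the first repeat (first two occurrences of the earliest-repeating
metanode). Since every correction subtracts non-negative walk weight, the
approximation never falls below the exact DWPC; it equals the exact value
whenever no complex group is present. Results are flagged `approximate`.

Path counts are computed with the same machinery at w = 0 and stored as
64-bit integers; DWPCs are 64-bit floats. Matrices denser than 0.7 are
serialized dense (`.npy`), sparser ones as compressed sparse (`.sparse.npz`);
the strict inequality ("< 0.7 is sparse") is asserted in tests. A small LRU
cache keyed by (segment abbreviation, w, store fingerprint) can reuse
segment results across metapaths; tests assert it is semantically invisible.

## Permutation null

XSwap is applied independently per metaedge: `multiplier × edge-count`
attempts (default multiplier 10), each picking two random edges and
exchanging endpoints, rejected if a self-loop or duplicate would result.
Undirected same-metanode metaedges are permuted on the canonical
(min, max) edge list and mirrored, preserving symmetry; swaps are applied to
the stored orientation without random re-orientation, which keeps the
two-disjoint-edge outcome set at exactly two states. Per-metaedge seeds are
derived as crc32 of (base seed, metaedge abbreviation), so adding a
metaedge does not reshuffle the others. Degree sequences are preserved
exactly, by construction, and asserted per metaedge.

Null DWPC values from permuted networks are pooled by (source degree w.r.t.
the metapath's first metaedge, target degree w.r.t. its last), storing only
additive running totals (N, n, Σx, Σx², permutation count). Grouping is
always within a metapath, never across metapaths.

## Gamma-hurdle significance

The pooled null is modeled as P(X = 0) = 1 − λ with Gamma(α, β) on the
positive part. Method-of-moments with Bessel's correction:
λ̂ = n/N, μ̂ = Σx/n, σ̂² = (nΣx² − (Σx)²)/(n(n−1)), α̂ = μ̂²/σ̂²,
β̂ = μ̂/σ̂². The fit is attempted only when n ≥ 2 and σ̂² > 0. The tail
probability of an observed DWPC t > 0 is p = λ·Q(α̂, β̂t) with Q the
regularized upper incomplete gamma (`scipy.special.gammaincc`); the λ factor
is required for internal consistency of P(X ≥ t) with the hurdle mass at
zero. t = 0 gives p = 1.

When the fit is ineligible, empirical rules computable from the summary
statistics apply: t = 0 → p = 1; all-zero null with t > 0 → p = 0; all
nonzero nulls equal (σ = 0) → p = 0 if t exceeds that value, else n/N.
A returned result records which method produced it, plus the nonzero null
mean and standard deviation when estimable.

Observed DWPCs are compared to null DWPCs on the raw scale: any monotone
transform of the statistic leaves tail probabilities invariant, so no
variance-stabilizing transform is applied before p-value computation.

Multiple testing across the metapaths evaluated for one query is handled by
a Bonferroni factor equal to the number of metapaths of the same length
between the two metanodes (counting one orientation per metapath), capped
at 1. No FDR procedure is provided: group-level p-values are far from
uniform under the null (most DWPCs are zero), which breaks the usual FDR
assumptions.

### Calibration

The held-out-permutation experiment (tests and acceptance script) generates
50 permutations of a 50×50 bipartite network (density 0.2), pools 49 into
degree-grouped statistics, and scores the held-out network's nonzero DWPCs
for the `AxBxA` metapath. Because λ varies by degree group, uniformity is
assessed on the gamma tail probability Q(α̂, β̂t) — the observed p equals
λQ, uniform on (0, λ) under the model — yielding ~2,100 evaluable pairs and
a Kolmogorov–Smirnov statistic of ≈ 0.03–0.05 across seeds.

## Search semantics

A query (a, b) scores every metapath of length ≤ 3 (default) between the
two metanodes, oriented from a's metanode to b's. When both endpoints share
a metanode, a non-palindromic metapath and its reverse are genuinely
different templates from a to b; both rows are returned, with reversed
abbreviations, so swapping the query nodes reverses abbreviations but
preserves values. Rows are sorted by adjusted p-value (ties: DWPC
descending, then abbreviation — the tie-break is an implementation choice).
Paths are enumerated for metapaths with nonzero DWPC, scored with the
*unadjusted* p-value by default (exposed as a choice in the API), with
−log₁₀(0) capped at 320 to keep scores finite. The database
storage-prioritization rule — keep all nonzero DWPCs at length 1, and those
with adjusted p below 5·(n_source·n_target)^(−0.3) at length ≥ 2 — is
modeled as an optional output filter rather than a storage tier.

## Synthetic data

The fixture generator materializes a user-specified metagraph with
per-metanode node counts and per-metaedge densities, exact edge counts, or
exact degree sequences (Havel–Hakimi for undirected same-metanode,
Gale–Ryser greedy otherwise, followed by seeded XSwap so the realization is
randomized while honoring degrees exactly). Random edges are uniform draws
without replacement from the allowed pair set; everything is a pure
function of the spec, including its seed.

Problem sizes were chosen so the full suite runs in well under a minute:
oracle-equivalence fixtures use 2–4 metanodes of 3–7 nodes (the matrix and
enumeration routes agree to ~1e-15 there, and nothing in either route's
arithmetic depends on scale); calibration uses the 50×50 network above;
planted-signal recovery uses 20 seeded Compound/Gene/Pathway networks with
extra `CbG` and `GpPW` edges concentrated on one pair, 25 permutations per
network. These synthetic networks emulate the storage layout, degree
heterogeneity and sparsity of real knowledge graphs but not their
correlated edge placement (e.g. hub–hub enrichment, ontology structure), so
passing tests demonstrate correctness of the statistics and algorithms, not
biological validity of any particular ranking.

The Hetionet v1.0 *schema* (11 metanodes, 24 metaedges, published node
counts; only the directed Gene-regulates-Gene metaedge is asymmetric) is
bundled as JSON for schema-level checks — metapath enumeration counts
(24/242/1,939 at lengths 1/2/3), the Disease–Pathway Bonferroni factor of
3, and storage-threshold arithmetic. Node and edge *data* are out of scope;
quantities requiring the full matrices (degree-pair tallies and the like)
are not recomputed.

## Known limitations

- Matrices are densified for computation; the package targets desk-scale
  and moderately sized networks, not the multi-billion-DWPC scale the
  storage format is designed to archive.
- Without random re-orientation, XSwap on undirected same-metanode
  metaedges explores a subset of the degree-preserving configuration space
  reachable by head-exchanges on the canonical orientation; mixing is
  empirically adequate (under half the edges remain in place at
  multiplier 10) but not uniform over all realizations.
- Complex repeat patterns cost exponential enumeration time; the path
  budget raises a structured error rather than running unboundedly.
- The gamma-hurdle is a model: groups with very few nonzero nulls fall back
  to coarse empirical rules, and p-values are quasi-significance scores,
  not frequentist guarantees.
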
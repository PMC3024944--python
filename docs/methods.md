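# Methods

## Assignment model

A reference taxonomy is a rooted multifurcating tree `T` with leaf set
`L`; each leaf carries a reference sequence.  A read `R_i` has a hit set
`M_i ⊆ L`: the leaves whose sequence contains a window of length `|R_i|`
within `k` mismatches (Hamming distance; `N` mismatches every base).
Reads with no hits are retained and reported as unassigned; reads with a
single hit go to that leaf.  An ambiguous read (`|M_i| ≥ 2`) is assigned
within `T_i`, the subtree rooted at the LCA of `M_i`.  For a candidate
node `j` of `T_i` the leaves of `T_i` split into TP (hits under `j`), FP
(non-hits under `j`), FN (hits outside `j`) and TN (the rest), and the
penalty score is

    PS(i,j) = q·|FN|/|TP| + (1−q)·|FP|/|TP|,   PS = ∞ if |TP| = 0,

minimized over `j`.  Boundary behavior: `q = 0` admits a zero-penalty
assignment at a hit leaf; `q = 1` forces the LCA; `q = 0.5` coincides
with F-measure maximization.  All of these are covered by exact tests.

### Algorithms and complexity

Preprocessing (once per taxonomy): a left-to-right postorder traversal
assigns each node its 1-based number `post(j)` and the minimum number
`m(j)` in its subtree; `j` is a proper ancestor of `j'` iff
`m(j) ≤ m(j') ≤ post(j') < post(j)`, an O(1) test on closed, laterally
disjoint-or-nested intervals.  LCA queries use an Euler tour with a
sparse table (O(|T| log |T|) preprocessing, O(1) per query).  Subtree
leaf counts `|L_j|` are accumulated in the same pass.

Per read, two routes are implemented and cross-checked:

* **naive** — score every node of `T_i` using the recursive relations
  `|M_{i,j}| = Σ_children`, `|L_{i,j}| = Σ_children`,
  `|N_{i,j}| = |L_{i,j}| − |M_{i,j}|` (leaf base cases: a hit leaf
  contributes (1,1), a non-hit leaf (0,1)); O(|T_i|).
* **fast** — score only *relevant* nodes (hit leaves and LCAs of two or
  more hits), which always contain a minimizer: if `j` is not relevant,
  the LCA of its hits has the same `|M_{i,j}|` and no more false
  positives.  The relevant nodes form the topological restriction
  `T_i || M_i` (≤ `2|M_i| − 1` nodes), built by sorting hits by postorder
  number, adding adjacent-pair LCAs, sorting the node intervals by
  `(m(j) asc, post(j) desc)` and recovering parent links with a stack
  sweep; O(|M_i|) per read after preprocessing.

The fast route reports only relevant minimizers; the naive route reports
the full tie set.  Equality of the *minimum score* (not of tie sets) is
the contract, verified exactly against a whole-tree brute-force oracle on
500 seeded instances × 11 q values.

### Numerics, ties, degenerate inputs

Scores are exact `Fraction`s; `q` given as a float is snapped to the
nearest rational with denominator ≤ 10⁶ (so grid values like 0.1 are
exact) and validated to [0, 1].  Ties are therefore exact, with a
deterministic canonical representative: fewest subtree leaves, then
smallest postorder number — the most specific choice, consistent with the
q=0 guarantee of a leaf optimum.  The full tie set is exposed alongside
(`best_nodes`, `n_ties`).  Child order, and hence postorder numbering, is
taken from input-file order for run-to-run determinism.  Empty hit sets
yield an unassigned marker; duplicate hits are deduplicated with a
warning; duplicate leaf names, ragged lineage rows and empty inputs are
hard errors.

## Validation metrics

With a known true source leaf `H_i`, the confusion is computed against
the singleton set `{H_i}` within `T_i`: `TPR_H ∈ {0, 1}` (1 iff `H_i`
lies under the assigned node) and
`FPR_H = (|L_{i,j}| − TPR_H)/(|L_i| − 1)`.  The signed distance of the
ROC point to the diagonal is

    D = +(√2/2)·(|L_i| − |L_{i,j}|)/(|L_i| − 1)      if H under j,
    D = −(√2/2)·(|L_i| − |L_{i,j}| − 1)/(|L_i| − 1)  otherwise.

The negative branch is implemented exactly as the method defines it even
though it is *not* the geometric point-to-diagonal distance of
`(FPR_H, 0)` (which would be `(√2/2)·FPR_H`); the two differ by the
constant `√2/2` minus a rescaling.  This asymmetry is deliberate and
documented rather than "fixed", so results remain comparable with the
method as published elsewhere.  `G_q` sums `D` over reads at fixed `q`;
LCA assignments contribute exactly 0 whenever the truth is among the
hits, so `G_1 = 0` on clean data.

Without truth, `E(D) = p·D_in + (1−p)·D_out` with `p = |M_{i,j}|/|M_i|`.
The per-read best-q rule maximizes `E(D)` over the grid and falls back to
the LCA when no candidate is positive (the LCA itself always has
`E(D) = 0`).  Truth-based precision and recall per read are
`TPR_H/|L_{i,j}|` and `TPR_H`; dataset values are unweighted means over
ambiguous, non-degenerate reads (`|M_i| ≥ 2` and `|L_i| > 1`; degenerate
reads are excluded from all sums and counted separately).  The mean is
used rather than the sum so values are comparable across dataset sizes;
at `q = 0` every assignment sits at a leaf, forcing precision = recall
exactly under any fixed aggregation.

Monotone trends (precision non-increasing, recall non-decreasing in `q`)
are asserted per consecutive grid step within two standard errors of the
difference of the two mean estimates.  Small low-q precision inversions
within that noise are expected: the q=0 canonical leaf is an arbitrary
member of the hit set, while slightly larger `q` locates the hit-dense
cluster that also concentrates the truth.

## Synthetic data generator

The generator emulates a 454-style 16S rRNA amplicon experiment at desk
scale, with every stage driven by one seed (sub-streams for tree,
sequences and reads), byte-identical across runs.

* **Taxonomy** — uniform-depth ranked tree (7 ranks by default, canonical
  names).  Level widths are bottom-heavy: they shrink geometrically by
  `branching` (default 3) going up from the species level, so a 200-leaf
  tree has a handful of phyla and ~3 species per genus — the shape of
  curated 16S taxonomies, which are narrow at the top and wide at the
  bottom.  Nodes at each level are partitioned among the previous level's
  nodes with every parent receiving at least one child; quota-1 lineages
  produce unary chains, as real taxonomies contain.
* **Sequences** — root sequence uniform random (default 1,500 bp,
  near-full-length 16S); each child is its parent with independent
  per-site substitutions at `per_level_substitution_rate` (default
  0.015/site/level, leaving sibling species ~97% identical — the
  conventional 16S species-level identity threshold).  Similarity thus
  decays with tree distance, which is what makes reads ambiguous among
  nearby leaves.
* **Reads** — uniform source leaf and window (default 100 bp, optionally
  restricted to a sub-region to mimic hypervariable-region amplicons);
  per-base substitution errors (default 0.005) and at most one ±1 bp
  event per homopolymer run of length ≥ 2 (default rate 0.01 per run),
  reflecting the homopolymer-dominated error profile of 454 sequencing;
  reads shorter than 75% of the expected length are discarded.  The true
  source leaf of every read is recorded.

Default dataset size is 200 leaves × 2,000 reads, matched at `k = 2`
mismatches; five such seeds run in ~10 s and give ≥ 4,000 pooled
ambiguous reads with the truth among the hits for ~99.9% of matched
reads.  These sizes were chosen so that statistical checks have power
while whole suites stay fast.

What the generator does **not** model: PCR chimeras, clone-size
distributions, quality scores (FASTQ), contaminant or off-target reads,
rate heterogeneity across sites (real 16S has conserved and hypervariable
regions), and taxonomies with non-uniform leaf depth.  Passing tests on
synthetic data therefore demonstrate the correctness of the assignment
and validation machinery and the direction of parameter effects, not
classifier performance on real communities.  One consequence of the
simple fixed-`k` matcher: the mean hit-set size *decreases* as the read
error rate rises (each error consumes mismatch budget), so ambiguity is
tuned via the reference divergence and read length rather than the error
rate.

## Built-in matcher

The matcher implements the Hamming-window criterion directly: a leaf is a
hit iff some reference window of the read's length is within `k`
mismatches.  Search uses the pigeonhole principle (split the read into
`k+1` blocks; any qualifying window matches one block exactly), i.e.
exact-seed lookup plus vectorized Hamming verification; reads of length
≤ `k` trivially match every long-enough reference.  It is a test/demo
stand-in for a production read mapper: forward strand by default (with an
opt-in reverse-complement scan, since amplicon reads are typically
orientation-normalized), no quality awareness, no indexing structures
beyond the in-memory seed table.  Equivalence to a naive sliding-window
scan is tested, including `N` handling and `hits(k) ⊆ hits(k+1)`
monotonicity.  BLAST tabular input is supported as an alternative source
of hit sets, grouping each query's subjects that tie at its minimum
e-value under a cutoff (default 10⁻³).

## Known limitations

* The O(1)-LCA structure assumes a static taxonomy; there is no tree
  editing or NCBI dump ingestion.
* The fast route's tie set omits non-relevant co-minimizers by design
  (e.g. a unary chain below the LCA at `q = 1`); downstream rank tallies
  use the canonical node, with the tie count reported per read.
* Reported ranks are depth-based labels; non-uniform-depth taxonomies are
  supported but get generic `level-k` ranks.
* The validation distances inherit the printed asymmetric negative branch
  (above); absolute `G_q` values are therefore comparable only within
  this convention.
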
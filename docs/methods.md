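# Methods

`celltreeq` infers *cell-type trees* — hierarchies relating cell-types by
their differentiation history — from ChIP-Seq histone-modification peak
calls, using quartet-based phylogenetics, and scores the resulting trees
against known cell-type groups.

## Data model

The premise is that histone marks (H3K4me3, H3K27me3, H3K36me3, H3K27ac,
...) are gained and lost approximately independently across genomic regions
during differentiation, so each region behaves like a two-state character
evolving along the cell-type tree.  A peak library (one per cell-type) is
reduced to presence/absence characters in one of two ways:

* **Overlap representation** (default).  All peaks from all libraries form
  an interval graph — one vertex per peak, an edge when two peaks share at
  least one base.  Each connected component ("interesting region") is one
  matrix column; a cell is 1 iff the row's library contributed a peak to
  the component.  Coordinates are BED-style 0-based half-open, and
  *abutting* intervals ([0,10) and [10,20)) do **not** overlap.  Connected
  components are the reduction that makes "one column per region" well
  defined; by construction no column is all-zero.  The encoding is
  invariant to library input order and to pre-merging overlapping peaks
  within a library (both are tested properties).
* **Windowing representation**.  Chromosomes are tiled into fixed-size
  bins; a cell is 1 iff at least one peak of the library intersects the
  bin.  Requires chromosome sizes; kept mainly for comparison.

Strand and peak scores are ignored — the coding is presence/absence only.
Multiple marks can be combined by concatenating matrices over the
cell-types common to all of them (a supermatrix), dropping non-shared rows
with a log message.

## Substitution model and likelihood

Characters evolve under a stationary two-state Markov chain.  The default
is the symmetric Cavender–Farris–Neyman (CFN) model, π₀ = π₁ = ½, with

P(change | branch t) = (1 − e^(−2t)) / 2,

t in expected substitutions per character.  A general stationary chain
with empirical frequencies is available (`model="empirical"`), with
P_ij(t) = π_j + (δ_ij − π_j)·e^(−t/(2π₀π₁)) so branch lengths keep the
same units.  No rate heterogeneity (Γ) and no ascertainment correction are
applied; constant columns are retained (under the symmetric model they
inform branch lengths but not topology).  The interface leaves room for
both extensions.

Quartet log-likelihoods use Felsenstein pruning with the virtual root on
the internal edge; the model is reversible, so root placement does not
affect the result (tested).  Site patterns are compressed to the ≤16
unique patterns with counts, making the per-evaluation cost independent of
matrix length.

### Branch-length optimization

For a fixed quartet topology the five branch lengths are fitted by
coordinate ascent.  The key numerical device: writing e = e^(−rate·t), every
transition matrix is affine in its own e, so with the other four branches
fixed the per-pattern likelihood is a + b·e and the coordinate objective
Σ c·log(a + b·e) is strictly concave.  Each coordinate step therefore
needs two full pattern evaluations (e = 0 and e = 1) plus a safeguarded
Newton/bisection on the monotone derivative, and is solved *exactly* within
bounds.  Cycling stops when a full cycle improves the log-likelihood by
less than `tol` (default 1e−6; max 100 cycles); the log-likelihood is
non-decreasing by construction because only improving steps are accepted.
Branch lengths are box-constrained to [1e−8, 20] (20 ≈ saturation).
Initial lengths come from pairwise CFN distances
d = −½·ln(1 − 2p̂), with the mismatch fraction p̂ clamped to
[1e−6, 0.499].  An all-constant 4-row matrix has unidentifiable lengths:
the fit returns all-zero lengths with a warning flag rather than an error.

## Quartet inference (IQA and MLQA)

For a matrix on n cell-types, both schemes output exactly one quartet per
4-subset (C(n,4) total), each weighted by its optimized log-likelihood:

* **MLQA** fits all three topologies of each 4-row submatrix and keeps the
  highest-likelihood one.  Exact ties (within 1e−9) are broken in
  canonical topology order with a logged warning.
* **IQA** mimics a per-subset ML tree search: the starting pairing
  minimizes the sum of within-pair CFN distances (the four-point
  condition), branch lengths are optimized, and nearest-neighbour
  interchanges are accepted while they strictly improve the likelihood.
  Because a quartet has only three topologies the search is exhaustive in
  the worst case, so IQA and MLQA must agree wherever the best topology is
  separated by more than numerical tolerance — asserted in the tests.

A 4-leaf tree's likelihood depends only on the four corresponding rows, so
submatrix restriction is the computable reading of "likelihood with respect
to the full matrix".

## Amalgamation

The target is a single unrooted binary tree consistent with as many
quartets as possible (NP-hard).  Two solvers:

* **Exact** (n ≤ 10): all (2n−5)!! topologies enumerated by stepwise leaf
  addition; consistency counting uses a precomputed split→quartet bitset
  table so each tree costs O(n) bit operations.  Ties break to the
  lexicographically smallest canonical newick.  Serves as the oracle for
  the heuristic.
* **QFM-style heuristic**: recursive bipartitioning.  At each level the
  current taxon set (plus a dummy taxon standing for the rest of the tree)
  is split to maximize satisfied-minus-violated quartets, where a quartet
  ab|cd is satisfied when one pair lies wholly on each side, violated when
  both pairs straddle the cut, and deferred otherwise.  Deferred quartets
  descend into whichever side holds ≥3 of their taxa, the far-side taxon
  replaced by the dummy.  The partition search is Fiduccia–Mattheyses
  style: repeatedly move the single best unlocked taxon (deterministic
  tie-break by label), lock it, and at pass end keep the best prefix;
  passes repeat while they gain.  Each side must keep at least two taxa —
  this both matches the recursion's needs and guarantees the side-plus-dummy
  subproblems strictly shrink (1-vs-rest cuts would not terminate).
  Random balanced restarts (default 20) guard against local optima; the
  default was raised from a smaller value after it failed to recover
  fully consistent inputs on a fifth of test seeds, whereas 20 restarts
  recovers all of them at negligible cost next to the likelihood stage.
  Deterministic given the seed (default 42).

Quartet weights from MLQA/IQA are log-likelihoods — negative and
scale-dependent — so they are *not* used as amalgamation weights by
default; `weighted=True` opts into the summed-weight objective, which with
unit weights reduces exactly to the count objective.

## Evaluation metrics

Trees are unrooted, so a "clade" is one side of an edge; both sides of
every edge are considered.  Given a leaf→group map:

* **Groupings score (m1, m2)**: sizes of the two largest maximal clades
  containing only members of the group (maximal pure sides of a tree are
  automatically disjoint).  (k, 0) means the group forms one exact clade;
  the score is deliberately sensitive to a single alien intrusion.
* **α-ratio profile**: for each member count m from the largest pure clade
  size up to the group size, the minimal clade size s housing at least m
  members, reported as α = m/s.  α stays near 1 when the group is nearly
  contiguous despite intruders, which is exactly the failure mode the
  groupings score over-penalizes.  s is non-decreasing in m (asserted).

Degenerate case (every leaf in one group): groupings (n, 0), profile
{(n, n)}.  Both metrics depend only on the split set, hence are invariant
under rerooting/rotation of the newick rendering (tested).

## Synthetic data

The generator stands in for ENCODE/CISTROME peak calls so every stage is
testable offline.  Model trees use uniform random leaf attachment;
branch lengths are uniform on [0.05, 0.6] with internal branches floored
at 0.3 — the strong-internal-signal regime the recovery experiments
assume.  Characters are i.i.d. across sites (matching the independent
gain/loss premise; no linkage or chromatin-domain correlation).  Default
problem size is 10 taxa × 5000 sites.  `matrix_to_peaks` inverts the
overlap representation onto a synthetic chromosome (one anchor interval
per column, gap-separated), so re-encoding reproduces the planted matrix
up to all-zero columns, which the overlap representation cannot express —
those are logged and dropped.  `paint_groups` assigns group labels to
contiguous patches of a deterministic tree traversal so evaluation metrics
have a known ground truth.

What passing synthetic tests do *not* show: real peak data have
length/score distributions, spatially correlated domains, batch effects
and replicate structure that the generator does not emulate; results here
validate the algorithms, not the biology.

## Known limitations

* **Saturation at depth.**  Under the default generator regime the
  leaf-to-leaf path length for distant pairs in a 10-taxon tree reaches
  ~3 expected substitutions, i.e. a CFN mismatch probability of ~0.499.
  At 5000 sites the sampling error of the mismatch fraction (~0.007)
  swamps that signal, so deep 4-subsets are unresolvable by any
  likelihood method — an independent R/phangorn fit reproduces our
  per-topology log-likelihoods to all printed digits and picks the same
  topology on such subsets.  Roughly a quarter of quartets then carry no
  usable signal, and the true tree no longer uniquely maximizes quartet
  consistency: full 10-taxon end-to-end recovery fails for most seeds
  under these conditions, and the corresponding end-to-end test documents
  this honestly rather than passing.  Shallower trees (branch lengths a
  few times smaller, as in the CLI wiring tests) recover reliably.
* Exact amalgamation is exponential and guarded to n ≤ 10.
* IQA and MLQA differ only in search order on 4-leaf problems; the
  operational distinction matters for external ML engines, less so here.
* The equivariance of the heuristic under relabeling holds for inputs with
  a clear optimum; under heavy ties the restart randomization is tied to
  label order and may break exact equivariance.
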
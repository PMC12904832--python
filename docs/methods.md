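# Methods

## Model of computation

The package simulates a distributed-memory reduction over p processing
elements (PEs). All arithmetic is strict 64-bit IEEE 754 binary64 with
round-to-nearest ties-to-even, no fused multiply-add and no reassociation:
the engine applies the reduction operator `⊕` pairwise, one application per
internal node of the reduction tree, with the operand order fixed as
(earlier-post-order value) `⊕` (later-post-order value). Commutativity is
never assumed — the non-commutative token-concatenation monoid is a built-in
operator precisely because it is a complete witness of the realized order:
its output spells out the association order literally.

### Reduction tree

The tree over n elements splits interval `[a,b)` at `a + ⌈(b−a)/2⌉` and
recurses; singleton intervals are leaves. This is the canonical balanced
pairwise-summation shape: deterministic, depth ⌈log₂ n⌉, and the same shape
the sequential oracle evaluates. A pairwise reduction is required for
bit-reproducibility; the particular *shape* of the binary tree is a free
design choice, and the balanced ceiling-split was chosen because it minimizes
depth and matches the classic pairwise-summation error analysis (worst-case
rounding error O(log n) versus O(n) for a left fold). Nodes are identified
by their global post-order index; n = 0 is rejected rather than requiring
operators to supply an identity element.

### Communication tree

A k-nomial tree over the p PEs: the parent of PE r > 0 is r with its lowest
nonzero base-k digit cleared. For k = 2 this reduces to the standard binomial
tree used by MPI reduction collectives; the generalization to arbitrary k ≥ 2
(tests exercise k ∈ {2,4}) keeps the same digit-clearing rule. The tree has
exactly p−1 edges, so a reduction exchanges the theoretical minimum of p−1
messages and an all-reduction (reduce, then broadcast down the same tree)
exactly 2(p−1).

### Schedule compilation (pre-processing)

Each leaf push is assigned to the element's owner; each internal node to the
lowest common ancestor, in the communication tree, of the owners of the
leaves below it — computed bottom-up as `lca(pe(left), pe(right))`, which
equals the LCA of the whole owner set. A value produced on one PE and
consumed on an ancestor is routed hop-by-hop up the communication tree; every
intermediate PE records a `push_recv` at the producing node's post-order
position and, not consuming the value, leaves it on its stack — so the
residual stack (bottom to top) of every non-root PE is exactly its outgoing
message payload, ordered by post-order of the producing nodes. Within one
PE, ordering all ops by global post-order position makes the local stack
discipline correct: a containment argument (each node's PE is a
communication-tree ancestor-or-equal of its children's PEs) guarantees that
the two values on top of the stack at a `reduce` are precisely the node's
children. The compiled result is pure data (JSON-serializable) and is
validated by symbolic replay in the test suite.

PEs owning no elements still occupy their communication-tree position, may
purely forward, and send an (empty) message, keeping the manifest uniform at
one message per edge. The reduce result materializes at comm-tree root PE 0;
an ownership map whose LCA is deeper forwards the root value up.

### Engine

The simulated engine steps PEs round-robin; a PE blocks on `push_recv` until
the sending PE has completed its program (messages are delivered whole, one
per edge, consumed FIFO). Scheduling order cannot influence the result —
only message availability gates progress — and a test executes two opposite
PE interleavings and compares bit patterns. An optional real message-passing
backend would implement the same engine interface; none is shipped. Any
optimized local kernel must reproduce the fixed tree order bit-exactly; the
shipped base case is the scalar interpreter itself.

## Baselines

- `sequential_pairwise_oracle` — the ground truth: single-process post-order
  evaluation of the same balanced tree, implemented directly on intervals,
  independent of the compiler and engine.
- `sequential_fold` — strict left-to-right fold, the reference semantics of
  Gather-Bcast.
- `gather_bcast_reduce` — gather all elements at the root, fold, broadcast:
  reproducible but with a root bottleneck of p−1 messages and n received
  elements, reported in its stats.
- `baseline_nonrepro_reduce` — the conventional scheme: per-PE left fold of
  local elements, then a fold of the per-PE partials in rank order. For
  floating-point operators its association depends on p and on the ownership
  map; this is the phenomenon the package exists to remove.

## Phylogenetic demonstration

Per-site log-likelihoods are computed by Felsenstein pruning under JC69
(uniform base frequencies ¼; `P_same(t) = ¼ + ¾·e^(−4t/3)`,
`P_diff(t) = ¼ − ¼·e^(−4t/3)`, t in expected substitutions per site). The
model is deliberately minimal: the demonstrated principle is decoupling the
accumulation order from the site-to-PE assignment, not model sophistication —
GTR, rate heterogeneity, branch-length optimization and vectorized kernels
are out of scope. Implementation notes:

- child partials are combined in listed (left-to-right) order with explicit
  four-term transition sums in a fixed association, so scalar and
  column-vectorized evaluation produce identical bits;
- gaps and `N` contribute all-ones partials; any other character is an error;
- a zero-likelihood site yields −inf, which propagates (never clamped); the
  total carries a count of such sites;
- trees parsed from Newick are evaluated at the parsed top-level node as-is,
  folding over all its children; under reversible JC69 the likelihood is
  root-invariant, so no deterministic re-rooting step is needed — the parsed
  shape already fixes one evaluation order;
- sites are never deduplicated (pattern compression would change the
  accumulation order);
- the site-to-PE balancer is emulated by contiguous blocks of ⌈n/p⌉ / ⌊n/p⌋
  sites (larger blocks first). Real load balancers are more elaborate; all
  the demonstration needs is that the assignment depends on p.

In `repro` mode each per-site value sits at its global site index and the sum
runs through the reproducible engine, making the total log-likelihood bitwise
independent of p (asserted for p ∈ {1,2,3,5,8}, including configurations
with idle PEs). In `naive` mode the same ownership feeds the conventional
baseline, which is p-dependent on realistic inputs.

## Tree divergence metrics

A tree's topology is described by its non-trivial bipartitions (splits from
inner edges), canonicalized as the side not containing the lexicographically
smallest taxon. The relative Robinson-Foulds distance is
`|B₁ Δ B₂| / (|B₁| + |B₂|)` — the proportion of splits that differ — which
equals the symmetric-difference count normalized by 2(n−3) for fully resolved
binary trees. Multifurcating trees are permitted (they simply have fewer
splits); the 0/0 case (two stars) is defined as 0. The divergence report over
repeated runs flags a run set as diverging when it contains ≥ 2 distinct
topologies and treats log-likelihood gaps below 10⁻³ log units as not
significantly different; larger gaps on topologically distinct pairs are
marked as requiring an external AU test, which is deliberately not
implemented.

## Synthetic data

All inputs are generated by pure functions of their parameters and a seed,
using numpy's PCG64 (`default_rng`) project-wide; artifacts written to disk
carry a JSON sidecar with seed, regime and generator name. Value regimes:

- `uniform01` — iid U(0,1), n benign summands like per-site scores;
- `mixed_magnitude` — magnitudes over ±12 decades with random signs, so a
  running fold repeatedly absorbs values below its ulp;
- `cancellation` — shuffled pairs (+x, −x+δ) with x up to 10⁹ and relative
  perturbations δ/x ~ N(0, 10⁻⁶): the exact total is tiny while partial sums
  are huge, maximizing sensitivity to association order.

Tree/alignment fixtures use sequential random joins for the topology,
Exp(mean 0.1) branch lengths, and site-independent JC69 simulation from a
uniform root state. What the generators do *not* emulate: rate heterogeneity
across sites, indels/gap patterns, base-composition bias, and empirical
tree-search dynamics. Passing tests therefore show that the *accumulation
machinery* is bit-reproducible and order-exact on data spanning the relevant
numerical regimes — they do not quantify how often real tree searches diverge,
which requires empirical alignments and a full inference tool.

## Numerical and scale choices

- The reproducible-vs-baseline agreement check uses a maximum *absolute*
  difference below 10⁻⁶ on uniform(0,1) sums (n up to 10⁴; observed ~10⁻¹¹);
  absolute rather than relative, matching the scale of the data regime it is
  run on.
- The accuracy comparison (balanced tree vs left fold) is statistical: median
  absolute error against correctly rounded sums (`math.fsum`) over 100 seeded
  cancellation arrays; medians, because single draws can favor either order.
- The full sweep covers 200 seeded inputs × p ∈ {1,2,3,4,7,8,16} ×
  k ∈ {2,4} × three ownership schemes (8 400 configurations), with 180
  inputs at n ≤ 1000 and 20 at n = 10⁴ — sizes chosen so the whole suite
  evaluates in well under a minute on one core while still exercising
  multi-level communication trees and deep reduction trees.
- The non-reproducibility witness (cancellation, n = 64, seed 0) was found by
  evaluation and then frozen, so the baseline's p-dependence is a stable
  regression anchor rather than a lottery.

## Known limitations

- The engine is a simulation: it demonstrates ordering semantics and message
  minimality, not wall-clock performance; communication/computation overlap
  exists in the schedule structure but is not timed.
- Operators are scalar Python callables; no vectorized base case is provided.
- JC69 only; no branch-length or model optimization, no tree search.
- The AU significance test is out of scope; the divergence report only flags
  candidate pairs for external testing.
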
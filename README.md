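# reprored

Bit-reproducible distributed reduction with a fixed operation order,
demonstrated on phylogenetic likelihood accumulation.

## The problem

IEEE 754 floating-point addition is not associative: `(a + b) + c` and
`a + (b + c)` can round differently. A conventional parallel reduction first
folds each processing element's (PE's) local elements into a partial result
and then combines the partials along whatever communication pattern the
runtime picks — so the realized association, and hence the final bit pattern,
depends on the PE count and on the data distribution. In iterative heuristics
this is not cosmetic: maximum-likelihood phylogenetic tree searches compare
likelihood scores between candidate trees, and a rounding difference of one
ulp can send the search down a different path, producing topologically
different phylogenies from the same input depending only on how many cores
were used.

## The algorithm

`reprored` makes the operation order a function of the input alone:

- a **reduction tree** — a balanced binary tree over the n globally ordered
  elements `e_0 … e_{n-1}` (interval `[a,b)` splits at `a + ⌈(b−a)/2⌉`) —
  fixes the exact order of the `n−1` applications of the associative operator
  `⊕`; its shape depends only on n, never on the PE count p;
- a **k-nomial communication tree** over the p PEs (parent of PE r is r with
  its lowest nonzero base-k digit cleared; k = 2 gives the classic binomial
  tree) routes exactly the theoretical minimum of p−1 messages per reduction;
- a **pre-processing step** assigns every leaf push to the element's owner and
  every internal `⊕` to the lowest common ancestor, in the communication
  tree, of the PEs owning the operand leaves, and compiles per-PE stack
  programs (`push_local` / `push_recv` / `reduce`) plus per-edge message
  manifests. A sender's residual stack, bottom to top, is exactly the payload
  its parent expects.

Executing the programs on the deterministic simulated engine yields, for any
associative operator (not just summation), a result bit-identical to the
single-process post-order evaluation of the reduction tree — for every p,
degree and ownership map. As a bonus, balanced pairwise evaluation also has a
smaller rounding error than a left-to-right fold.

The phylogenetic demonstrator computes per-site log-likelihoods of an
alignment on a tree under the Jukes-Cantor (JC69) model with Felsenstein
pruning, assigns sites to PEs with a p-dependent contiguous balancer, but
accumulates the per-site values in the fixed global site order of the
alignment — the total log-likelihood is bitwise independent of p, while the
conventional per-PE accumulation (`naive` mode) is not. Robinson-Foulds
utilities (`relative_rf`, `classify_divergence`) quantify the topological
divergence that non-reproducible accumulation can cause between repeated
runs.

## Worked example

The conventional reduction, run on a cancellation-heavy array of 64 values,
gives a different bit pattern for almost every PE count:

```
$ reprored reduce --gen cancellation:64 --seed 0 --engine baseline --p 1,2,4,8
p=1    -256.37159811516176  hex=-0x1.005f210dd7e00p+8  [non-reproducible per-PE fold]
p=2    -256.3715980350971   hex=-0x1.005f210c80000p+8  [non-reproducible per-PE fold]
p=4    -256.37159814313054  hex=-0x1.005f210e50000p+8  [non-reproducible per-PE fold]
p=8    -256.3715981201967   hex=-0x1.005f210ded800p+8  [non-reproducible per-PE fold]
VERDICT: NOT REPRODUCIBLE
```

The four printed sums differ from the eighth decimal digit on — the same
input, folded in four different association orders. The reproducible engine
returns one bit pattern for every PE count, with exactly p−1 messages and
n−1 = 63 operator applications each time:

```
$ reprored reduce --gen cancellation:64 --seed 0 --p 1,2,4,8
p=1    -256.3715981245041  hex=-0x1.005f210e00000p+8  [messages=0 ops=63]
p=2    -256.3715981245041  hex=-0x1.005f210e00000p+8  [messages=1 ops=63]
p=4    -256.3715981245041  hex=-0x1.005f210e00000p+8  [messages=3 ops=63]
p=8    -256.3715981245041  hex=-0x1.005f210e00000p+8  [messages=7 ops=63]
VERDICT: REPRODUCIBLE
```

Results are printed in hex-float because decimal printing can mask bit
differences. The same check for the phylogenetic total log-likelihood:

```
$ reprored phylo --gen-taxa 8 --gen-sites 500 --seed 11 --p 1,2,3,5,8
...
VERDICT: REPRODUCIBLE
$ reprored phylo --gen-taxa 8 --gen-sites 500 --seed 11 --mode naive --p 1,4
...
VERDICT: NOT REPRODUCIBLE
```

Other subcommands: `reprored schedule` dumps the compiled per-PE programs and
message manifests for inspection, `reprored rfdist a.nwk b.nwk` prints the
relative Robinson-Foulds distance, and `reprored gen` writes deterministic
hex-float / FASTA / Newick fixtures with provenance sidecars.

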
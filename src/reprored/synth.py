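"""Deterministic generators for all test inputs.

Value arrays in three regimes that probe rounding-order sensitivity at desk
scale, ownership maps stressing different data distributions, and small
alignment/tree fixtures simulated under JC69.  Every generator is a pure
function of its parameters and seed; the project-wide pseudo-random generator
is numpy's PCG64 (``numpy.random.default_rng``), recorded in the metadata
sidecar of every artifact written to disk so fixtures stay portable.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

from .schedule import OwnershipMap
from .phylo import MSA, PhyloTree, TreeNode, partition_sites, write_fasta, write_newick

__all__ = [
    "REGIMES",
    "OWNERSHIP_SCHEMES",
    "gen_values",
    "gen_ownership",
    "gen_msa_tree",
    "write_values_with_metadata",
]

PRNG_NAME = "numpy PCG64 (default_rng)"

REGIMES = ("uniform01", "mixed_magnitude", "cancellation")
OWNERSHIP_SCHEMES = ("contiguous", "round_robin", "random")


def gen_values(
    n: int,
    regime: str,
    seed: int,
    magnitude_span: float = 12.0,
    perturbation_scale: float = 1e-6,
) -> np.ndarray:
    """Generate ``n`` float64 values in a named regime.

    ``uniform01``
        iid U(0, 1) — benign, realistic per-site-score-like data.
    ``mixed_magnitude``
        magnitudes spread over ``±magnitude_span`` decades with random signs,
        so the fold's running sum repeatedly absorbs values far below its own
        ulp.
    ``cancellation``
        pairs (+x, -x + delta) with |delta| ~ perturbation_scale · x, shuffled;
        the mathematically exact sum is near the perturbation total while
        intermediate sums are large — maximal exposure of association order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; available: {REGIMES}")
    rng = np.random.default_rng(seed)
    if regime == "uniform01":
        return rng.random(n)
    if regime == "mixed_magnitude":
        mant = rng.uniform(1.0, 10.0, n)
        expo = rng.uniform(-magnitude_span, magnitude_span, n)
        sign = rng.choice([-1.0, 1.0], n)
        return sign * mant * np.power(10.0, expo)
    # cancellation
    m = n // 2
    out = np.empty(n)
    if m > 0:
        x = rng.uniform(1.0, 10.0, m) * np.power(10.0, rng.uniform(0.0, 8.0, m))
        delta = rng.normal(0.0, perturbation_scale, m) * x
        out[:m] = x
        out[m : 2 * m] = -x + delta
    if n % 2:
        out[-1] = rng.normal(0.0, 1.0)
    rng.shuffle(out)
    return out


def gen_ownership(n: int, p: int, scheme: str, seed: int = 0) -> OwnershipMap:
    """Total element→PE map: contiguous blocks, round robin, or seeded random."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    if scheme == "contiguous":
        return partition_sites(n, p)
    if scheme == "round_robin":
        return OwnershipMap.from_list([i % p for i in range(n)], p)
    if scheme == "random":
        rng = np.random.default_rng(seed)
        return OwnershipMap.from_list(rng.integers(0, p, n).tolist(), p)
    raise ValueError(f"unknown ownership scheme {scheme!r}; available: {OWNERSHIP_SCHEMES}")


def gen_msa_tree(
    n_taxa: int,
    n_sites: int,
    seed: int,
    mean_branch_length: float = 0.1,
):
    """Random binary tree plus an alignment simulated on it under JC69.

    The topology arises from sequential random joins of subtree roots; branch
    lengths are Exp(mean ``mean_branch_length``) substitutions/site.  Each
    site evolves independently from a uniform root state down the tree using
    the JC69 transition probabilities.  Returns ``(PhyloTree, MSA)``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if n_sites < 1:
        raise ValueError("need at least 1 site")
    rng = np.random.default_rng(seed)

    nodes = [TreeNode(label=f"T{i}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(mean_branch_length))
        right.length = float(rng.exponential(mean_branch_length))
        nodes.append(TreeNode(children=[left, right]))
    tree = PhyloTree(root=nodes[0])

    bases = np.array(list("ACGT"))
    states = {}  # node -> state index array over sites

    def simulate(node: TreeNode, parent_states: np.ndarray | None):
        if parent_states is None:
            st = rng.integers(0, 4, n_sites)
        else:
            e = np.exp(-4.0 * node.length / 3.0)
            stay = rng.random(n_sites) < (0.25 + 0.75 * e)
            st = np.where(stay, parent_states, (parent_states + rng.integers(1, 4, n_sites)) % 4)
        states[id(node)] = st
        for c in node.children:
            simulate(c, st)

    simulate(tree.root, None)
    labels = []
    seqs = []
    for node in tree.root.postorder():
        if node.is_leaf():
            labels.append(node.label)
            seqs.append("".join(bases[states[id(node)]]))
    msa = MSA(labels=tuple(labels), sequences=tuple(seqs))
    return tree, msa


def write_values_with_metadata(path, values: Sequence, seed: int, regime: str) -> None:
    """Write a hex-float value file plus a JSON sidecar recording provenance."""
    from . import __version__
    from .engine import write_values_file

    write_values_file(path, values)
    meta = {
        "n": len(values),
        "seed": seed,
        "regime": regime,
        "prng": PRNG_NAME,
        "package_version": __version__,
        "format": "C99 hex-float, one per line",
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def write_msa_tree(prefix, tree: PhyloTree, msa: MSA, seed: int) -> None:
    """Write FASTA + Newick fixture files with a provenance sidecar."""
    from . import __version__

    write_fasta(str(prefix) + ".fasta", msa)
    write_newick(tree, str(prefix) + ".nwk")
    meta = {
        "n_taxa": msa.n_taxa,
        "n_sites": msa.n_sites,
        "seed": seed,
        "model": "JC69",
        "prng": PRNG_NAME,
        "package_version": __version__,
    }
    with open(str(prefix) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
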
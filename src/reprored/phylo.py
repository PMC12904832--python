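"""Toy pruning-algorithm likelihood demonstrating order-decoupled accumulation.

Per-site log-likelihoods of an alignment on a tree are independent across
sites, so they can be computed under any site-to-PE assignment.  What makes
the *total* score PE-count dependent in conventional parallel inference codes
is the accumulation: each PE folds its local sites into a partial, and the
partials are combined in a communication-pattern-dependent order.  This module
computes per-site values under a p-dependent contiguous-block assignment but
accumulates them in the fixed global site order of the input alignment via the
reproducible reduction engine — yielding a total that is bit-identical for
every PE count.  A ``naive`` mode uses the conventional per-PE fold instead,
exhibiting the usual p-dependence.

The substitution model is deliberately minimal — Jukes-Cantor (JC69): uniform
base frequencies 1/4 and a single rate, with transition probabilities
P_same(t) = 1/4 + 3/4 e^(-4t/3) and P_diff(t) = 1/4 - 1/4 e^(-4t/3) for a
branch of length t expected substitutions per site.  The point demonstrated is
accumulation-order decoupling, not model sophistication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .schedule import OwnershipMap, build_comm_tree, build_reduction_tree, compile_schedule
from .engine import (
    baseline_nonrepro_reduce,
    execute_reduce,
    make_operator,
)

__all__ = [
    "MSA",
    "TreeNode",
    "PhyloTree",
    "read_alignment",
    "parse_newick",
    "read_newick",
    "write_newick",
    "site_log_likelihood",
    "site_loglik_vector",
    "partition_sites",
    "tree_loglik",
    "TreeLoglik",
    "jc69_transition_matrix",
]

_ALPHABET = set("ACGT-N")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MSA:
    """Aligned sequences over {A,C,G,T,-,N}; site order is the file order."""

    labels: tuple
    sequences: tuple

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("alignment needs at least 2 taxa")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("unequal sequence lengths")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def column(self, site: int) -> dict:
        return {lab: seq[site] for lab, seq in zip(self.labels, self.sequences)}


def read_alignment(path, format: str = "fasta") -> MSA:
    """Read a FASTA or relaxed PHYLIP alignment, preserving file order.

    Lowercase bases are accepted and uppercased.
    """
    from Bio import AlignIO, SeqIO

    if format == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ValueError(f"{path}: empty alignment file")
        labels = tuple(r.id for r in records)
        seqs = tuple(str(r.seq).upper() for r in records)
    elif format == "phylip":
        try:
            aln = AlignIO.read(path, "phylip-relaxed")
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
        labels = tuple(r.id for r in aln)
        seqs = tuple(str(r.seq).upper() for r in aln)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return MSA(labels=labels, sequences=seqs)


def write_fasta(path, msa: MSA) -> None:
    with open(path, "w") as fh:
        for lab, seq in zip(msa.labels, msa.sequences):
            fh.write(f">{lab}\n{seq}\n")


class TreeNode:
    """Tree node with ordered children and a branch length to its parent."""

    __slots__ = ("label", "length", "children")

    def __init__(self, label=None, length=0.0, children=None):
        self.label = label
        self.length = float(length)
        self.children = list(children) if children else []

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self


@dataclass
class PhyloTree:
    """Rooted tree with leaf labels and branch lengths (expected subst./site).

    Unrooted Newick strings (a top-level multifurcation) are kept as parsed:
    the likelihood is evaluated at the parsed top-level node, folding over its
    children in file order.  Under the reversible JC69 model the likelihood is
    invariant to root placement, so no re-rooting is performed.
    """

    root: TreeNode

    @property
    def leaf_labels(self) -> tuple:
        return tuple(n.label for n in self.root.postorder() if n.is_leaf())

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def n_internal_edges(self) -> int:
        cnt = 0
        for node in self.root.postorder():
            if node is not self.root and not node.is_leaf():
                cnt += 1
        return cnt


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; missing branch lengths default to 0 (warns)."""
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from None

    missing = [0]

    def convert(dnode) -> TreeNode:
        if dnode.edge.length is None:
            missing[0] += 1
            length = 0.0
        else:
            length = float(dnode.edge.length)
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(label=label, length=length)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    if missing[0] > 1:  # the root edge legitimately has no length
        warnings.warn(
            f"{missing[0] - 1} branch length(s) missing; defaulting to 0",
            stacklevel=2,
        )
    tree = PhyloTree(root=root)
    labels = tree.leaf_labels
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels in tree")
    return tree


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def _newick_str(node: TreeNode, top: bool) -> str:
    if node.is_leaf():
        core = node.label or ""
    else:
        core = "(" + ",".join(_newick_str(c, False) for c in node.children) + ")"
        if node.label:
            core += node.label
    if top:
        return core
    return f"{core}:{node.length:.10g}"


def write_newick(tree: PhyloTree, path=None) -> str:
    text = _newick_str(tree.root, top=True) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def jc69_transition_matrix(t: float) -> np.ndarray:
    """4x4 JC69 transition probability matrix for branch length ``t``."""
    if t < 0:
        raise ValueError("negative branch length")
    e = np.exp(-4.0 * t / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


def _leaf_partials(seq: str, sites: np.ndarray) -> np.ndarray:
    """(4, n_sites) conditional likelihoods for a leaf; gaps/N are all-ones."""
    out = np.zeros((4, len(sites)))
    for j, site in enumerate(sites):
        ch = seq[site]
        if ch in _BASE_INDEX:
            out[_BASE_INDEX[ch], j] = 1.0
        elif ch in ("-", "N"):
            out[:, j] = 1.0
        else:
            raise ValueError(f"non-IUPAC character {ch!r} at site {site}")
    return out


def _partials(node: TreeNode, msa: MSA, seq_of: dict, sites: np.ndarray) -> np.ndarray:
    if node.is_leaf():
        if node.label not in seq_of:
            raise ValueError(f"tree leaf {node.label!r} not found in alignment")
        return _leaf_partials(seq_of[node.label], sites)
    acc = None
    for child in node.children:  # fixed order: as listed (left then right)
        cp = _partials(child, msa, seq_of, sites)
        P = jc69_transition_matrix(child.length)
        # explicit 4-term sums in fixed order: no BLAS reassociation
        contrib = np.empty_like(cp)
        for i in range(4):
            contrib[i] = ((P[i, 0] * cp[0] + P[i, 1] * cp[1]) + P[i, 2] * cp[2]) + P[i, 3] * cp[3]
        acc = contrib if acc is None else acc * contrib
    return acc


def site_loglik_vector(tree: PhyloTree, msa: MSA, sites=None) -> np.ndarray:
    """Natural-log per-site likelihoods under JC69, in global site order.

    Felsenstein pruning with a fixed child-evaluation order; a site whose
    likelihood is exactly 0 yields -inf (propagated, never clamped).
    """
    tree_leaves = set(tree.leaf_labels)
    msa_leaves = set(msa.labels)
    if tree_leaves != msa_leaves:
        raise ValueError(
            f"tree/alignment taxon mismatch: only in tree {sorted(tree_leaves - msa_leaves)}, "
            f"only in alignment {sorted(msa_leaves - tree_leaves)}"
        )
    if sites is None:
        sites = np.arange(msa.n_sites)
    else:
        sites = np.asarray(sites)
    seq_of = dict(zip(msa.labels, msa.sequences))
    part = _partials(tree.root, msa, seq_of, sites)
    lik = 0.25 * (((part[0] + part[1]) + part[2]) + part[3])
    with np.errstate(divide="ignore"):
        return np.log(lik)


def site_log_likelihood(tree: PhyloTree, msa: MSA, site: int) -> float:
    """Log-likelihood of one alignment column (see :func:`site_loglik_vector`)."""
    if not (0 <= site < msa.n_sites):
        raise ValueError(f"site {site} out of range [0, {msa.n_sites})")
    return float(site_loglik_vector(tree, msa, sites=[site])[0])


def partition_sites(n_sites: int, p: int) -> OwnershipMap:
    """Contiguous block assignment emulating a p-dependent load balancer.

    Earlier PEs get blocks of size ceil(n/p), later ones floor(n/p); PEs past
    the site count own nothing.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    q, r = divmod(n_sites, p)
    owners = []
    for pe in range(p):
        owners.extend([pe] * (q + 1 if pe < r else q))
    return OwnershipMap.from_list(owners, p)


class TreeLoglik(NamedTuple):
    total: float
    n_neg_inf_sites: int
    mode: str
    p: int


def tree_loglik(
    tree: PhyloTree,
    msa: MSA,
    p: int,
    mode: str = "repro",
    degree: int = 2,
) -> TreeLoglik:
    """Total log-likelihood accumulated over per-site values on p simulated PEs.

    ``repro``: each per-site value sits at its global site index and the sum
    runs through the reproducible fixed-tree reduction — the total is bitwise
    independent of ``p``.  ``naive``: conventional per-PE fold over the same
    contiguous ownership, then fold of partials in rank order — p-dependent in
    general.
    """
    if mode not in ("repro", "naive"):
        raise ValueError(f"unknown mode {mode!r}")
    vec = site_loglik_vector(tree, msa)
    n_inf = int(np.isinf(vec).sum())
    values = vec.tolist()
    own = partition_sites(msa.n_sites, p)
    fadd = make_operator("float-add")
    if mode == "repro":
        rt = build_reduction_tree(msa.n_sites)
        ct = build_comm_tree(p, degree)
        sched = compile_schedule(rt, ct, own)
        total, _ = execute_reduce(sched, values, fadd)
    else:
        total = baseline_nonrepro_reduce(values, own, p, fadd)
    return TreeLoglik(total=float(total), n_neg_inf_sites=n_inf, mode=mode, p=p)
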
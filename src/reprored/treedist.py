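"""Topological divergence between trees from repeated runs.

The relative Robinson-Foulds (RF) distance is the proportion of non-trivial
bipartitions (splits induced by inner edges) that differ between two trees on
the same taxa: |B1 Δ B2| / (|B1| + |B2|), which equals the usual symmetric
difference normalized by 2(n-3) for fully resolved binary trees.
Multifurcating trees (fewer splits) are permitted; 0/0 is defined as 0.

``classify_divergence`` applies the screening used for repeated inference
runs that differ only in their parallelization setting: a run set *diverges*
if it contains at least two topologically distinct trees, and pairs whose
log-likelihoods differ by less than a threshold (default 1e-3 log units) are
treated as not significantly different; larger gaps are flagged as candidates
for an external significance test (AU test), which is not implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .phylo import PhyloTree

__all__ = [
    "BipartitionSet",
    "RunRecord",
    "bipartitions",
    "relative_rf",
    "classify_divergence",
]


@dataclass(frozen=True)
class BipartitionSet:
    """Non-trivial splits of a taxon set, canonicalized.

    Each split is stored as the frozen side *not* containing the reference
    taxon (the lexicographically smallest label), so each inner edge maps to
    exactly one canonical set regardless of orientation or root placement.
    """

    taxa: frozenset
    splits: frozenset

    def __len__(self) -> int:
        return len(self.splits)


def bipartitions(tree: PhyloTree) -> BipartitionSet:
    """One canonical split per inner edge of the tree.

    Splits of size < 2 or > n-2 (pendant and root edges) are trivial and
    excluded.  Raises on duplicate taxa.
    """
    labels = [n.label for n in tree.root.postorder() if n.is_leaf()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxa in tree")
    taxa = frozenset(labels)
    n = len(taxa)
    ref = min(taxa)
    splits = set()

    def clade(node) -> frozenset:
        if node.is_leaf():
            return frozenset((node.label,))
        below = frozenset().union(*(clade(c) for c in node.children))
        if node is not tree.root:
            side = taxa - below if ref in below else below
            if 2 <= len(side) <= n - 2:
                splits.add(side)
        return below

    clade(tree.root)
    return BipartitionSet(taxa=taxa, splits=frozenset(splits))


def relative_rf(t1: PhyloTree, t2: PhyloTree) -> float:
    """Relative Robinson-Foulds distance in [0, 1] between two trees.

    |B1 Δ B2| / (|B1| + |B2|); 0 when both trees have no non-trivial splits.
    """
    b1 = bipartitions(t1)
    b2 = bipartitions(t2)
    if b1.taxa != b2.taxa:
        raise ValueError(
            f"taxon sets differ: only in first {sorted(b1.taxa - b2.taxa)}, "
            f"only in second {sorted(b2.taxa - b1.taxa)}"
        )
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return len(b1.splits ^ b2.splits) / denom


@dataclass(frozen=True)
class RunRecord:
    """One inference run: a label (its parallelization setting), the resulting
    tree, and its final log-likelihood."""

    label: str
    tree: PhyloTree
    loglik: float


def classify_divergence(records, ll_threshold: float = 1e-3) -> dict:
    """Divergence report over repeated runs of the same analysis.

    Returns a dict with the pairwise relative RF matrix, the number of
    distinct topologies, a ``diverging`` flag (>= 2 distinct topologies), the
    maximum pairwise log-likelihood difference, and — when that gap reaches
    ``ll_threshold`` — the list of pairs that require an external AU test.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 run records")
    m = len(records)
    rf = [[0.0] * m for _ in range(m)]
    for i in range(m):
        for j in range(i + 1, m):
            d = relative_rf(records[i].tree, records[j].tree)
            rf[i][j] = rf[j][i] = d

    # group identical topologies (rf == 0 is an equivalence on split sets)
    topo_id = [-1] * m
    n_topo = 0
    for i in range(m):
        if topo_id[i] >= 0:
            continue
        topo_id[i] = n_topo
        for j in range(i + 1, m):
            if topo_id[j] < 0 and rf[i][j] == 0.0:
                topo_id[j] = n_topo
        n_topo += 1

    max_ll_diff = 0.0
    flagged = []
    for i in range(m):
        for j in range(i + 1, m):
            gap = abs(records[i].loglik - records[j].loglik)
            max_ll_diff = max(max_ll_diff, gap)
            if rf[i][j] > 0.0 and gap >= ll_threshold:
                flagged.append((records[i].label, records[j].label))

    return {
        "n_runs": m,
        "labels": [r.label for r in records],
        "rf_matrix": rf,
        "topology_id": topo_id,
        "n_distinct_topologies": n_topo,
        "diverging": n_topo >= 2,
        "max_loglik_diff": max_ll_diff,
        "exceeds_ll_threshold": max_ll_diff >= ll_threshold,
        "ll_threshold": ll_threshold,
        "requires_external_au_test": flagged,
    }


def format_report(report: dict) -> str:
    """Human-readable table form of a divergence report."""
    lines = [
        f"runs: {report['n_runs']}  distinct topologies: {report['n_distinct_topologies']}"
        f"  diverging: {report['diverging']}",
        f"max |delta lnL|: {report['max_loglik_diff']:.6g}"
        f"  (threshold {report['ll_threshold']:g})",
    ]
    labels = report["labels"]
    width = max(len(l) for l in labels) + 2
    lines.append(" " * width + " ".join(f"{l:>8}" for l in labels))
    for lab, row in zip(labels, report["rf_matrix"]):
        lines.append(f"{lab:<{width}}" + " ".join(f"{v:8.4f}" for v in row))
    if report["requires_external_au_test"]:
        for a, b in report["requires_external_au_test"]:
            lines.append(f"pair ({a}, {b}): requires external AU test")
    else:
        lines.append("no pairs require external AU testing")
    return "\n".join(lines)
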
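"""Fixed reduction trees, k-nomial communication trees, and per-PE schedules.

The central idea: the *order* in which an associative operator is applied over
n globally ordered elements is dictated by a binary reduction tree that depends
only on n — never on the number of processing elements (PEs) or on which PE
holds which element.  Communication between PEs is routed along a separate
k-nomial tree over the p PEs.  A pre-processing step assigns every reduction
operation to the lowest common ancestor (in the communication tree) of the PEs
owning the operand leaves, and compiles per-PE stack-machine programs plus
message manifests.  Executing those programs (see :mod:`reprored.engine`)
realizes the exact post-order evaluation of the reduction tree on any PE
count, which is what makes the result bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

__all__ = [
    "ReductionTree",
    "CommTree",
    "OwnershipMap",
    "Schedule",
    "PUSH_LOCAL",
    "PUSH_RECV",
    "REDUCE",
    "build_reduction_tree",
    "build_comm_tree",
    "comm_lca",
    "compile_schedule",
    "schedule_stats",
    "validate_schedule",
]

# opcodes (stack machine realizing a post-order traversal)
PUSH_LOCAL = "push_local"  # arg: global element index  (addValue)
PUSH_RECV = "push_recv"    # arg: sending child PE
REDUCE = "reduce"          # arg: internal node id       (reduceTwoValues)


@dataclass(frozen=True)
class ReductionTree:
    """Balanced binary tree over ``n_leaves`` globally ordered elements.

    Nodes are identified by their global post-order position (0-based); a tree
    over n leaves has 2n-1 nodes, node ``2n-2`` being the root.  Leaves carry
    the element index they represent; internal nodes carry their two children
    and the half-open leaf interval ``[lo, hi)`` they cover.
    """

    n_leaves: int
    left: tuple  # child node id, or None for leaves
    right: tuple
    leaf: tuple  # element index, or None for internal nodes
    lo: tuple
    hi: tuple
    parent: tuple  # parent node id, None for root

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_leaf(self, node: int) -> bool:
        return self.leaf[node] is not None

    def internal_nodes(self) -> list:
        """Internal node ids in post-order (the r_j indexing)."""
        return [v for v in range(self.n_nodes) if self.leaf[v] is None]


def _split(lo: int, hi: int) -> int:
    """Split point of interval [lo, hi): left part gets ceil(len/2) elements."""
    return lo + (hi - lo + 1) // 2


@lru_cache(maxsize=64)
def build_reduction_tree(n: int) -> ReductionTree:
    """Build the fixed balanced reduction tree over ``n`` elements.

    An interval ``[a, b)`` with two or more elements splits at
    ``a + ceil((b-a)/2)``; singleton intervals are leaves.  The shape is a
    function of ``n`` alone.  ``n = 0`` is rejected: no identity element of
    the reduction operator is assumed.
    """
    if n < 1:
        raise ValueError("empty reduction: n must be >= 1")
    left: list = []
    right: list = []
    leaf: list = []
    lo: list = []
    hi: list = []

    def rec(a: int, b: int) -> int:
        if b - a == 1:
            left.append(None)
            right.append(None)
            leaf.append(a)
        else:
            m = _split(a, b)
            l_id = rec(a, m)
            r_id = rec(m, b)
            left.append(l_id)
            right.append(r_id)
            leaf.append(None)
        lo.append(a)
        hi.append(b)
        return len(leaf) - 1

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n.bit_length() + 100))
    try:
        rec(0, n)
    finally:
        sys.setrecursionlimit(old)

    parent: list = [None] * len(leaf)
    for v in range(len(leaf)):
        if leaf[v] is None:
            parent[left[v]] = v
            parent[right[v]] = v
    return ReductionTree(
        n_leaves=n,
        left=tuple(left),
        right=tuple(right),
        leaf=tuple(leaf),
        lo=tuple(lo),
        hi=tuple(hi),
        parent=tuple(parent),
    )


@dataclass(frozen=True)
class CommTree:
    """k-nomial tree over ``p`` PEs rooted at PE 0.

    The parent of PE r > 0 is r with its lowest nonzero base-k digit cleared;
    for k = 2 this is the classic binomial tree.  Exactly p-1 edges; the tree
    depends only on (p, k).
    """

    p: int
    k: int
    parent: tuple  # parent PE, None for root
    children: tuple  # tuple of tuples, ascending order
    depth: tuple  # number of nonzero base-k digits

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff PE ``a`` is an ancestor of or equal to PE ``b``."""
        while b is not None:
            if a == b:
                return True
            b = self.parent[b]
        return False


@lru_cache(maxsize=256)
def build_comm_tree(p: int, degree: int = 2) -> CommTree:
    if p < 1:
        raise ValueError("p must be >= 1")
    if degree < 2:
        raise ValueError("k-nomial degree must be >= 2")
    k = degree
    parent: list = [None] * p
    depth = [0] * p
    children: list = [[] for _ in range(p)]
    for r in range(1, p):
        x, place = r, 1
        while x % k == 0:
            x //= k
            place *= k
        par = r - (x % k) * place
        parent[r] = par
        children[par].append(r)
        depth[r] = depth[par] + 1
    return CommTree(
        p=p,
        k=k,
        parent=tuple(parent),
        children=tuple(tuple(sorted(c)) for c in children),
        depth=tuple(depth),
    )


def _lca2(ct: CommTree, a: int, b: int) -> int:
    while a != b:
        if ct.depth[a] >= ct.depth[b]:
            a = ct.parent[a]
        else:
            b = ct.parent[b]
    return a


def comm_lca(tree: CommTree, pes: Iterable) -> int:
    """Deepest PE that is an ancestor of, or equal to, every PE in ``pes``."""
    it = list(pes)
    if not it:
        raise ValueError("comm_lca of an empty PE set")
    for r in it:
        if not (0 <= r < tree.p):
            raise ValueError(f"PE {r} out of range [0, {tree.p})")
    acc = it[0]
    for r in it[1:]:
        acc = _lca2(tree, acc, r)
    return acc


@dataclass(frozen=True)
class OwnershipMap:
    """Total map from global element index to owning PE.

    The map may be arbitrary (non-contiguous); PEs may own nothing.  This
    emulates load-balancer-dependent assignment of elements (e.g. alignment
    sites) to PEs.
    """

    owners: tuple
    p: int

    def __post_init__(self):
        for i, r in enumerate(self.owners):
            if not (0 <= r < self.p):
                raise ValueError(f"element {i} owned by PE {r} outside [0, {self.p})")

    @property
    def n(self) -> int:
        return len(self.owners)

    @staticmethod
    def from_list(owners: Sequence, p: int) -> "OwnershipMap":
        return OwnershipMap(owners=tuple(int(r) for r in owners), p=int(p))


@dataclass(frozen=True)
class Schedule:
    """Compiled per-PE programs and message manifests for one data distribution.

    ``programs[r]`` is the ordered op list of PE r as ``(opcode, arg)`` pairs,
    ordered by the global post-order position of the corresponding reduction
    tree node.  ``manifests[(child, parent)]`` lists, bottom of stack first,
    the reduction-tree node ids whose values the (single) message on that
    communication edge carries; every comm-tree edge appears, possibly with an
    empty payload.
    """

    n: int
    p: int
    degree: int
    owners: tuple
    programs: tuple
    manifests: dict = field(hash=False)
    node_pe: tuple  # PE where each reduction-tree node's value is produced

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "p": self.p,
                "degree": self.degree,
                "owners": list(self.owners),
                "programs": [[list(op) for op in prog] for prog in self.programs],
                "manifests": {
                    f"{c}->{q}": list(v) for (c, q), v in sorted(self.manifests.items())
                },
            },
            indent=1,
        )

    @staticmethod
    def from_json(text: str) -> "Schedule":
        d = json.loads(text)
        manifests = {}
        for key, v in d["manifests"].items():
            c, q = key.split("->")
            manifests[(int(c), int(q))] = tuple(v)
        sched = Schedule(
            n=d["n"],
            p=d["p"],
            degree=d["degree"],
            owners=tuple(d["owners"]),
            programs=tuple(tuple((op, arg) for op, arg in prog) for prog in d["programs"]),
            manifests=manifests,
            node_pe=(),
        )
        return sched


def compile_schedule(rt: ReductionTree, ct: CommTree, own: OwnershipMap) -> Schedule:
    """Assign every reduction operation to a PE and compile executable programs.

    Each leaf's push is assigned to the owner of the element; each internal
    node's reduce is assigned to the communication-tree LCA of the PEs owning
    the leaves beneath it.  A value produced on one PE and consumed on another
    is routed hop-by-hop up the communication tree; on every receiving PE it
    appears as a PUSH_RECV at the producing node's post-order position, so the
    sender's residual stack (bottom to top) is exactly its outgoing payload.
    """
    if own.n != rt.n_leaves:
        raise ValueError(
            f"ownership covers {own.n} elements, reduction tree has {rt.n_leaves}"
        )
    if own.p != ct.p:
        raise ValueError(f"ownership PE count {own.p} != comm tree PE count {ct.p}")

    n_nodes = rt.n_nodes
    node_pe = [0] * n_nodes
    for v in range(n_nodes):
        if rt.leaf[v] is not None:
            node_pe[v] = own.owners[rt.leaf[v]]
        else:
            node_pe[v] = _lca2(ct, node_pe[rt.left[v]], node_pe[rt.right[v]])

    programs: list = [[] for _ in range(ct.p)]
    manifests = {}
    for r in range(1, ct.p):
        manifests[(r, ct.parent[r])] = []

    for v in range(n_nodes):
        pe = node_pe[v]
        if rt.leaf[v] is not None:
            programs[pe].append((PUSH_LOCAL, rt.leaf[v]))
        else:
            programs[pe].append((REDUCE, v))
        # route this node's value towards its consumer
        par_node = rt.parent[v]
        consumer = node_pe[par_node] if par_node is not None else 0  # result at root PE
        cur = pe
        while cur != consumer:
            up = ct.parent[cur]
            manifests[(cur, up)].append(v)
            programs[up].append((PUSH_RECV, cur))
            cur = up

    return Schedule(
        n=rt.n_leaves,
        p=ct.p,
        degree=ct.k,
        owners=own.owners,
        programs=tuple(tuple(prog) for prog in programs),
        manifests={e: tuple(v) for e, v in manifests.items()},
        node_pe=tuple(node_pe),
    )


def schedule_stats(s: Schedule) -> dict:
    """Exact message, payload, op-count and stack-depth summary of a schedule."""
    per_pe_ops = []
    max_depth = []
    for prog in s.programs:
        counts = {PUSH_LOCAL: 0, PUSH_RECV: 0, REDUCE: 0}
        depth = peak = 0
        for op, _ in prog:
            counts[op] += 1
            depth += 1 if op != REDUCE else -1
            peak = max(peak, depth)
        per_pe_ops.append(counts)
        max_depth.append(peak)
    payload_lengths = {e: len(v) for e, v in s.manifests.items()}
    return {
        "messages": len(s.manifests),
        "payload_lengths": payload_lengths,
        "values_transmitted": sum(payload_lengths.values()),
        "per_pe_ops": per_pe_ops,
        "max_stack_depth": max_depth,
        "total_reduce_ops": sum(c[REDUCE] for c in per_pe_ops),
        "total_push_local": sum(c[PUSH_LOCAL] for c in per_pe_ops),
    }


def validate_schedule(s: Schedule, rt: ReductionTree, ct: CommTree) -> None:
    """Symbolically replay every PE's program against the manifests.

    Raises AssertionError if any PE pops an empty stack, a REDUCE pops
    operands that are not exactly the node's (right, left) children, a
    received value goes unconsumed and unforwarded, or a residual stack does
    not match the outgoing payload.
    """
    cursors = {e: 0 for e in s.manifests}
    for pe, prog in enumerate(s.programs):
        stack: list = []
        for op, arg in prog:
            if op == PUSH_LOCAL:
                # leaf node id: the leaf whose element index is arg
                stack.append(_leaf_node_id(rt, arg))
            elif op == PUSH_RECV:
                edge = (arg, pe)
                payload = s.manifests[edge]
                assert cursors[edge] < len(payload), f"PE {pe}: recv beyond payload on {edge}"
                stack.append(payload[cursors[edge]])
                cursors[edge] += 1
            else:  # REDUCE
                assert len(stack) >= 2, f"PE {pe}: REDUCE {arg} pops an empty stack"
                b = stack.pop()
                a = stack.pop()
                assert a == rt.left[arg] and b == rt.right[arg], (
                    f"PE {pe}: REDUCE {arg} got operands ({a}, {b}), "
                    f"expected ({rt.left[arg]}, {rt.right[arg]})"
                )
                stack.append(arg)
        if pe == 0:
            assert stack == [rt.root], f"root PE residual stack {stack} != [{rt.root}]"
        else:
            out = s.manifests[(pe, ct.parent[pe])]
            assert tuple(stack) == out, (
                f"PE {pe}: residual stack {stack} != outgoing payload {list(out)}"
            )
    for edge, cur in cursors.items():
        assert cur == len(s.manifests[edge]), f"unconsumed values on edge {edge}"


def _leaf_node_id(rt: ReductionTree, element: int) -> int:
    """Post-order node id of the leaf holding a given element index."""
    v = rt.root
    while rt.leaf[v] is None:
        v = rt.left[v] if element < rt.lo[rt.right[v]] else rt.right[v]
    return v
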
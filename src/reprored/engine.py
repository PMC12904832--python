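"""Deterministic simulated execution of reduction schedules, plus baselines.

The engine interprets the per-PE stack programs compiled by
:mod:`reprored.schedule` over concrete values, passing intermediate results
between simulated PEs as FIFO messages along the communication tree.  Because
every ``reduce`` op names a fixed reduction-tree node, the realized operator
application order is identical for every PE count, degree and ownership map —
the result is bit-identical to the single-process pairwise oracle.

Also provided: the strict left-to-right fold, the gather-everything-at-root
reproducible fallback, and the conventional non-reproducible baseline (local
fold per PE, then fold of per-PE partials), whose float results depend on the
PE count.

Floating-point regime: strict 64-bit IEEE 754 binary64 with round-to-nearest
ties-to-even, no fused multiply-add, no reassociation anywhere.  Any optimized
local kernel substituted for the interpreter must reproduce the fixed-tree
operation order bit-exactly; none is shipped here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .schedule import (
    PUSH_LOCAL,
    PUSH_RECV,
    REDUCE,
    CommTree,
    OwnershipMap,
    ReductionTree,
    Schedule,
    _split,
    build_comm_tree,
    build_reduction_tree,
)

__all__ = [
    "ReductionOperator",
    "EngineTrace",
    "make_operator",
    "execute_reduce",
    "execute_allreduce",
    "sequential_pairwise_oracle",
    "sequential_fold",
    "gather_bcast_reduce",
    "baseline_nonrepro_reduce",
    "float_bits",
    "read_values_file",
    "write_values_file",
]


@dataclass(frozen=True)
class ReductionOperator:
    """A named associative binary operation.

    The engine applies ``fn(a, b)`` with ``a`` the operand earlier in global
    post-order (second-popped from the stack) and ``b`` the later one; operand
    order is never swapped, so non-commutative monoids are supported.  The
    ``commutative`` flag is informational only.
    """

    name: str
    fn: Callable
    commutative: bool
    domain: str = "float64"

    def apply(self, a, b):
        return self.fn(a, b)


_REGISTRY = {
    "float-add": ReductionOperator("float-add", lambda a, b: a + b, True, "float64"),
    "float-mul": ReductionOperator("float-mul", lambda a, b: a * b, True, "float64"),
    "max": ReductionOperator("max", lambda a, b: a if a >= b else b, True, "ordered"),
    "int-add": ReductionOperator("int-add", lambda a, b: a + b, True, "int"),
    "concat": ReductionOperator("concat", lambda a, b: a + b, False, "str"),
}


def make_operator(name: str) -> ReductionOperator:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown operator {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


@dataclass
class EngineTrace:
    """Execution record of one simulated reduction: counters and message log."""

    n: int
    p: int
    op_applications: int = 0
    messages_sent: int = 0
    values_transmitted: int = 0
    per_pe_executed: list = field(default_factory=list)
    message_log: list = field(default_factory=list)  # (sender, receiver, payload_len)
    final_stacks: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "p": self.p,
                "op_applications": self.op_applications,
                "messages_sent": self.messages_sent,
                "values_transmitted": self.values_transmitted,
                "per_pe_executed": self.per_pe_executed,
                "message_log": self.message_log,
            },
            indent=1,
        )


class _OperatorError(RuntimeError):
    pass


def execute_reduce(
    s: Schedule,
    values: Sequence,
    op: ReductionOperator,
    pe_order: Sequence | None = None,
):
    """Run a compiled schedule over concrete values on the simulated engine.

    PEs are stepped round-robin (in ``pe_order``, default rank order); a PE
    blocks on PUSH_RECV until the single message of the corresponding edge has
    been delivered, which happens when the sending PE completes its program.
    The scheduling order cannot affect the result — only message availability
    gates progress, and values are consumed strictly in payload order.

    Returns ``(root result, EngineTrace)``.
    """
    if len(values) != s.n:
        raise ValueError(f"got {len(values)} values, schedule expects {s.n}")
    p = s.p
    order = list(pe_order) if pe_order is not None else list(range(p))
    if sorted(order) != list(range(p)):
        raise ValueError("pe_order must be a permutation of range(p)")

    ct = build_comm_tree(p, s.degree)
    pc = [0] * p
    stacks: list = [[] for _ in range(p)]
    delivered: dict = {}  # edge -> list of values
    cursor = {e: 0 for e in s.manifests}
    sent = [False] * p
    trace = EngineTrace(n=s.n, p=p, per_pe_executed=[0] * p)

    def step(pe: int) -> bool:
        """Execute ops on ``pe`` until blocked or done; True if progressed."""
        prog = s.programs[pe]
        progressed = False
        while pc[pe] < len(prog):
            opcode, arg = prog[pc[pe]]
            if opcode == PUSH_LOCAL:
                stacks[pe].append(values[arg])
            elif opcode == PUSH_RECV:
                edge = (arg, pe)
                if edge not in delivered:
                    return progressed  # blocked: message not yet arrived
                stacks[pe].append(delivered[edge][cursor[edge]])
                cursor[edge] += 1
            else:  # REDUCE
                b = stacks[pe].pop()
                a = stacks[pe].pop()
                try:
                    stacks[pe].append(op.apply(a, b))
                except Exception as exc:
                    raise _OperatorError(
                        f"operator {op.name!r} failed at reduction node {arg} on PE {pe}"
                    ) from exc
                trace.op_applications += 1
            pc[pe] += 1
            trace.per_pe_executed[pe] += 1
            progressed = True
        if not sent[pe] and pe != 0:
            parent = ct.parent[pe]
            delivered[(pe, parent)] = list(stacks[pe])
            trace.messages_sent += 1
            trace.values_transmitted += len(stacks[pe])
            trace.message_log.append((pe, parent, len(stacks[pe])))
            sent[pe] = True
            progressed = True
        return progressed

    remaining = set(range(p))
    while remaining:
        progressed_any = False
        for pe in order:
            if pe not in remaining:
                continue
            if step(pe):
                progressed_any = True
            if pc[pe] == len(s.programs[pe]) and (sent[pe] or pe == 0):
                remaining.discard(pe)
        if remaining and not progressed_any:
            raise RuntimeError(f"engine deadlock; PEs {sorted(remaining)} blocked")

    if len(stacks[0]) != 1:
        raise RuntimeError(f"root stack holds {len(stacks[0])} values, expected 1")
    trace.final_stacks = [list(st) for st in stacks]
    return stacks[0][0], trace


def execute_allreduce(
    s: Schedule,
    values: Sequence,
    op: ReductionOperator,
    pe_order: Sequence | None = None,
):
    """Reduce to the root PE, then broadcast the result down the comm tree.

    Returns ``(list of per-PE results, EngineTrace)``; all entries are the
    same object/bit pattern as the root result, and the trace counts the
    additional p-1 broadcast messages (2(p-1) total).
    """
    result, trace = execute_reduce(s, values, op, pe_order=pe_order)
    ct = build_comm_tree(s.p, s.degree)
    results = [None] * s.p
    results[0] = result
    # breadth-first down the k-nomial tree; one message per edge
    frontier = [0]
    while frontier:
        nxt = []
        for pe in frontier:
            for child in ct.children[pe]:
                results[child] = results[pe]
                trace.messages_sent += 1
                trace.values_transmitted += 1
                trace.message_log.append((pe, child, 1))
                nxt.append(child)
        frontier = nxt
    return results, trace


def sequential_pairwise_oracle(values: Sequence, op: ReductionOperator):
    """Single-process evaluation of the fixed balanced reduction tree.

    Recursively splits ``[a, b)`` at ``a + ceil((b-a)/2)`` and combines
    ``left ⊕ right`` — the bit-exact ground truth every distributed execution
    must match.  Implemented directly on intervals, independent of the
    schedule compiler and engine.
    """
    n = len(values)
    if n == 0:
        raise ValueError("empty reduction: n must be >= 1")

    def rec(a: int, b: int):
        if b - a == 1:
            return values[a]
        m = _split(a, b)
        return op.apply(rec(a, m), rec(m, b))

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n.bit_length() + 100))
    try:
        return rec(0, n)
    finally:
        sys.setrecursionlimit(old)


def sequential_fold(values: Sequence, op: ReductionOperator):
    """Strict left-to-right fold: (((e0 ⊕ e1) ⊕ e2) ⊕ ...)."""
    if len(values) == 0:
        raise ValueError("empty reduction: n must be >= 1")
    acc = values[0]
    for v in values[1:]:
        acc = op.apply(acc, v)
    return acc


def gather_bcast_reduce(values: Sequence, own: OwnershipMap, op: ReductionOperator):
    """Gather every element at the root PE, fold left-to-right, broadcast.

    The reproducible fallback recommended by the MPI standard: correct and
    PE-count independent, but the root receives p-1 messages and all n
    elements, and the fold itself is serial.  Returns ``(value, stats)``.
    """
    if own.n != len(values):
        raise ValueError("ownership/values length mismatch")
    result = sequential_fold(values, op)
    stats = {
        "root_messages_received": own.p - 1,
        "root_elements_received": own.n,
        "broadcast_messages": own.p - 1,
        "serial_fold_length": own.n,
    }
    return result, stats


def baseline_nonrepro_reduce(
    values: Sequence, own: OwnershipMap, p: int, op: ReductionOperator
):
    """Conventional non-reproducible reduction: per-PE fold, then rank-order fold.

    Each PE folds its locally owned elements left-to-right in local (global
    index) order into one partial; the partials are then folded in PE rank
    order, skipping PEs that own nothing.  For floating-point operators the
    realized association — and hence the rounding — depends on p and on the
    ownership map.
    """
    if own.p != p:
        raise ValueError(f"ownership built for p={own.p}, called with p={p}")
    if own.n != len(values):
        raise ValueError("ownership/values length mismatch")
    locals_: list = [[] for _ in range(p)]
    for i, pe in enumerate(own.owners):
        locals_[pe].append(values[i])
    partials = [sequential_fold(chunk, op) for chunk in locals_ if chunk]
    return sequential_fold(partials, op)


def float_bits(x: float) -> str:
    """Hex string of the 64-bit IEEE 754 pattern of ``x`` (big-endian)."""
    import struct

    return struct.pack(">d", float(x)).hex()


def read_values_file(path) -> list:
    """Read one float per line; both decimal and C99 hex-float literals accepted.

    Hex-float literals (``0x1.5p3``) round-trip bit patterns exactly and are
    the preferred fixture format.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.strip()
            if not tok or tok.startswith("#"):
                continue
            try:
                if "x" in tok or "X" in tok:
                    out.append(float.fromhex(tok))
                else:
                    out.append(float(tok))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad float literal {tok!r}") from None
    if not out:
        raise ValueError(f"{path}: no values")
    return out


def write_values_file(path, values: Sequence, hex_format: bool = True) -> None:
    with open(path, "w") as fh:
        for v in values:
            fh.write((float(v).hex() if hex_format else repr(float(v))) + "\n")
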
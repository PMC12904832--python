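"""Reduction tree shape, k-nomial comm tree, LCA assignment, schedule compiler."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reprored as rr
from reprored.schedule import (
    PUSH_LOCAL,
    PUSH_RECV,
    REDUCE,
    _leaf_node_id,
    validate_schedule,
)


class TestReductionTree:
    def test_degenerate_single_leaf(self):
        rt = rr.build_reduction_tree(1)
        assert rt.n_leaves == 1
        assert len(rt.internal_nodes()) == 0
        assert rt.leaf[rt.root] == 0

    def test_internal_node_count(self):
        assert len(rr.build_reduction_tree(5).internal_nodes()) == 4

    def test_ceiling_split_at_root(self):
        rt = rr.build_reduction_tree(4)
        left, right = rt.left[rt.root], rt.right[rt.root]
        assert (rt.lo[left], rt.hi[left]) == (0, 2)
        assert (rt.lo[right], rt.hi[right]) == (2, 4)

    def test_odd_split_left_larger(self):
        rt = rr.build_reduction_tree(5)
        left = rt.left[rt.root]
        assert (rt.lo[left], rt.hi[left]) == (0, 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty reduction"):
            rr.build_reduction_tree(0)

    @given(st.integers(min_value=1, max_value=300))
    @settings(deadline=None, max_examples=40)
    def test_interval_structure(self, n):
        """Every internal node covers exactly the union of its children's intervals."""
        rt = rr.build_reduction_tree(n)
        assert rt.n_nodes == 2 * n - 1
        for v in range(rt.n_nodes):
            if rt.leaf[v] is None:
                l, r = rt.left[v], rt.right[v]
                assert rt.lo[v] == rt.lo[l] and rt.hi[v] == rt.hi[r]
                assert rt.hi[l] == rt.lo[r]  # contiguous
                assert l < r < v  # post-order numbering
            else:
                assert rt.hi[v] - rt.lo[v] == 1


class TestCommTree:
    def test_single_pe_no_edges(self):
        ct = rr.build_comm_tree(1, 2)
        assert ct.parent == (None,)

    def test_two_pes(self):
        ct = rr.build_comm_tree(2, 2)
        assert ct.parent == (None, 0)

    def test_binomial_p4(self):
        ct = rr.build_comm_tree(4, 2)
        assert ct.parent == (None, 0, 0, 2)

    @pytest.mark.parametrize("p,k", [(0, 2), (-1, 2), (3, 1), (3, 0)])
    def test_bad_parameters(self, p, k):
        with pytest.raises(ValueError):
            rr.build_comm_tree(p, k)

    @pytest.mark.parametrize("k", [2, 3, 4])
    @pytest.mark.parametrize("p", [1, 2, 5, 16, 17, 64])
    def test_valid_rooted_tree(self, p, k):
        """p-1 edges, acyclic, every PE reachable from PE 0."""
        ct = rr.build_comm_tree(p, k)
        assert sum(1 for r in range(p) if ct.parent[r] is not None) == p - 1
        for r in range(p):
            assert ct.is_ancestor(0, r)
            if r > 0:
                assert ct.parent[r] < r  # parents precede children: acyclic

    def test_degree4_matches_digit_clearing(self):
        # 7 = 13 base 4 -> clear lowest digit -> 4;  8 = 20 base 4 -> 0
        ct = rr.build_comm_tree(16, 4)
        assert ct.parent[7] == 4
        assert ct.parent[8] == 0
        assert ct.parent[15] == 12


class TestCommLca:
    def test_singleton(self):
        assert rr.comm_lca(rr.build_comm_tree(8, 2), [3]) == 3

    def test_sibling_chain(self):
        ct = rr.build_comm_tree(4, 2)
        assert rr.comm_lca(ct, [2, 3]) == 2
        assert rr.comm_lca(ct, [1, 3]) == 0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            rr.comm_lca(rr.build_comm_tree(4, 2), [])

    def test_out_of_range_pe(self):
        with pytest.raises(ValueError):
            rr.comm_lca(rr.build_comm_tree(4, 2), [1, 7])


class TestCompileSchedule:
    def test_worked_two_pe_example(self):
        """Hand-traced n=4, p=2 contiguous-halves schedule."""
        rt = rr.build_reduction_tree(4)
        ct = rr.build_comm_tree(2, 2)
        own = rr.OwnershipMap.from_list([0, 0, 1, 1], 2)
        s = rr.compile_schedule(rt, ct, own)
        assert s.programs[1] == (
            (PUSH_LOCAL, 2),
            (PUSH_LOCAL, 3),
            (REDUCE, 5),
        )
        assert s.programs[0] == (
            (PUSH_LOCAL, 0),
            (PUSH_LOCAL, 1),
            (REDUCE, 2),
            (PUSH_RECV, 1),
            (REDUCE, 6),
        )
        assert s.manifests[(1, 0)] == (5,)

    def test_single_pe_program(self):
        n = 9
        s = rr.compile_schedule(
            rr.build_reduction_tree(n),
            rr.build_comm_tree(1, 2),
            rr.gen_ownership(n, 1, "contiguous"),
        )
        ops = [op for op, _ in s.programs[0]]
        assert ops.count(PUSH_LOCAL) == n
        assert ops.count(REDUCE) == n - 1
        assert not s.manifests

    def test_ownership_length_mismatch(self):
        with pytest.raises(ValueError):
            rr.compile_schedule(
                rr.build_reduction_tree(4),
                rr.build_comm_tree(2, 2),
                rr.OwnershipMap.from_list([0, 0, 1], 2),
            )

    def test_ownership_pe_out_of_range(self):
        with pytest.raises(ValueError):
            rr.OwnershipMap.from_list([0, 5], 2)

    def test_pe_count_mismatch(self):
        with pytest.raises(ValueError):
            rr.compile_schedule(
                rr.build_reduction_tree(4),
                rr.build_comm_tree(2, 2),
                rr.OwnershipMap.from_list([0, 0, 2, 2], 3),
            )

    @given(
        n=st.integers(1, 60),
        p=st.integers(1, 9),
        k=st.sampled_from([2, 4]),
        seed=st.integers(0, 10_000),
    )
    @settings(deadline=None, max_examples=60)
    def test_schedule_invariants(self, n, p, k, seed):
        """Conservation, global order, containment, and replay validity."""
        rt = rr.build_reduction_tree(n)
        ct = rr.build_comm_tree(p, k)
        own = rr.gen_ownership(n, p, "random", seed)
        s = rr.compile_schedule(rt, ct, own)

        # conservation
        all_ops = [op for prog in s.programs for op in prog]
        assert sum(1 for o, _ in all_ops if o == REDUCE) == n - 1
        assert sum(1 for o, _ in all_ops if o == PUSH_LOCAL) == n

        # flattening REDUCE ops by post-order reconstructs the internal-node
        # sequence of the fixed tree — the PE-independence of the order
        reduces = sorted(arg for o, arg in all_ops if o == REDUCE)
        assert reduces == rt.internal_nodes()

        # per-PE op lists are ordered by global post-order position
        cursors = {e: 0 for e in s.manifests}
        for pe, prog in enumerate(s.programs):
            positions = []
            for o, arg in prog:
                if o == PUSH_LOCAL:
                    positions.append(_leaf_node_id(rt, arg))
                elif o == REDUCE:
                    positions.append(arg)
                else:
                    e = (arg, pe)
                    positions.append(s.manifests[e][cursors[e]])
                    cursors[e] += 1
            assert positions == sorted(positions)

        # containment: each internal node's PE is a comm ancestor-or-equal of
        # both children's PEs
        for v in rt.internal_nodes():
            pe = s.node_pe[v]
            assert ct.is_ancestor(pe, s.node_pe[rt.left[v]])
            assert ct.is_ancestor(pe, s.node_pe[rt.right[v]])

        # message payloads are in post-order of producing nodes
        for payload in s.manifests.values():
            assert list(payload) == sorted(payload)

        validate_schedule(s, rt, ct)

    def test_determinism_byte_identical(self):
        args = (17, 5, 2, 123)

        def build():
            n, p, k, seed = args
            return rr.compile_schedule(
                rr.build_reduction_tree(n),
                rr.build_comm_tree(p, k),
                rr.gen_ownership(n, p, "random", seed),
            ).to_json()

        assert build().encode() == build().encode()

    def test_empty_pe_forwards(self):
        """A PE owning nothing still occupies its comm position and may forward."""
        # all elements on PE 3 (child of 2, grandchild of 0); PEs 1, 2 own nothing
        own = rr.OwnershipMap.from_list([3, 3, 3, 3], 4)
        rt = rr.build_reduction_tree(4)
        ct = rr.build_comm_tree(4, 2)
        s = rr.compile_schedule(rt, ct, own)
        assert s.programs[1] == ()
        assert s.manifests[(1, 0)] == ()  # empty message kept
        # root value computed on PE 3, forwarded through 2 to 0
        assert s.manifests[(3, 2)] == (rt.root,)
        assert s.manifests[(2, 0)] == (rt.root,)
        validate_schedule(s, rt, ct)


class TestScheduleStats:
    def test_message_minimum_p8(self):
        s = rr.compile_schedule(
            rr.build_reduction_tree(100),
            rr.build_comm_tree(8, 2),
            rr.gen_ownership(100, 8, "round_robin"),
        )
        assert rr.schedule_stats(s)["messages"] == 7

    def test_no_messages_single_pe(self):
        s = rr.compile_schedule(
            rr.build_reduction_tree(6),
            rr.build_comm_tree(1, 2),
            rr.gen_ownership(6, 1, "contiguous"),
        )
        assert rr.schedule_stats(s)["messages"] == 0

    def test_worked_example_payload(self):
        s = rr.compile_schedule(
            rr.build_reduction_tree(4),
            rr.build_comm_tree(2, 2),
            rr.OwnershipMap.from_list([0, 0, 1, 1], 2),
        )
        stats = rr.schedule_stats(s)
        assert stats["payload_lengths"] == {(1, 0): 1}
        assert stats["total_reduce_ops"] == 3
        assert stats["total_push_local"] == 4


class TestSerialization:
    def test_json_round_trip(self):
        s = rr.compile_schedule(
            rr.build_reduction_tree(11),
            rr.build_comm_tree(3, 2),
            rr.gen_ownership(11, 3, "random", 7),
        )
        s2 = rr.Schedule.from_json(s.to_json())
        assert s2.programs == s.programs
        assert s2.manifests == s.manifests
        assert (s2.n, s2.p, s2.degree, s2.owners) == (s.n, s.p, s.degree, s.owners)

    def test_json_is_valid_documented_layout(self):
        s = rr.compile_schedule(
            rr.build_reduction_tree(4),
            rr.build_comm_tree(2, 2),
            rr.OwnershipMap.from_list([0, 0, 1, 1], 2),
        )
        d = json.loads(s.to_json())
        assert set(d) == {"n", "p", "degree", "owners", "programs", "manifests"}
        assert d["programs"][1] == [["push_local", 2], ["push_local", 3], ["reduce", 5]]
        assert d["manifests"] == {"1->0": [5]}
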
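import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cophymap import (
    CODIVERGENCE,
    HOST_SWITCH,
    CostScheme,
    EventCounts,
    EventRecord,
    InputError,
    JUNGLE,
    NodeOrdering,
    PhyloTree,
    StructureError,
    audit_time_consistency,
    default_ordering,
    schedule_cherries,
    total_cost,
    tree_collapse,
    validate_ordering,
    yule_tree,
)
from cophymap.model import assemble_mapping

from conftest import make_tanglegram


class TestPhyloTree:
    def test_basic_shape(self):
        t = PhyloTree.from_nested((("A", "B"), "C"))
        assert t.n_leaves == 3
        assert t.n_internal == 2
        assert len(t) == 5

    def test_leaf_count_invariant(self):
        t = PhyloTree.from_nested(((("A", "B"), ("C", "D")), "E"))
        assert t.n_internal == t.n_leaves - 1

    def test_duplicate_labels_rejected(self):
        with pytest.raises(StructureError, match="duplicate"):
            PhyloTree.from_nested((("A", "B"), "A"))

    def test_empty_label_rejected(self):
        with pytest.raises(StructureError, match="empty"):
            PhyloTree.from_nested((("A", ""), "C"))

    def test_ancestry_and_lca(self):
        t = PhyloTree.from_nested((("A", "B"), ("C", "D")))
        a, c = t.leaf_by_label("A"), t.leaf_by_label("C")
        assert t.lca(a, c) == t.root
        assert t.is_ancestor(t.root, a)
        assert not t.is_ancestor(a, t.root)
        ab = t.parent[a]
        assert t.lca(a, t.leaf_by_label("B")) == ab
        assert t.sibling(a) == t.leaf_by_label("B")


class TestDefaultOrdering:
    def test_three_leaf_forced(self):
        t = PhyloTree.from_nested((("A", "B"), "C"))
        o = default_ordering(t)
        ab = t.parent[t.leaf_by_label("A")]
        assert o.depth[t.root] == 0
        assert o.depth[ab] == 1
        assert all(o.depth[l] == 2 for l in t.leaves())

    def test_two_leaf_degenerate(self):
        t = PhyloTree.from_nested(("A", "B"))
        o = default_ordering(t)
        assert o.depth[t.root] == 0
        assert all(o.depth[l] == 1 for l in t.leaves())

    def test_balanced_four(self):
        t = PhyloTree.from_nested((("A", "B"), ("C", "D")))
        o = default_ordering(t)
        internal = [v for v in t.internal_nodes() if v != t.root]
        assert o.depth[t.root] == 0
        assert sorted(o.depth[v] for v in internal) == [1, 2]

    def test_single_node_rejected(self):
        with pytest.raises(StructureError):
            default_ordering(PhyloTree.from_nested("A"))

    @pytest.mark.parametrize("seed", range(25))
    def test_always_valid_on_yule(self, seed):
        t = yule_tree(4 + (seed * 5) % 125, random.Random(seed))
        assert validate_ordering(t, default_ordering(t))


class TestValidateOrdering:
    def _tree(self):
        return PhyloTree.from_nested((("A", "B"), ("C", "D")))

    def _ordering(self, t, ab, cd):
        depth = {t.root: 0}
        for v in t.internal_nodes():
            if v == t.root:
                continue
            labs = {t.labels[l] for l in t.leaves() if t.is_ancestor(v, l)}
            depth[v] = ab if labs == {"A", "B"} else cd
        for l in t.leaves():
            depth[l] = 3
        return NodeOrdering(depth=depth, n_internal=3)

    def test_valid(self):
        t = self._tree()
        assert validate_ordering(t, self._ordering(t, ab=2, cd=1))

    def test_duplicate_depth_invalid(self):
        t = self._tree()
        assert not validate_ordering(t, self._ordering(t, ab=0, cd=1))

    def test_child_not_deeper_invalid(self):
        t = PhyloTree.from_nested((("A", "B"), "C"))
        ab = t.parent[t.leaf_by_label("A")]
        depth = {t.root: 1, ab: 0}
        for l in t.leaves():
            depth[l] = 2
        assert not validate_ordering(t, NodeOrdering(depth=depth, n_internal=2))

    def test_missing_node_is_an_error_not_false(self):
        t = self._tree()
        with pytest.raises(InputError):
            validate_ordering(t, NodeOrdering(depth={t.root: 0}, n_internal=3))


class TestScheduleCherries:
    def test_descending_depths(self):
        t = PhyloTree.from_nested((("A", "B"), ("C", "D")))
        o = default_ordering(t)
        order = schedule_cherries(t, o)
        depths = [o.depth[v] for v in order]
        assert depths == sorted(depths, reverse=True)
        assert len(order) == t.n_internal

    def test_three_leaf(self):
        t = PhyloTree.from_nested((("A", "B"), "C"))
        o = default_ordering(t)
        ab = t.parent[t.leaf_by_label("A")]
        assert schedule_cherries(t, o) == [ab, t.root]

    def test_two_leaf(self):
        t = PhyloTree.from_nested(("A", "B"))
        assert schedule_cherries(t, default_ordering(t)) == [t.root]


class TestTotalCost:
    def test_codivergence_free(self):
        assert total_cost(EventCounts(2, 0, 0, 0), JUNGLE) == 0

    def test_jungle_weights(self):
        assert total_cost(EventCounts(0, 1, 1, 1), JUNGLE) == 4

    def test_arithmetic(self):
        assert total_cost(EventCounts(3, 2, 1, 4), JUNGLE) == 8

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            EventCounts(-1, 0, 0, 0)

    def test_negative_weights_rejected(self):
        with pytest.raises(InputError):
            CostScheme(w_loss=-1)

    @given(
        st.tuples(*[st.integers(min_value=0, max_value=50)] * 4),
        st.tuples(*[st.integers(min_value=0, max_value=50)] * 4),
    )
    @settings(max_examples=50, deadline=None)
    def test_additivity(self, a, b):
        ca, cb = EventCounts(*a), EventCounts(*b)
        csum = EventCounts(*(x + y for x, y in zip(a, b)))
        assert total_cost(csum, JUNGLE) == total_cost(ca, JUNGLE) + total_cost(
            cb, JUNGLE
        )


class TestAudit:
    def test_collapse_outputs_pass(self, small_instances):
        for tg in small_instances[:15]:
            assert audit_time_consistency(tree_collapse(tg))

    def test_disjoint_switch_spans_fail(self):
        tg = make_tanglegram(
            "(((A,B),C),D);", "(a,d);", {"a": "A", "d": "D"}
        )
        host = tg.host
        o = default_ordering(host)
        ab = host.parent[host.leaf_by_label("A")]
        a = host.leaf_by_label("A")
        d = host.leaf_by_label("D")
        # takeoff span [d(AB), leaf) = [2,3); landing span [-1, 0): disjoint
        ev = EventRecord(
            kind=HOST_SWITCH,
            parasite_node=tg.parasite.root,
            time_index=2,
            takeoff_edge=(ab, a),
            landing_edge=(None, host.root),
            takeoff_child=tg.parasite.leaf_by_label("a"),
            landing_child=tg.parasite.leaf_by_label("d"),
        )
        mapping = tree_collapse(tg)
        mapping.events = [ev]
        assert not audit_time_consistency(mapping)

    def test_child_before_parent_fails(self, congruent3):
        mapping = tree_collapse(congruent3)
        assert audit_time_consistency(mapping)
        mapping.events = list(reversed(mapping.events))
        assert not audit_time_consistency(mapping)


class TestAssembleMapping:
    def test_codivergence_losses_derived(self, loss_instance):
        tg = loss_instance
        o = default_ordering(tg.host)
        ev = EventRecord(
            kind=CODIVERGENCE,
            parasite_node=tg.parasite.root,
            time_index=0,
            host_node=tg.host.root,
        )
        m = assemble_mapping(tg, o, {tg.parasite.root: ev})
        counts = m.counts()
        assert counts.n_codivergence == 1
        assert counts.n_loss == 1  # a's lineage passes the (A,B) node
        assert m.cost() == 1
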
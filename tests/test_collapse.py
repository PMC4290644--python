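import itertools
import random

import numpy as np
import pytest

from cophymap import (
    SimParams,
    audit_time_consistency,
    default_ordering,
    exact_dp,
    generate_instance,
    right_push,
    tree_collapse,
    validate_ordering,
)
from cophymap.collapse import (
    ALL_PATTERNS,
    CollapseConfig,
    CollapseState,
    PatternMatch,
    choose_pattern,
    detect_patterns,
)
from cophymap.ga import decode, random_chromosome
from cophymap.model import Cherry, PhyloTree, Tanglegram, schedule_cherries

from conftest import make_tanglegram

AGGRESSIVE = CollapseConfig(defer_switches=False)


def first_cherry_state(tg, config=CollapseConfig()):
    ordering = default_ordering(tg.host)
    state = CollapseState(tg, ordering, config)
    q = schedule_cherries(tg.host, ordering)[0]
    x, y = tg.host.children[q]
    return state, Cherry(x, y, q)


class TestDetectPatterns:
    def test_codivergence_match(self, congruent3):
        state, cherry = first_cherry_state(congruent3)
        matches = detect_patterns(state, cherry)
        assert [m.kind for m in matches] == ["codivergence"]

    def test_duplication_match(self):
        tg = make_tanglegram("((A,B),C);", "(x,y);", {"x": "A", "y": "A"})
        state, cherry = first_cherry_state(tg)
        matches = detect_patterns(state, cherry)
        assert [m.kind for m in matches] == ["duplication"]

    def test_no_parasite_means_no_match(self):
        tg = make_tanglegram("((A,B),C);", "(x,y);", {"x": "C", "y": "C"})
        state, cherry = first_cherry_state(tg)
        assert detect_patterns(state, cherry) == []

    def test_switch_match_enumerated(self):
        """Brute force over every 3-host-leaf / 2-parasite-leaf instance:
        with deferral off, the first cherry yields a host-switch match
        exactly when one parasite leaf maps into the cherry and the other
        outside it (and no cheaper pattern applies)."""
        shapes = ["((A,B),C);", "((A,C),B);", "((B,C),A);"]
        for shape, (ha, hb) in itertools.product(
            shapes, itertools.product("ABC", repeat=2)
        ):
            tg = make_tanglegram(shape, "(x,y);", {"x": ha, "y": hb})
            state, cherry = first_cherry_state(tg, AGGRESSIVE)
            matches = detect_patterns(state, cherry)
            in_cherry = {cherry.i_left, cherry.i_right}
            pos = [tg.host.leaf_by_label(ha), tg.host.leaf_by_label(hb)]
            n_in = sum(1 for p in pos if p in in_cherry)
            if n_in == 2:
                expected = "codivergence" if ha != hb else "duplication"
                assert [m.kind for m in matches] == [expected]
            elif n_in == 1 and ha != hb:
                kinds = {m.kind for m in matches}
                assert "host_switch" in kinds
                sw = next(m for m in matches if m.kind == "host_switch")
                assert sw.takeoff_leaf in in_cherry | set(pos)
                assert state.ordering.depth[sw.switch_target] >= (
                    state.ordering.depth[cherry.i_parent]
                )
            elif n_in == 0:
                assert matches == []

    def test_dup_switch_disabled_by_flag(self):
        cfg = CollapseConfig.without("dup_switch")
        assert not cfg.allows("dup_switch")
        assert cfg.allows("host_switch")


class TestChoosePattern:
    def _match(self, kind, cost, tidx=0):
        return PatternMatch(
            kind=kind,
            host_cherry=Cherry(0, 1, 2),
            parasite_nodes=(0,),
            local_cost=cost,
            traversal_index=tidx,
        )

    def test_cheaper_wins(self):
        cod = self._match("codivergence", 0.0)
        sw = self._match("host_switch", 2.0)
        assert choose_pattern([sw, cod]) is cod

    def test_empty_is_loss_decision(self):
        assert choose_pattern([]) is None

    def test_tie_broken_by_traversal_index(self):
        a = self._match("host_switch", 2.0, tidx=1)
        b = self._match("host_switch", 2.0, tidx=0)
        assert choose_pattern([a, b]) is b

    def test_kind_priority_on_cost_tie(self):
        sw = self._match("host_switch", 2.0)
        dsw = self._match("double_switch", 2.0)
        assert choose_pattern([sw, dsw]) is dsw


class TestCollapseEngine:
    def test_congruent(self, congruent3):
        m = tree_collapse(congruent3)
        c = m.counts()
        assert (c.n_codivergence, c.n_loss) == (2, 0)
        assert m.cost() == 0

    def test_loss_instance_matches_oracle(self, loss_instance):
        m = tree_collapse(loss_instance)
        opt, _ = exact_dp(loss_instance)
        assert m.cost() == opt == 1
        c = m.counts()
        assert (c.n_codivergence, c.n_loss) == (1, 1)

    def test_root_duplication_instance(self):
        # two parasite pairs over a 2-leaf host: a duplication above the
        # root is unavoidable and the stray lineage misses one divergence
        tg = make_tanglegram("(A,B);", "((x,y),z);", {"x": "A", "y": "B", "z": "B"})
        m = tree_collapse(tg)
        opt, _ = exact_dp(tg)
        assert m.cost() == opt == 2

    def test_chain_switch(self, chain5_switch):
        m = right_push(tree_collapse(chain5_switch))
        opt, _ = exact_dp(chain5_switch)
        assert m.cost() == opt == 2
        assert m.counts().n_host_switch == 1

    def test_single_leaf_parasite(self):
        tg = make_tanglegram("((A,B),C);", "(a1,a2);", {"a1": "A", "a2": "A"})
        assert tree_collapse(tg).cost() == 1  # one duplication

    def test_every_internal_node_evented_once(self, small_instances):
        for tg in small_instances:
            m = tree_collapse(tg)
            evented = [e.parasite_node for e in m.events if e.kind != "loss"]
            assert sorted(evented) == sorted(tg.parasite.internal_nodes())
            for leaf, host_leaf in tg.phi.items():
                assert m.placement[leaf] == host_leaf

    def test_counts_identity(self, small_instances):
        for tg in small_instances:
            c = tree_collapse(tg).counts()
            assert (
                c.n_codivergence + c.n_duplication + c.n_host_switch
                == tg.parasite.n_internal
            )


class TestTimeConsistencyProperty:
    @pytest.mark.parametrize("seed", range(40))
    def test_random_instances_and_orderings(self, seed):
        params = SimParams(n_host_leaves=4 + (seed * 3) % 29, rng_seed=seed)
        tg = generate_instance(params)
        rng = random.Random(10_000 + seed)
        for rep in range(3):
            ordering = decode(tg.host, random_chromosome(tg.host, rng))
            assert validate_ordering(tg.host, ordering)
            m = tree_collapse(tg, ordering)
            assert audit_time_consistency(m)
            assert audit_time_consistency(right_push(m))


class TestGreedyBounds:
    def test_never_beats_exact_dp(self, small_instances):
        for tg in small_instances:
            ordering = default_ordering(tg.host)
            cost = right_push(tree_collapse(tg, ordering)).cost()
            opt, witness = exact_dp(tg, ordering)
            assert opt <= cost + 1e-9
            assert audit_time_consistency(witness)


class TestLinearScaling:
    def test_congruent_series_is_linear(self):
        sizes = [8, 16, 32, 64, 128, 256, 512, 1024]
        ops = []
        for n in sizes:
            params = SimParams(
                n_host_leaves=n, rng_seed=7,
                p_codiv=1.0, p_dup=0.0, p_switch=0.0, p_loss=0.0,
            )
            m = tree_collapse(generate_instance(params))
            assert m.cost() == 0
            ops.append(m.op_count)
        for a, b in zip(ops, ops[1:]):
            assert b / a < 2.5
        x, y = np.array(sizes, float), np.array(ops, float)
        coef = np.polyfit(x, y, 1)
        resid = y - np.polyval(coef, x)
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 > 0.99


class TestHybridEffect:
    def test_hybrids_never_hurt_on_average(self):
        base = CollapseConfig.base_only()
        tot8 = tot4 = 0.0
        for i in range(120):
            tg = generate_instance(SimParams(n_host_leaves=4 + (i % 9), rng_seed=i))
            tot8 += right_push(tree_collapse(tg)).cost()
            tot4 += right_push(tree_collapse(tg, config=base)).cost()
        assert tot8 <= tot4 + 1e-9
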
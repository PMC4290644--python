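"""Greedy cherry-collapse reconstruction over a fixed host node ordering.

Host cherries are processed deepest-first.  At each cherry a bounded DFS
walks from the two host leaves into the parasite tree (at most
:data:`PATTERN_DFS_LEVELS` parasite levels) and classifies the local
configuration against an eight-pattern table: four base patterns
(codivergence, duplication, host switch, loss) and four hybrid bundles that
commit two consecutive events at once (codivergence-switch,
duplication-switch, loss-switch, double-switch).  The cheapest pattern is
applied and one or both cherries collapse; when nothing matches, the host
cherry collapses on its own and the lineages stranded on it ride up to the
parent (paying losses in the derived accounting).

Because cherries are consumed in strictly decreasing depth order, every
live lineage outside the current cherry sits at a depth at or below the
cherry parent, so any switch recorded here lands on an edge that coexists
in time with the takeoff edge — time consistency holds by construction and
is re-audited in tests.

Switches are only taken when locally worth it: a switch match is *deferred*
(left to loss inference) whenever letting both lineages climb to their
meeting point and codiverge there is estimated to cost no more than the
switch.  Deferred matches are re-examined at every ancestor cherry, so a
deferral is never final.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .model import (
    CODIVERGENCE,
    DUPLICATION,
    HOST_SWITCH,
    LOSS,
    Cherry,
    CophyloMapping,
    CostScheme,
    EventRecord,
    InputError,
    JUNGLE,
    NodeOrdering,
    PhyloTree,
    StructureError,
    Tanglegram,
    assemble_mapping,
    schedule_cherries,
)

__all__ = [
    "PATTERN_DFS_LEVELS",
    "BASE_PATTERNS",
    "HYBRID_PATTERNS",
    "ALL_PATTERNS",
    "PATTERN_PRIORITY",
    "PatternMatch",
    "CollapseConfig",
    "CollapseState",
    "detect_patterns",
    "choose_pattern",
    "apply_pattern",
    "tree_collapse",
]

#: Maximum number of parasite levels the detection DFS may traverse.
#: Base patterns need two (leaf + cherry parent); hybrids look one cherry
#: further, through the grandparent and its other lineage.
PATTERN_DFS_LEVELS = 4

P_CODIVERGENCE = "codivergence"
P_DUPLICATION = "duplication"
P_HOST_SWITCH = "host_switch"
P_LOSS = "loss"
P_CODIV_SWITCH = "codiv_switch"
P_DUP_SWITCH = "dup_switch"
P_LOSS_SWITCH = "loss_switch"
P_DOUBLE_SWITCH = "double_switch"

BASE_PATTERNS = frozenset({P_CODIVERGENCE, P_DUPLICATION, P_HOST_SWITCH, P_LOSS})
HYBRID_PATTERNS = frozenset(
    {P_CODIV_SWITCH, P_DUP_SWITCH, P_LOSS_SWITCH, P_DOUBLE_SWITCH}
)
ALL_PATTERNS = BASE_PATTERNS | HYBRID_PATTERNS

#: Fixed tie-break priority when two matches have equal local cost.
PATTERN_PRIORITY = (
    P_CODIVERGENCE,
    P_CODIV_SWITCH,
    P_DOUBLE_SWITCH,
    P_LOSS_SWITCH,
    P_DUP_SWITCH,
    P_DUPLICATION,
    P_HOST_SWITCH,
)
_PRIORITY_RANK = {k: i for i, k in enumerate(PATTERN_PRIORITY)}

# Patterns whose application collapses the host cherry on the spot.  A
# codivergence does *not*: several parasite cherries may track the same host
# divergence, so the host cherry stays open until no pattern matches and
# then collapses once (the loss decision).
_HOST_COLLAPSING = frozenset({P_LOSS_SWITCH})


@dataclass(frozen=True)
class CollapseConfig:
    """Which patterns the detector may emit.

    The duplication-switch hybrid is on by default; all eight patterns are
    individually switchable for ablation runs.
    """

    enabled_patterns: frozenset = frozenset(ALL_PATTERNS)
    #: adaptive profile weighs a switch against climbing to a shared
    #: codivergence; aggressive always takes an available switch.
    defer_switches: bool = True

    @classmethod
    def base_only(cls) -> "CollapseConfig":
        return cls(enabled_patterns=BASE_PATTERNS)

    @classmethod
    def without(cls, *kinds: str) -> "CollapseConfig":
        bad = set(kinds) - ALL_PATTERNS
        if bad:
            raise InputError(f"unknown pattern kind(s): {sorted(bad)}")
        return cls(enabled_patterns=frozenset(ALL_PATTERNS - set(kinds)))

    def allows(self, kind: str) -> bool:
        return kind in self.enabled_patterns


@dataclass(frozen=True)
class PatternMatch:
    """One detected local pattern, ready to apply.

    ``local_cost`` is the per-event (amortised) cost of the bundle under the
    active scheme, so that a two-event hybrid competes fairly with a
    one-event base pattern.  ``parasite_nodes`` lists the 1-3 parasite nodes
    the bundle touches, bottom-up.
    """

    kind: str
    host_cherry: Cherry
    parasite_nodes: Tuple[int, ...]
    local_cost: float
    traversal_index: int
    switch_target: Optional[int] = None
    # application payload: (p, sib, u) for the matched cherry, plus
    # (g, w) for hybrids and the second switch target.
    p: int = -1
    sib: int = -1
    u: int = -1
    takeoff_leaf: int = -1
    g: int = -1
    w: int = -1
    second_target: int = -1


class CollapseState:
    """Working state of the collapse loop.

    Lineages are tracked as *reps*: each live parasite subtree is
    represented by its root node id, positioned at a live host leaf.
    ``rep_anchor`` remembers the host node where the rep's own event sits
    (its phi target for leaves), which is what the loss derivation and the
    deferral estimate reason about.
    """

    def __init__(self, tg: Tanglegram, ordering: NodeOrdering, config: CollapseConfig):
        self.tg = tg
        self.host = tg.host
        self.parasite = tg.parasite
        self.ordering = ordering
        self.config = config
        self.live: Set[int] = set(tg.parasite.leaves())
        self.rep_pos: Dict[int, int] = dict(tg.phi)
        self.rep_anchor: Dict[int, int] = dict(tg.phi)
        self.host_reps: Dict[int, List[int]] = {}
        for p, h in tg.phi.items():
            self.host_reps.setdefault(h, []).append(p)
        self.node_events: Dict[int, EventRecord] = {}
        # one live rep per parasite subtree, as a position proxy for
        # lineages that have not merged yet (lookahead heuristics only)
        self.witness: Dict[int, int] = {}
        for leaf in tg.phi:
            node: Optional[int] = leaf
            while node is not None:
                self.witness[node] = leaf
                node = tg.parasite.parent[node]
        self.ops = 0

    # -- helpers -------------------------------------------------------------

    def parasite_done(self) -> bool:
        return len(self.live) == 1 and self.parasite.root in self.live

    def _merge_parasite(self, u: int, a: int, b: int, pos: int, anchor: int) -> None:
        self.live.discard(a)
        self.live.discard(b)
        for rep in (a, b):
            h = self.rep_pos.pop(rep)
            self.host_reps[h].remove(rep)
        self.live.add(u)
        self.rep_pos[u] = pos
        self.rep_anchor[u] = anchor
        self.host_reps.setdefault(pos, []).append(u)
        node: Optional[int] = u
        while node is not None:
            self.witness[node] = u
            node = self.parasite.parent[node]
        self.ops += 1

    def subtree_pos(self, node: int) -> Optional[int]:
        """Host position of a live lineage in ``node``'s parasite subtree."""
        if node in self.live:
            return self.rep_pos[node]
        cand = self.witness.get(node)
        if cand is not None and cand in self.live:
            return self.rep_pos[cand]
        return None

    def collapse_host_cherry(self, cherry: Cherry) -> None:
        q = cherry.i_parent
        moved = self.host_reps.pop(cherry.i_left, []) + self.host_reps.pop(
            cherry.i_right, []
        )
        for rep in moved:
            self.rep_pos[rep] = q
            self.ops += 1
        self.host_reps.setdefault(q, []).extend(moved)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _join_cost(host: PhyloTree, scheme: CostScheme, a: int, b: int) -> float:
    """Estimated cost of merging two lineages positioned at host nodes a, b.

    Both strictly below their LCA: climb losses on each side, then a
    codivergence at the meeting node.  One already at the meeting node (or
    both co-located): no codivergence is available there, so the join is a
    duplication above it and the lower lineage descends at full price.
    """
    meet = host.lca(a, b)
    da = host.topo_depth(a) - host.topo_depth(meet)
    db = host.topo_depth(b) - host.topo_depth(meet)
    if da > 0 and db > 0:
        return scheme.w_codivergence + scheme.w_loss * (da + db - 2)
    return scheme.w_duplication + scheme.w_loss * (da + db)


def _defer_switch(
    state: CollapseState, u: int, pos_in: int, pos_out: int, takeoff: int,
    scheme: CostScheme,
) -> bool:
    """True when letting the two lineages climb and codiverge is no worse.

    Deferral cost: one loss per host divergence either side passes before
    meeting, plus a free-ish codivergence there.  One level of lookahead:
    deferring parks the merged lineage at the meeting node rather than the
    takeoff leaf, which changes how far the pair's own sibling lineage (the
    grandparent's other child) must climb to join — that difference is
    charged too.  A deferred pair is re-examined at every ancestor cherry.
    """
    host = state.host
    parasite = state.parasite
    meet = host.lca(pos_in, pos_out)
    defer_cost = _join_cost(host, scheme, pos_in, pos_out)
    g = parasite.parent[u]
    if g is not None:
        pos_w = state.subtree_pos(parasite.sibling(u))
        if pos_w is not None:
            defer_cost += _join_cost(host, scheme, meet, pos_w) - _join_cost(
                host, scheme, takeoff, pos_w
            )
    return scheme.w_host_switch > defer_cost


def detect_patterns(
    state: CollapseState, cherry: Cherry, scheme: CostScheme = JUNGLE
) -> List[PatternMatch]:
    """All pattern matches at the given host cherry.

    The DFS starts at the cherry's two (live) host leaves, follows live phi
    into the parasite tree, and inspects at most :data:`PATTERN_DFS_LEVELS`
    parasite levels: the matched cherry, then for hybrids its grandparent's
    other lineage.
    """
    x, y, q = cherry.i_left, cherry.i_right, cherry.i_parent
    cfg = state.config
    parasite = state.parasite
    matches: List[PatternMatch] = []
    seen: Set[int] = set()
    in_cherry = {x, y}
    reps = list(state.host_reps.get(x, ())) + list(state.host_reps.get(y, ()))
    only_rep = len(reps) == 1

    for tidx, p in enumerate(reps):
        state.ops += 1
        par = parasite.parent[p]
        if par is None or par in seen:
            continue
        sib = parasite.sibling(p)
        if sib not in state.live:
            continue
        seen.add(par)
        hp = state.rep_pos[p]
        hs = state.rep_pos[sib]

        if hs in in_cherry and hp != hs:
            if cfg.allows(P_CODIVERGENCE):
                matches.append(
                    PatternMatch(
                        kind=P_CODIVERGENCE,
                        host_cherry=cherry,
                        parasite_nodes=(p, sib, par),
                        local_cost=scheme.w_codivergence,
                        traversal_index=tidx,
                        p=p,
                        sib=sib,
                        u=par,
                    )
                )
            continue
        if hs == hp:
            if cfg.allows(P_DUPLICATION):
                matches.append(
                    PatternMatch(
                        kind=P_DUPLICATION,
                        host_cherry=cherry,
                        parasite_nodes=(p, sib, par),
                        local_cost=scheme.w_duplication,
                        traversal_index=tidx,
                        p=p,
                        sib=sib,
                        u=par,
                    )
                )
            continue

        # hp in cherry, hs outside: switch family.  The outside position is
        # at depth >= d(q) automatically (deeper cherries are already gone) —
        # except a rep merged at the cherry parent itself, whose edge has
        # already closed by d(q); that pair can only resolve higher up.
        if hs == q:
            continue
        g = parasite.parent[par]
        w = parasite.sibling(par) if g is not None else -1
        w_live = g is not None and w in state.live
        # orientation: the merged lineage stays on the takeoff side, so take
        # off from wherever the grandparent's other subtree already sits.
        pos_w_proxy = state.subtree_pos(w) if g is not None else None
        if pos_w_proxy == hs:
            takeoff, target = hs, hp
        else:
            takeoff, target = hp, hs
        if cfg.defer_switches and _defer_switch(state, par, hp, hs, takeoff, scheme):
            continue
        base_kwargs = dict(
            host_cherry=cherry,
            traversal_index=tidx,
            p=p,
            sib=sib,
            u=par,
            takeoff_leaf=takeoff,
            switch_target=target,
        )
        if cfg.allows(P_HOST_SWITCH):
            matches.append(
                PatternMatch(
                    kind=P_HOST_SWITCH,
                    parasite_nodes=(p, sib, par),
                    local_cost=scheme.w_host_switch,
                    **base_kwargs,
                )
            )
        if g is None:
            if cfg.allows(P_LOSS_SWITCH) and only_rep:
                matches.append(
                    PatternMatch(
                        kind=P_LOSS_SWITCH,
                        parasite_nodes=(p, sib, par),
                        local_cost=(scheme.w_host_switch + scheme.w_loss) / 2.0,
                        **base_kwargs,
                    )
                )
            continue
        if not w_live:
            if cfg.allows(P_LOSS_SWITCH) and only_rep:
                matches.append(
                    PatternMatch(
                        kind=P_LOSS_SWITCH,
                        parasite_nodes=(p, sib, par),
                        local_cost=(scheme.w_host_switch + scheme.w_loss) / 2.0,
                        **base_kwargs,
                    )
                )
            continue
        hw = state.rep_pos[w]
        other = y if hp == x else x
        state.ops += 1
        if hw == other and cfg.allows(P_CODIV_SWITCH):
            matches.append(
                PatternMatch(
                    kind=P_CODIV_SWITCH,
                    parasite_nodes=(p, sib, par),
                    local_cost=(scheme.w_host_switch + scheme.w_codivergence) / 2.0,
                    g=g,
                    w=w,
                    **base_kwargs,
                )
            )
        elif hw == hp and cfg.allows(P_DUP_SWITCH):
            matches.append(
                PatternMatch(
                    kind=P_DUP_SWITCH,
                    parasite_nodes=(p, sib, par),
                    local_cost=(scheme.w_host_switch + scheme.w_duplication) / 2.0,
                    g=g,
                    w=w,
                    **base_kwargs,
                )
            )
        elif (
            hw not in in_cherry
            and hw != takeoff
            and hw != q
            and cfg.allows(P_DOUBLE_SWITCH)
            and not (
                cfg.defer_switches
                and _defer_switch(state, g, takeoff, hw, takeoff, scheme)
            )
        ):
            matches.append(
                PatternMatch(
                    kind=P_DOUBLE_SWITCH,
                    parasite_nodes=(p, sib, par),
                    local_cost=scheme.w_host_switch,
                    g=g,
                    w=w,
                    second_target=hw,
                    **base_kwargs,
                )
            )
    return matches


def choose_pattern(matches: Sequence[PatternMatch]) -> Optional[PatternMatch]:
    """Cheapest match; ties broken by fixed kind priority, then traversal order.

    ``None`` means the loss decision: nothing matched, collapse the host
    cherry and let the stranded lineages ride up.
    """
    if not matches:
        return None
    return min(
        matches,
        key=lambda m: (m.local_cost, _PRIORITY_RANK[m.kind], m.traversal_index),
    )


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------

def _record_switch(
    state: CollapseState,
    u: int,
    stay_child: int,
    jump_child: int,
    takeoff: Tuple[int, int],
    landing_leaf: int,
    time_index: int,
) -> None:
    landing = (state.host.parent[landing_leaf], landing_leaf)
    state.node_events[u] = EventRecord(
        kind=HOST_SWITCH,
        parasite_node=u,
        time_index=time_index,
        takeoff_edge=takeoff,
        landing_edge=landing,
        takeoff_child=stay_child,
        landing_child=jump_child,
    )


def apply_pattern(state: CollapseState, match: PatternMatch) -> bool:
    """Apply one chosen pattern; returns True iff the host cherry collapsed."""
    cherry = match.host_cherry
    q = cherry.i_parent
    t = state.ordering.depth[q]
    for node in (match.p, match.sib):
        if node not in state.live:
            raise StructureError("stale pattern match: parasite node already collapsed")
    state.ops += 1
    kind = match.kind

    if kind == P_CODIVERGENCE:
        state.node_events[match.u] = EventRecord(
            kind=CODIVERGENCE, parasite_node=match.u, time_index=t, host_node=q
        )
        state._merge_parasite(match.u, match.p, match.sib, pos=q, anchor=q)
        return False

    if kind == P_DUPLICATION:
        h = state.rep_pos[match.p]
        state.node_events[match.u] = EventRecord(
            kind=DUPLICATION, parasite_node=match.u, time_index=t, edge=(q, h)
        )
        state._merge_parasite(match.u, match.p, match.sib, pos=h, anchor=h)
        return False

    # every remaining kind starts with the matched switch at u; the stay
    # child is whichever child sits on the takeoff side.
    x0 = match.takeoff_leaf
    takeoff_edge = (state.host.parent[x0], x0)
    if state.rep_pos[match.p] == x0:
        stay, jump = match.p, match.sib
    else:
        stay, jump = match.sib, match.p
    _record_switch(
        state, match.u, stay, jump, takeoff_edge, state.rep_pos[jump], t
    )
    state._merge_parasite(match.u, match.p, match.sib, pos=x0, anchor=x0)

    if kind == P_HOST_SWITCH:
        return False
    if kind == P_LOSS_SWITCH:
        state.collapse_host_cherry(cherry)
        return True
    if kind == P_CODIV_SWITCH:
        state.node_events[match.g] = EventRecord(
            kind=CODIVERGENCE, parasite_node=match.g, time_index=t, host_node=q
        )
        state._merge_parasite(match.g, match.u, match.w, pos=q, anchor=q)
        return False
    if kind == P_DUP_SWITCH:
        state.node_events[match.g] = EventRecord(
            kind=DUPLICATION, parasite_node=match.g, time_index=t, edge=takeoff_edge
        )
        state._merge_parasite(match.g, match.u, match.w, pos=x0, anchor=x0)
        return False
    if kind == P_DOUBLE_SWITCH:
        _record_switch(state, match.g, match.u, match.w, takeoff_edge, match.second_target, t)
        state._merge_parasite(match.g, match.u, match.w, pos=x0, anchor=x0)
        return False
    raise InputError(f"cannot apply pattern kind {kind!r}")


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def tree_collapse(
    tg: Tanglegram,
    ordering: Optional[NodeOrdering] = None,
    scheme: CostScheme = JUNGLE,
    config: CollapseConfig = CollapseConfig(),
) -> CophyloMapping:
    """Reconstruct a time-consistent mapping by cherry collapse.

    Three terminal states: (a) both trees collapse together and the last
    event is a codivergence at the host root; (b) the parasite finishes
    first and the remaining host is ignored; (c) the host finishes first and
    the remaining parasite nodes are appended above the host root as
    duplication events.
    """
    from .model import default_ordering  # local import to avoid cycle at import time

    if ordering is None:
        ordering = default_ordering(tg.host)
    if tg.host.n_internal == 0:
        raise StructureError("host tree with a single node cannot be processed")
    state = CollapseState(tg, ordering, config)

    if not state.parasite_done():
        for q in schedule_cherries(tg.host, ordering):
            state.ops += 1
            xq, yq = tg.host.children[q]
            cherry = Cherry(i_left=xq, i_right=yq, i_parent=q)
            while True:
                matches = detect_patterns(state, cherry, scheme)
                chosen = choose_pattern(matches)
                if chosen is None:
                    state.collapse_host_cherry(cherry)
                    break
                if apply_pattern(state, chosen):
                    break
            if state.parasite_done():
                break

    # terminal state (c): host exhausted, parasite structure remains.  Each
    # remaining pair is appended above the host root as a duplication —
    # unless a deep host switch between the two lineages' own positions is
    # cheaper than dragging both up to the root.
    if not state.parasite_done():
        _finish_above_root(state, tg, ordering, scheme)
        if not state.parasite_done():
            raise StructureError("collapse failed to exhaust the parasite tree")

    return assemble_mapping(tg, ordering, state.node_events, op_count=state.ops)


def _root_entry_losses(host: PhyloTree, side: dict) -> int:
    """Losses for one lineage descending from the synthetic root edge."""
    if side["kind"] == "node":
        return host.topo_depth(side["target"])
    top, _ = side["target"]
    if top is None:
        return 0
    return host.topo_depth(top) + 1


def _finish_above_root(state, tg, ordering, scheme: CostScheme) -> None:
    from .rightpush import best_switch_pair, build_la_index, _side_spec

    host = tg.host
    parasite = state.parasite
    root_edge = (None, host.root)
    la = build_la_index(host, ordering)
    progress = True
    while not state.parasite_done() and progress:
        progress = False
        for rep in sorted(state.live):
            par = parasite.parent[rep]
            if par is None:
                continue
            sib = parasite.sibling(rep)
            if sib not in state.live or par in state.node_events:
                continue
            sides = [
                _side_spec(parasite, tg.phi, state.node_events, rep, None),
                _side_spec(parasite, tg.phi, state.node_events, sib, None),
            ]
            dup_cost = scheme.w_duplication + scheme.w_loss * sum(
                _root_entry_losses(host, s) for s in sides
            )
            found = best_switch_pair(host, ordering, la, sides, floor=-1)
            if (
                found is not None
                and scheme.w_host_switch + scheme.w_loss * found[1] < dup_cost
            ):
                edges, _, t_star = found
                state.node_events[par] = EventRecord(
                    kind=HOST_SWITCH,
                    parasite_node=par,
                    time_index=max(t_star, 0),
                    takeoff_edge=edges[0],
                    landing_edge=edges[1],
                    takeoff_child=rep,
                    landing_child=sib,
                )
                anchor = edges[0][1]
            else:
                state.node_events[par] = EventRecord(
                    kind=DUPLICATION, parasite_node=par, time_index=0, edge=root_edge
                )
                anchor = host.root
            state._merge_parasite(par, rep, sib, pos=host.root, anchor=anchor)
            state.ops += 1
            progress = True
            break
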
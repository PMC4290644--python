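"""Switch relocation: push takeoff/landing edges toward the leaves.

The collapse engine records a host switch at the cherry where it was
detected, which can leave the landing edge far above the landed child's own
event and therefore over-count losses on the landed lineage.  Relocating
the pair of edges deeper — while keeping them inside a shared time interval
of the ordering — removes exactly those losses.  Moving the takeoff edge is
cost-neutral on its own side (losses shift between the parent's and the
child's segment one-for-one) but is what buys the landing edge room to
descend.

Relocation runs bottom-up over the parasite tree so every switch sees its
children's final positions; it never changes event kinds or their order,
only switch edges, switch times, and (implicitly) loss events.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .model import (
    CODIVERGENCE,
    DUPLICATION,
    HOST_SWITCH,
    CophyloMapping,
    EventRecord,
    InputError,
    NodeOrdering,
    PhyloTree,
    assemble_mapping,
)

__all__ = ["LAIndex", "build_la_index", "optimal_switch_edges", "right_push"]

Edge = Tuple[Optional[int], int]


class LAIndex:
    """Level-ancestor queries keyed by ordering depths.

    Jump-pointer (binary lifting) scheme: linear-ish preprocessing, O(log n)
    per query; the contract callers rely on is only "ancestor at a depth
    level, fast, after one preprocessing pass".
    """

    def __init__(self, host: PhyloTree, ordering: NodeOrdering) -> None:
        self.host = host
        self.ordering = ordering
        n = len(host)
        logn = max(1, (n - 1).bit_length())
        up = [[0] * n for _ in range(logn)]
        for v in range(n):
            p = host.parent[v]
            up[0][v] = v if p is None else p
        for k in range(1, logn):
            row, prev = up[k], up[k - 1]
            for v in range(n):
                row[v] = prev[prev[v]]
        self._up = up

    def query(self, node: int, q: int) -> int:
        """The unique ancestor ``a`` of ``node`` with ``d(a) <= q < d(child-on-path)``.

        If ``d(node) <= q`` the node itself is returned.
        """
        d = self.ordering.depth
        if d[node] <= q:
            return node
        v = node  # deepest node on the path with d(v) > q
        for k in range(len(self._up) - 1, -1, -1):
            anc = self._up[k][v]
            if d[anc] > q:
                v = anc
        parent = self.host.parent[v]
        assert parent is not None, "root has depth 0 <= q"
        return parent

    def edge_at(self, node: int, q: int) -> Edge:
        """The edge on the root-to-``node`` path whose top sits at level <= q.

        For ``q`` above the root's depth this is the synthetic root edge.
        """
        d = self.ordering.depth
        if d[node] <= q:
            return (self.host.parent[node], node)
        v = node
        for k in range(len(self._up) - 1, -1, -1):
            anc = self._up[k][v]
            if d[anc] > q:
                v = anc
        return (self.host.parent[v], v)


def build_la_index(host: PhyloTree, ordering: NodeOrdering) -> LAIndex:
    return LAIndex(host, ordering)


# ---------------------------------------------------------------------------
# Per-switch relocation
# ---------------------------------------------------------------------------

def _child_target(
    tg_parasite, phi: Dict[int, int], node_events: Dict[int, EventRecord], child: int
) -> Tuple[str, object, float]:
    """(target kind, target, time cap) for one switch child.

    Node targets (leaf phi / codivergence anchor) are approached from above;
    edge targets (the child's own duplication or takeoff edge) can be landed
    on exactly.  The cap is the child's own event time: the relocated switch
    may not postdate it.
    """
    if tg_parasite.is_leaf(child):
        return ("node", phi[child], float("inf"))
    ev = node_events[child]
    if ev.kind == CODIVERGENCE:
        return ("node", ev.host_node, float(ev.time_index))
    own = ev.edge if ev.kind == DUPLICATION else ev.takeoff_edge
    return ("edge", own, float(ev.time_index))


def _deepest_edge(
    host: PhyloTree, la: LAIndex, target_kind: str, target, level: float
) -> Edge:
    """Deepest edge toward the target whose top depth is <= level."""
    d = la.ordering.depth
    if target_kind == "node":
        node = target
        p = host.parent[node]
        if p is None or d[p] <= level:
            return (p, node)
        return la.edge_at(node, int(level))
    top, bottom = target
    if top is None or d[top] <= level:
        return (top, bottom)
    return la.edge_at(top, int(level))


def _side_losses(host: PhyloTree, target_kind: str, target, edge: Edge) -> int:
    """Losses on one descent segment for a candidate switch edge."""
    _, b = edge
    if target_kind == "node":
        return host.topo_depth(target) - host.topo_depth(b)
    top, _ = target
    if (edge[0], edge[1]) == (target[0], target[1]):
        return 0
    assert top is not None
    return host.topo_depth(top) - host.topo_depth(b) + 1


def _parent_floor(parasite: PhyloTree, node_events: Dict[int, EventRecord], p: int) -> int:
    """Time of the nearest ancestral event; the switch may not predate it."""
    parent = parasite.parent[p]
    while parent is not None:
        pev = node_events.get(parent)
        if pev is not None:
            return pev.time_index
        parent = parasite.parent[parent]
    return -1


def _side_spec(
    parasite: PhyloTree, phi: Dict[int, int], node_events: Dict[int, EventRecord],
    child: int, current: Optional[Edge],
) -> dict:
    kind, target, cap = _child_target(parasite, phi, node_events, child)
    return {"child": child, "kind": kind, "target": target, "cap": cap,
            "current": current}


def best_switch_pair(
    host: PhyloTree,
    ordering,
    la: LAIndex,
    sides: List[dict],
    floor: int,
) -> Optional[Tuple[List[Edge], int, int]]:
    """Deepest feasible (takeoff, landing) pair for two descent targets.

    Returns ``(edges, losses, t_star)`` or None when no pair of coexisting
    edges can serve both targets within the time caps.
    """
    level = min(s["cap"] for s in sides)
    edges = [_deepest_edge(host, la, s["kind"], s["target"], level) for s in sides]

    def span(e: Edge) -> Tuple[int, int]:
        return ordering.edge_span(e)

    # repair overlap: if one edge ends above the other's start, raise the
    # deeper side until the spans share an interval.
    for _ in range(2):
        (lo1, hi1), (lo2, hi2) = span(edges[0]), span(edges[1])
        if max(lo1, lo2, floor) < min(hi1, hi2):
            break
        if hi1 <= lo2:
            edges[1] = _deepest_edge(
                host, la, sides[1]["kind"], sides[1]["target"], hi1 - 1
            )
        elif hi2 <= lo1:
            edges[0] = _deepest_edge(
                host, la, sides[0]["kind"], sides[0]["target"], hi2 - 1
            )
        else:
            break

    (lo1, hi1), (lo2, hi2) = span(edges[0]), span(edges[1])
    t_star = max(lo1, lo2, floor)
    if edges[0] == edges[1]:
        return None
    if t_star >= min(hi1, hi2) or any(t_star > s["cap"] for s in sides):
        return None
    losses = sum(
        _side_losses(host, s["kind"], s["target"], e) for s, e in zip(sides, edges)
    )
    return edges, losses, t_star


def optimal_switch_edges(
    mapping: CophyloMapping, p: int, la: LAIndex
) -> Tuple[Edge, Edge, int]:
    """Best (takeoff, landing) edge pair for the switch at parasite node ``p``.

    Minimizes the losses between the pair and the two children's own
    positions, subject to the pair sharing a time interval and the switch
    time staying between the parent's and the children's event times.
    Returns the current pair if no strictly better feasible pair exists.
    """
    node_events = mapping.node_events()
    ev = node_events.get(p)
    if ev is None or ev.kind != HOST_SWITCH:
        raise InputError(f"parasite node {p} does not carry a host switch")
    tg = mapping.tanglegram
    host = tg.host
    floor = _parent_floor(tg.parasite, node_events, p)
    sides = [
        _side_spec(tg.parasite, tg.phi, node_events, ev.takeoff_child, ev.takeoff_edge),
        _side_spec(tg.parasite, tg.phi, node_events, ev.landing_child, ev.landing_edge),
    ]

    def pair_losses(pair: List[Edge]) -> int:
        return sum(
            _side_losses(host, s["kind"], s["target"], e)
            for s, e in zip(sides, pair)
        )

    current_pair = [sides[0]["current"], sides[1]["current"]]
    best_pair, best_losses = current_pair, pair_losses(current_pair)
    found = best_switch_pair(host, mapping.ordering, la, sides, floor)
    if found is not None and found[1] < best_losses:
        best_pair, best_losses = found[0], found[1]
    return best_pair[0], best_pair[1], best_losses


# ---------------------------------------------------------------------------
# Full pass
# ---------------------------------------------------------------------------

def right_push(mapping: CophyloMapping) -> CophyloMapping:
    """Relocate every host switch to its optimal edge pair, bottom-up.

    Codivergence/duplication/switch counts are untouched; only loss events
    (re-derived from the updated edges) can change, and never upward.
    Idempotent: a second pass finds every switch already optimal.
    """
    tg = mapping.tanglegram
    node_events = dict(mapping.node_events())
    if not any(ev.kind == HOST_SWITCH for ev in node_events.values()):
        return mapping
    la = build_la_index(tg.host, mapping.ordering)

    for node in tg.parasite.postorder():
        ev = node_events.get(node)
        if ev is None or ev.kind != HOST_SWITCH:
            continue
        snapshot = CophyloMapping(
            events=list(node_events.values()),
            placement=dict(mapping.placement),
            tanglegram=tg,
            ordering=mapping.ordering,
        )
        e_i, e_j, _ = optimal_switch_edges(snapshot, node, la)
        if (e_i, e_j) == (ev.takeoff_edge, ev.landing_edge):
            continue
        lo_i, _ = mapping.ordering.edge_span(e_i)
        lo_j, _ = mapping.ordering.edge_span(e_j)
        t_star = max(lo_i, lo_j, _parent_floor(tg.parasite, node_events, node), 0)
        node_events[node] = EventRecord(
            kind=HOST_SWITCH,
            parasite_node=node,
            time_index=t_star,
            takeoff_edge=e_i,
            landing_edge=e_j,
            takeoff_child=ev.takeoff_child,
            landing_child=ev.landing_child,
        )

    return assemble_mapping(tg, mapping.ordering, node_events, op_count=mapping.op_count)
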
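"""Reference reconstructions: switch-free reconciliation, edge-only mapping,
and an exact fixed-ordering dynamic program used as the package's oracle.

The DP explores states ``(parasite node, host edge, entry time)``: a
lineage enters a host edge at a time slice and may codiverge at the edge's
bottom node, pass it (a loss), duplicate in place, or switch to any other
edge whose time span overlaps.  It is exponential-free but deliberately
unoptimised and size-guarded — it exists to certify the greedy engine on
small instances, not to scale.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

from .model import (
    CODIVERGENCE,
    DUPLICATION,
    HOST_SWITCH,
    CophymapError,
    CophyloMapping,
    CostScheme,
    EventRecord,
    JUNGLE,
    NodeOrdering,
    PhyloTree,
    Tanglegram,
    assemble_mapping,
    default_ordering,
)

__all__ = [
    "SizeGuardError",
    "EXACT_DP_MAX_HOST_LEAVES",
    "page_reconcile",
    "edge_only_map",
    "exact_dp",
]

EXACT_DP_MAX_HOST_LEAVES = 12

Edge = Tuple[Optional[int], int]


class SizeGuardError(CophymapError):
    """The exact oracle refused an instance above its size guard."""


# ---------------------------------------------------------------------------
# Page-style switch-free reconciliation
# ---------------------------------------------------------------------------

def page_reconcile(
    tg: Tanglegram, ordering: Optional[NodeOrdering] = None
) -> CophyloMapping:
    """Optimal mapping when host switches are forbidden.

    Classical LCA reconciliation: each parasite node maps to the LCA of its
    children's images; a node whose image equals a child's image is a
    duplication, otherwise a codivergence.  Losses fall out of the shared
    segment accounting.  The result does not depend on the node ordering
    (none of codivergence/duplication/loss placement does), which is also
    asserted as a property in the tests.
    """
    host, parasite = tg.host, tg.parasite
    if ordering is None:
        ordering = default_ordering(host)
    image: Dict[int, int] = {}
    for node in parasite.postorder():
        if parasite.is_leaf(node):
            image[node] = tg.phi[node]
        else:
            a, b = parasite.children[node]
            image[node] = host.lca(image[a], image[b])

    node_events: Dict[int, EventRecord] = {}
    for node in parasite.internal_nodes():
        w = image[node]
        kids = parasite.children[node]
        if any(image[c] == w for c in kids) or host.is_leaf(w):
            edge = (host.parent[w], w)
            t = 0 if edge[0] is None else ordering.depth[edge[0]]
            node_events[node] = EventRecord(
                kind=DUPLICATION, parasite_node=node, time_index=t, edge=edge
            )
        else:
            node_events[node] = EventRecord(
                kind=CODIVERGENCE,
                parasite_node=node,
                time_index=ordering.depth[w],
                host_node=w,
            )
    return assemble_mapping(tg, ordering, node_events)


# ---------------------------------------------------------------------------
# Exact fixed-ordering DP
# ---------------------------------------------------------------------------

def _host_edges(host: PhyloTree) -> List[Edge]:
    edges: List[Edge] = [(None, host.root)]
    for v in range(len(host)):
        p = host.parent[v]
        if p is not None:
            edges.append((p, v))
    return edges


def exact_dp(
    tg: Tanglegram,
    ordering: Optional[NodeOrdering] = None,
    scheme: CostScheme = JUNGLE,
    max_host_leaves: int = EXACT_DP_MAX_HOST_LEAVES,
) -> Tuple[float, CophyloMapping]:
    """Minimum cost over all time-consistent mappings for a fixed ordering.

    Returns ``(cost, witness)``.  Instances above ``max_host_leaves`` are
    refused: this oracle is for verification, not analysis.
    """
    host, parasite = tg.host, tg.parasite
    if host.n_leaves > max_host_leaves:
        raise SizeGuardError(
            f"exact_dp refuses hosts with more than {max_host_leaves} leaves "
            f"(got {host.n_leaves})"
        )
    if ordering is None:
        ordering = default_ordering(host)
    d = ordering.depth
    edges = _host_edges(host)

    def span(e: Edge) -> Tuple[int, int]:
        top, bottom = e
        return (-1 if top is None else d[top]), d[bottom]

    w_c, w_d, w_s, w_l = (
        scheme.w_codivergence,
        scheme.w_duplication,
        scheme.w_host_switch,
        scheme.w_loss,
    )

    memo: Dict[Tuple[int, Edge, int], Tuple[float, tuple]] = {}

    def leaf_descent(p: int, v: int) -> float:
        target = tg.phi[p]
        if not host.is_ancestor(v, target):
            return math.inf
        steps = host.topo_depth(target) - host.topo_depth(v)
        return w_l * steps if steps else 0.0  # avoid inf * 0 under infinite w_l

    def f(p: int, e: Edge, tau: int) -> Tuple[float, tuple]:
        key = (p, e, tau)
        hit = memo.get(key)
        if hit is not None:
            return hit
        _, v = e
        if parasite.is_leaf(p):
            res = (leaf_descent(p, v), ("leaf",))
            memo[key] = res
            return res
        best = math.inf
        plan: tuple = ("stuck",)
        pl, pr = parasite.children[p]
        if not host.is_leaf(v):
            c1, c2 = host.children[v]
            for a, b in ((pl, pr), (pr, pl)):
                ca, _ = f(a, (v, c1), d[v])
                cb, _ = f(b, (v, c2), d[v])
                cost = w_c + ca + cb
                if cost < best:
                    best, plan = cost, ("codiv", v, a, b)
            for c in (c1, c2):
                cost, _ = f(p, (v, c), d[v])
                cost += w_l
                if cost < best:
                    best, plan = cost, ("pass", (v, c))
        ca, _ = f(pl, e, tau)
        cb, _ = f(pr, e, tau)
        if w_d + ca + cb < best:
            best, plan = w_d + ca + cb, ("dup", e, tau)
        hi_e = span(e)[1]
        for e2 in edges:
            if e2 == e:
                continue
            lo2, hi2 = span(e2)
            t_star = max(tau, lo2)
            if t_star >= hi_e or t_star >= hi2:
                continue
            for stay, jump in ((pl, pr), (pr, pl)):
                cs, _ = f(stay, e, t_star)
                cj, _ = f(jump, e2, t_star)
                cost = w_s + cs + cj
                if cost < best:
                    best, plan = cost, ("switch", e2, t_star, stay, jump)
        res = (best, plan)
        memo[key] = res
        return res

    best = math.inf
    best_start: Optional[Tuple[Edge, int]] = None
    for e in edges:
        lo, _ = span(e)
        tau0 = max(lo, -1)
        cost, _ = f(parasite.root, e, tau0)
        if cost < best:
            best, best_start = cost, (e, tau0)

    if not math.isfinite(best) or best_start is None:
        raise CophymapError("exact_dp found no feasible mapping")

    # Reconstruct a witness by replaying the memoised plans.
    node_events: Dict[int, EventRecord] = {}

    def rebuild(p: int, e: Edge, tau: int) -> None:
        _, plan = f(p, e, tau)
        kind = plan[0]
        if kind == "leaf":
            return
        if kind == "codiv":
            _, v, a, b = plan
            c1, c2 = host.children[v]
            node_events[p] = EventRecord(
                kind=CODIVERGENCE, parasite_node=p, time_index=d[v], host_node=v
            )
            rebuild(a, (v, c1), d[v])
            rebuild(b, (v, c2), d[v])
            return
        if kind == "pass":
            rebuild(p, plan[1], d[plan[1][0]])
            return
        if kind == "dup":
            _, de, dtau = plan
            node_events[p] = EventRecord(
                kind=DUPLICATION,
                parasite_node=p,
                time_index=max(dtau, 0),
                edge=de,
            )
            pl, pr = parasite.children[p]
            rebuild(pl, de, dtau)
            rebuild(pr, de, dtau)
            return
        if kind == "switch":
            _, e2, t_star, stay, jump = plan
            node_events[p] = EventRecord(
                kind=HOST_SWITCH,
                parasite_node=p,
                time_index=t_star,
                takeoff_edge=e,
                landing_edge=e2,
                takeoff_child=stay,
                landing_child=jump,
            )
            rebuild(stay, e, t_star)
            rebuild(jump, e2, t_star)
            return
        raise CophymapError("exact_dp witness reconstruction hit a dead state")

    if not parasite.is_leaf(parasite.root):
        rebuild(parasite.root, *best_start)
    witness = assemble_mapping(tg, ordering, node_events)
    return best, witness


def edge_only_map(
    tg: Tanglegram, ordering: Optional[NodeOrdering] = None
) -> CophyloMapping:
    """Cheapest mapping using only duplication and host-switch events.

    Realised by running the exact DP with codivergence and loss priced at
    infinity, which confines every lineage to the edges adjacent to the
    host leaves; the result upper-bounds any all-events optimum.
    """
    if ordering is None:
        ordering = default_ordering(tg.host)
    scheme = CostScheme(
        w_codivergence=math.inf, w_duplication=1.0, w_host_switch=2.0, w_loss=math.inf
    )
    _, witness = exact_dp(tg, ordering, scheme, max_host_leaves=10**9)
    return witness
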
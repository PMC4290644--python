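"""Synthetic cophylogenies: Yule host trees with a co-simulated parasite.

The host is a pure-birth tree.  The parasite is then evolved *down* the
host: lineages ride host edges and, at every host divergence they reach,
draw one of codivergence (track both daughters), loss (track one daughter),
duplication (two copies) or host switch (one copy stays, one jumps to a
uniformly chosen co-extant host edge).  Copies spawned at a divergence
resolve it with a codivergence-or-loss draw, so parasite growth stays
comparable to the host's.  Divergence times come from the host's default
ordering, so switch targets are alive at the moment of the jump and
generated histories are time-consistent by construction.

Event probabilities default to (0.5, 0.2, 0.15, 0.15); these defaults are
this package's own declared stand-in, not values taken from any reference
generator.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .model import (
    InputError,
    PhyloTree,
    Tanglegram,
    default_ordering,
)

__all__ = ["SimParams", "yule_tree", "evolve_parasite", "generate_instance"]

_EXTINCTION_RETRIES = 64


@dataclass(frozen=True)
class SimParams:
    n_host_leaves: int
    p_codiv: float = 0.5
    p_dup: float = 0.2
    p_switch: float = 0.15
    p_loss: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_codiv, self.p_dup, self.p_switch, self.p_loss)
        if any(p < 0 for p in probs):
            raise InputError("event probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise InputError(f"event probabilities must sum to 1, got {sum(probs)}")
        if self.n_host_leaves < 2:
            raise InputError("n_host_leaves must be >= 2")


def yule_tree(n_leaves: int, rng: random.Random, label_prefix: str = "H") -> PhyloTree:
    """Pure-birth tree: split a uniformly chosen extant lineage until done."""
    if n_leaves < 2:
        raise InputError("a Yule tree needs at least 2 leaves")
    parent: List[Optional[int]] = [None]
    children: List[Tuple[int, ...]] = [()]
    extant = [0]
    while len(extant) < n_leaves:
        idx = rng.randrange(len(extant))
        node = extant.pop(idx)
        a, b = len(parent), len(parent) + 1
        parent.extend([node, node])
        children.extend([(), ()])
        children[node] = (a, b)
        extant.extend([a, b])
    labels: List[Optional[str]] = [None] * len(parent)
    # deterministic labels by pre-order leaf rank
    count = 0
    stack = [0]
    while stack:
        v = stack.pop()
        if children[v]:
            stack.extend(reversed(children[v]))
        else:
            count += 1
            labels[v] = f"{label_prefix}{count}"
    return PhyloTree(parent, children, labels)


def _draw_event(params: SimParams, rng: random.Random, full_menu: bool) -> str:
    """One event draw; the restricted menu (codivergence/loss only) is used
    by lineages created at the divergence currently being resolved."""
    if full_menu:
        weights = [params.p_codiv, params.p_dup, params.p_switch, params.p_loss]
    else:
        weights = [params.p_codiv, 0.0, 0.0, params.p_loss]
    total = sum(weights)
    if total <= 0:
        return "codiv"
    r = rng.random() * total
    for kind, w in zip(("codiv", "dup", "switch", "loss"), weights):
        if r < w:
            return kind
        r -= w
    return "loss"


def evolve_parasite(
    host: PhyloTree,
    params: SimParams,
    rng: random.Random,
    record: Optional[List[dict]] = None,
) -> Tuple[PhyloTree, Dict[int, int]]:
    """Simulate one parasite tree over ``host``; returns ``(parasite, phi)``.

    ``phi`` maps parasite leaf ids to host leaf ids.  If ``record`` is given,
    one dict per simulated event is appended to it (a truth log for
    parameter-recovery experiments).
    """
    ordering = default_ordering(host)
    d = ordering.depth
    n_int = host.n_internal

    # parasite tree under construction
    p_parent: List[Optional[int]] = [None]
    p_children: List[Tuple[int, ...]] = [()]
    phi: Dict[int, int] = {}

    def new_node(par: int) -> int:
        idx = len(p_parent)
        p_parent.append(par)
        p_children.append(())
        return idx

    # lineages[i] = (parasite node id, host node whose edge the lineage is
    # riding), processed in host time-slice order so switch targets are
    # co-extant.  Each arrival at a divergence draws once from the full
    # event menu; a lineage born at the divergence itself (duplication copy,
    # switch stayer) resolves it with a codivergence/loss draw only, which
    # keeps parasite growth comparable to the host's own branching.
    node_at_depth = {d[v]: v for v in host.internal_nodes()}
    lineages: List[Tuple[int, int]] = [(0, host.root)]
    extant: Dict[int, bool] = {host.root: True}
    for tau in range(n_int):
        w = node_at_depth[tau]
        c1, c2 = host.children[w]
        extant.pop(w, None)
        extant[c1] = True
        extant[c2] = True
        still: List[Tuple[int, int]] = []
        others: List[Tuple[int, int]] = []
        queue: List[Tuple[int, bool]] = []
        for pn, hv in lineages:
            if hv == w:
                queue.append((pn, True))
            else:
                others.append((pn, hv))
        while queue:
            pn, full_menu = queue.pop(0)
            kind = _draw_event(params, rng, full_menu=full_menu)
            if kind == "codiv":
                a, b = new_node(pn), new_node(pn)
                p_children[pn] = (a, b)
                still.extend([(a, c1), (b, c2)])
            elif kind == "loss":
                side = c1 if rng.random() < 0.5 else c2
                still.append((pn, side))
            elif kind == "dup":
                a, b = new_node(pn), new_node(pn)
                p_children[pn] = (a, b)
                queue.extend([(a, False), (b, False)])
            else:  # switch
                targets = [v for v in extant if v != c1 and v != c2]
                if not targets:
                    side = c1 if rng.random() < 0.5 else c2
                    still.append((pn, side))
                    kind = "loss"
                else:
                    tgt = targets[rng.randrange(len(targets))]
                    a, b = new_node(pn), new_node(pn)
                    p_children[pn] = (a, b)
                    queue.append((a, False))
                    still.append((b, tgt))
            if record is not None:
                record.append({"time": tau, "host": w, "kind": kind})
        lineages = others + still

    for pn, hv in lineages:
        if not host.is_leaf(hv):
            raise InputError("simulation ended with a lineage on an internal host node")
        phi[pn] = hv

    labels: List[Optional[str]] = [None] * len(p_parent)
    count = 0
    stack = [0]
    while stack:
        v = stack.pop()
        if p_children[v]:
            stack.extend(reversed(p_children[v]))
        else:
            count += 1
            labels[v] = f"p{count}"
    parasite = PhyloTree(p_parent, p_children, labels)
    return parasite, phi


def generate_instance(params: SimParams) -> Tanglegram:
    """Yule host + co-evolved parasite; both trees end up with >= 2 nodes."""
    rng = random.Random(params.rng_seed)
    host = yule_tree(params.n_host_leaves, rng)
    for _ in range(_EXTINCTION_RETRIES):
        parasite, phi = evolve_parasite(host, params, rng)
        if parasite.n_leaves >= 2:
            return Tanglegram(host=host, parasite=parasite, phi=phi)
    raise InputError(
        "could not generate a parasite with >= 2 leaves; "
        "lower p_loss or raise n_host_leaves"
    )
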
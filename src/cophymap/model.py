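"""Core domain model: trees, tanglegrams, node orderings, events and mappings.

A host/parasite pair is analysed as the tuple ``(H, P, phi)`` where both
trees are rooted and strictly bifurcating and ``phi`` sends every parasite
leaf to exactly one host leaf.  Internal host nodes carry unique integer
depths (a *node ordering*) which totally order the host divergence times;
the ordering is what makes host-switch feasibility checkable with integer
interval comparisons.

Event histories (`CophyloMapping`) are stored root-first.  Loss events are
never asserted directly by the reconstruction engine: they are derived from
the event structure by :func:`derive_loss_events`, which walks every parent
to child lineage segment through the host tree and charges one loss per
internal host node passed without a divergence event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

__all__ = [
    "CophymapError",
    "StructureError",
    "InputError",
    "PhyloTree",
    "Tanglegram",
    "NodeOrdering",
    "Cherry",
    "EventRecord",
    "CophyloMapping",
    "CostScheme",
    "EventCounts",
    "JUNGLE",
    "CODIVERGENCE",
    "DUPLICATION",
    "HOST_SWITCH",
    "LOSS",
    "default_ordering",
    "validate_ordering",
    "schedule_cherries",
    "total_cost",
    "audit_time_consistency",
    "derive_loss_events",
    "assemble_mapping",
]


class CophymapError(Exception):
    """Base error for this package."""


class StructureError(CophymapError):
    """A tree or tanglegram violates a structural invariant."""


class InputError(CophymapError):
    """An operation received malformed or incomplete input."""


# Event kinds.
CODIVERGENCE = "codivergence"
DUPLICATION = "duplication"
HOST_SWITCH = "host_switch"
LOSS = "loss"

EVENT_KINDS = (CODIVERGENCE, DUPLICATION, HOST_SWITCH, LOSS)


class PhyloTree:
    """Rooted bifurcating tree with uniquely labelled leaves.

    Nodes are integer ids ``0..n-1``.  Every internal node has exactly two
    children; leaf labels are unique non-empty strings.  A tree with a
    single node (one leaf, no internal nodes) is representable but is
    rejected by the ordering/reconstruction machinery.
    """

    __slots__ = (
        "parent",
        "children",
        "labels",
        "root",
        "_topo_depth",
        "_tin",
        "_tout",
        "_leaf_for_label",
        "_up",
    )

    def __init__(
        self,
        parent: Sequence[Optional[int]],
        children: Sequence[Tuple[int, ...]],
        labels: Sequence[Optional[str]],
    ) -> None:
        self.parent = list(parent)
        self.children = [tuple(c) for c in children]
        self.labels = list(labels)
        roots = [i for i, p in enumerate(self.parent) if p is None]
        if len(roots) != 1:
            raise StructureError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._validate()
        self._index()
        self._up: Optional[List[List[int]]] = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_nested(cls, nested) -> "PhyloTree":
        """Build from nested 2-tuples of labels, e.g. ``(("A", "B"), "C")``."""
        parent: List[Optional[int]] = []
        children: List[Tuple[int, ...]] = []
        labels: List[Optional[str]] = []

        def build(spec, par: Optional[int]) -> int:
            idx = len(parent)
            parent.append(par)
            children.append(())
            labels.append(None)
            if isinstance(spec, str):
                labels[idx] = spec
            else:
                if len(spec) != 2:
                    raise StructureError("nested spec must be binary")
                left = build(spec[0], idx)
                right = build(spec[1], idx)
                children[idx] = (left, right)
            return idx

        build(nested, None)
        return cls(parent, children, labels)

    def _validate(self) -> None:
        n = len(self.parent)
        seen_labels = set()
        for i in range(n):
            kids = self.children[i]
            if len(kids) not in (0, 2):
                raise StructureError(
                    f"node {i} has {len(kids)} children; tree must be bifurcating"
                )
            if not kids:
                lab = self.labels[i]
                if not lab:
                    raise StructureError(f"leaf {i} has an empty label")
                if lab in seen_labels:
                    raise StructureError(f"duplicate leaf label {lab!r}")
                seen_labels.add(lab)
            for c in kids:
                if self.parent[c] != i:
                    raise StructureError("parent/child pointers disagree")

    def _index(self) -> None:
        n = len(self.parent)
        self._topo_depth = [0] * n
        self._tin = [0] * n
        self._tout = [0] * n
        self._leaf_for_label = {}
        clock = 0
        stack: List[Tuple[int, bool]] = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                self._tout[node] = clock
                clock += 1
                continue
            self._tin[node] = clock
            clock += 1
            stack.append((node, True))
            p = self.parent[node]
            self._topo_depth[node] = 0 if p is None else self._topo_depth[p] + 1
            for c in reversed(self.children[node]):
                stack.append((c, False))
            if not self.children[node]:
                self._leaf_for_label[self.labels[node]] = node

    # -- basic queries --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_for_label)

    @property
    def n_internal(self) -> int:
        return len(self.parent) - self.n_leaves

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def leaves(self) -> List[int]:
        return [i for i in range(len(self.parent)) if not self.children[i]]

    def internal_nodes(self) -> List[int]:
        return [i for i in range(len(self.parent)) if self.children[i]]

    def leaf_by_label(self, label: str) -> int:
        try:
            return self._leaf_for_label[label]
        except KeyError:
            raise InputError(f"no leaf labelled {label!r}") from None

    def leaf_labels(self) -> List[str]:
        return [self.labels[i] for i in self.leaves()]

    def topo_depth(self, node: int) -> int:
        return self._topo_depth[node]

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(self.children[node]):
                stack.append(c)

    def postorder(self) -> Iterator[int]:
        out: List[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self.children[node])
        return reversed(out)

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff ``a`` is an ancestor of ``b`` or ``a == b``."""
        return self._tin[a] <= self._tin[b] and self._tout[b] <= self._tout[a]

    def _lifting(self) -> List[List[int]]:
        if self._up is None:
            n = len(self.parent)
            logn = max(1, (n - 1).bit_length())
            up = [[0] * n for _ in range(logn)]
            for v in range(n):
                p = self.parent[v]
                up[0][v] = v if p is None else p
            for k in range(1, logn):
                row, prev = up[k], up[k - 1]
                for v in range(n):
                    row[v] = prev[prev[v]]
            self._up = up
        return self._up

    def lca(self, a: int, b: int) -> int:
        if self.is_ancestor(a, b):
            return a
        if self.is_ancestor(b, a):
            return b
        up = self._lifting()
        for k in range(len(up) - 1, -1, -1):
            anc = up[k][a]
            if not self.is_ancestor(anc, b):
                a = anc
        return self.parent[a]

    def path_up(self, lower: int, upper: int) -> List[int]:
        """Nodes from ``lower`` up to ``upper`` inclusive; upper must be an ancestor."""
        if not self.is_ancestor(upper, lower):
            raise InputError(f"node {upper} is not an ancestor of {lower}")
        out = [lower]
        node = lower
        while node != upper:
            node = self.parent[node]
            out.append(node)
        return out

    def sibling(self, node: int) -> int:
        p = self.parent[node]
        if p is None:
            raise InputError("root has no sibling")
        a, b = self.children[p]
        return b if node == a else a


@dataclass(frozen=True)
class Tanglegram:
    """The tuple ``(H, P, phi)``; phi maps parasite leaf ids to host leaf ids."""

    host: PhyloTree
    parasite: PhyloTree
    phi: Dict[int, int]

    def __post_init__(self) -> None:
        para_leaves = set(self.parasite.leaves())
        if set(self.phi) != para_leaves:
            missing = para_leaves - set(self.phi)
            extra = set(self.phi) - para_leaves
            raise StructureError(
                f"phi must be total on parasite leaves (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )
        host_leaves = set(self.host.leaves())
        for p, h in self.phi.items():
            if h not in host_leaves:
                raise StructureError(f"phi target {h} for parasite leaf {p} is not a host leaf")

    def phi_by_label(self) -> Dict[str, str]:
        return {
            self.parasite.labels[p]: self.host.labels[h] for p, h in self.phi.items()
        }


@dataclass(frozen=True)
class NodeOrdering:
    """Unique integer depths for host internal nodes; leaves share depth ``n_internal``."""

    depth: Dict[int, int]
    n_internal: int

    def of(self, node: int) -> int:
        return self.depth[node]

    def edge_span(self, edge: Tuple[Optional[int], int]) -> Tuple[int, int]:
        """Half-open time span ``[d(top), d(bottom))`` of a host edge.

        The synthetic edge above the root has span ``[-1, 0)``.
        """
        top, bottom = edge
        lo = -1 if top is None else self.depth[top]
        return lo, self.depth[bottom]


@dataclass(frozen=True)
class Cherry:
    i_left: int
    i_right: int
    i_parent: int


@dataclass
class EventRecord:
    """One event in a cophylogeny mapping.

    ``host_node`` anchors codivergences (and passed nodes for losses);
    duplications sit on ``edge``; host switches carry ``takeoff_edge`` /
    ``landing_edge`` plus which parasite child stayed and which one jumped.
    Edges are ``(top, bottom)`` host node pairs; ``top is None`` denotes the
    synthetic edge above the host root.
    """

    kind: str
    parasite_node: int
    time_index: int
    host_node: Optional[int] = None
    edge: Optional[Tuple[Optional[int], int]] = None
    takeoff_edge: Optional[Tuple[Optional[int], int]] = None
    landing_edge: Optional[Tuple[Optional[int], int]] = None
    takeoff_child: Optional[int] = None
    landing_child: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise InputError(f"unknown event kind {self.kind!r}")
        has_switch_edges = self.takeoff_edge is not None and self.landing_edge is not None
        if (self.kind == HOST_SWITCH) != has_switch_edges:
            raise InputError("takeoff/landing edges must be set iff kind is host_switch")

    def anchor_node(self) -> int:
        """Bottom-most host node identifying where the event sits."""
        if self.kind == CODIVERGENCE:
            assert self.host_node is not None
            return self.host_node
        if self.kind == DUPLICATION:
            assert self.edge is not None
            return self.edge[1]
        if self.kind == HOST_SWITCH:
            assert self.takeoff_edge is not None
            return self.takeoff_edge[1]
        assert self.host_node is not None
        return self.host_node


@dataclass(frozen=True)
class CostScheme:
    w_codivergence: float = 0.0
    w_duplication: float = 1.0
    w_host_switch: float = 2.0
    w_loss: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_codivergence", "w_duplication", "w_host_switch", "w_loss"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")

    def of(self, kind: str) -> float:
        return {
            CODIVERGENCE: self.w_codivergence,
            DUPLICATION: self.w_duplication,
            HOST_SWITCH: self.w_host_switch,
            LOSS: self.w_loss,
        }[kind]


#: Default per-event weights (0, 1, 2, 1): a switch is priced as a
#: duplication followed by a jump; codivergence is free.
JUNGLE = CostScheme()


@dataclass(frozen=True)
class EventCounts:
    n_codivergence: int = 0
    n_duplication: int = 0
    n_host_switch: int = 0
    n_loss: int = 0

    def __post_init__(self) -> None:
        for name in ("n_codivergence", "n_duplication", "n_host_switch", "n_loss"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")

    @classmethod
    def tally(cls, events: Iterable[EventRecord]) -> "EventCounts":
        c = d = s = l = 0
        for ev in events:
            if ev.kind == CODIVERGENCE:
                c += 1
            elif ev.kind == DUPLICATION:
                d += 1
            elif ev.kind == HOST_SWITCH:
                s += 1
            else:
                l += 1
        return cls(c, d, s, l)


def total_cost(counts: EventCounts, scheme: CostScheme = JUNGLE) -> float:
    return (
        scheme.w_codivergence * counts.n_codivergence
        + scheme.w_duplication * counts.n_duplication
        + scheme.w_host_switch * counts.n_host_switch
        + scheme.w_loss * counts.n_loss
    )


@dataclass
class CophyloMapping:
    """An ordered event history placing the parasite tree in the host tree.

    ``events`` is root-first: a parasite node's event never precedes its
    parent's event.  ``placement`` records the bottom-most host anchor of
    every parasite node (phi for leaves, the event anchor for internals).
    """

    events: List[EventRecord]
    placement: Dict[int, int]
    tanglegram: Tanglegram
    ordering: NodeOrdering
    op_count: int = 0

    def node_events(self) -> Dict[int, EventRecord]:
        return {
            ev.parasite_node: ev for ev in self.events if ev.kind != LOSS
        }

    def counts(self) -> EventCounts:
        return EventCounts.tally(self.events)

    def cost(self, scheme: CostScheme = JUNGLE) -> float:
        return total_cost(self.counts(), scheme)


# ---------------------------------------------------------------------------
# Node orderings
# ---------------------------------------------------------------------------

def default_ordering(host: PhyloTree) -> NodeOrdering:
    """Deterministic valid ordering: internal depths follow pre-order rank.

    Pre-order visits parents before children, so the rank of each internal
    node among internal nodes already satisfies parent < child.
    """
    if len(host) < 2:
        raise StructureError("host tree with a single node has no ordering")
    depth: Dict[int, int] = {}
    rank = 0
    for node in host.preorder():
        if not host.is_leaf(node):
            depth[node] = rank
            rank += 1
    n_internal = rank
    for leaf in host.leaves():
        depth[leaf] = n_internal
    return NodeOrdering(depth=depth, n_internal=n_internal)


def validate_ordering(host: PhyloTree, ordering: NodeOrdering) -> bool:
    """True iff ``ordering`` is a valid timing of ``host``.

    Raises :class:`InputError` (rather than returning False) when a host
    node is missing from the ordering altogether.
    """
    n_internal = host.n_internal
    for node in range(len(host)):
        if node not in ordering.depth:
            raise InputError(f"ordering is missing host node {node}")
    if ordering.n_internal != n_internal:
        return False
    internal_depths = sorted(ordering.depth[v] for v in host.internal_nodes())
    if internal_depths != list(range(n_internal)):
        return False
    for leaf in host.leaves():
        if ordering.depth[leaf] != n_internal:
            return False
    for node in host.internal_nodes():
        for child in host.children[node]:
            if ordering.depth[child] <= ordering.depth[node]:
                return False
    return ordering.depth[host.root] == 0


def schedule_cherries(host: PhyloTree, ordering: NodeOrdering) -> List[int]:
    """Internal host nodes in processing order: depth strictly descending.

    Processing deepest-first guarantees every internal node is a cherry of
    the partially collapsed tree when its turn comes.  Bucketing by depth
    keeps this linear in the host size.
    """
    if not validate_ordering(host, ordering):
        raise InputError("invalid node ordering")
    buckets: List[Optional[int]] = [None] * host.n_internal
    for node in host.internal_nodes():
        buckets[ordering.depth[node]] = node
    return [node for node in reversed(buckets) if node is not None]


# ---------------------------------------------------------------------------
# Loss derivation and mapping assembly
# ---------------------------------------------------------------------------

def _entry_edges(
    host: PhyloTree, ev: EventRecord, child_anchors: Tuple[int, int], children: Tuple[int, int]
) -> Dict[int, Tuple[Optional[int], int]]:
    """Host edge on which each parasite child lineage starts, given its parent event."""
    c1, c2 = children
    if ev.kind == CODIVERGENCE:
        w = ev.host_node
        assert w is not None
        side1, side2 = host.children[w]
        a1, a2 = child_anchors
        in1 = host.is_ancestor(side1, a1)
        in2 = host.is_ancestor(side2, a2)
        if in1 and in2:
            return {c1: (w, side1), c2: (w, side2)}
        if host.is_ancestor(side2, a1) and host.is_ancestor(side1, a2):
            return {c1: (w, side2), c2: (w, side1)}
        raise StructureError(
            f"codivergence at host {w}: children anchors {child_anchors} do not split"
        )
    if ev.kind == DUPLICATION:
        assert ev.edge is not None
        return {c1: ev.edge, c2: ev.edge}
    assert ev.kind == HOST_SWITCH
    assert ev.takeoff_edge is not None and ev.landing_edge is not None
    if ev.takeoff_child not in children or ev.landing_child not in children:
        raise StructureError("switch children do not match parasite topology")
    return {ev.takeoff_child: ev.takeoff_edge, ev.landing_child: ev.landing_edge}


def _segment_losses(
    host: PhyloTree,
    ordering: NodeOrdering,
    entry: Tuple[Optional[int], int],
    child: int,
    child_ev: Optional[EventRecord],
    child_anchor: int,
) -> List[EventRecord]:
    """Losses along one lineage segment from its entry edge to the child's event.

    One loss per internal host node the lineage passes through without an
    event: walking from the entry edge's bottom endpoint down to the node
    where the child's event sits (entering an edge counts its top node as
    passed; arriving at a codivergence or a leaf does not).
    """
    _, y = entry
    if child_ev is None or child_ev.kind == CODIVERGENCE:
        # target is a node (leaf phi target, or codivergence anchor)
        stop = child_anchor
        if y == stop:
            return []
        passed = host.path_up(stop, y)[1:]  # strictly above stop, up to and incl. y
    else:
        own = child_ev.edge if child_ev.kind == DUPLICATION else child_ev.takeoff_edge
        assert own is not None
        if own == entry:
            return []
        top = own[0]
        if top is None:
            raise StructureError("nested event on the synthetic root edge")
        passed = host.path_up(top, y)  # from y down to top inclusive of both
    losses = []
    for node in passed:
        if host.is_leaf(node):
            raise StructureError("lineage segment passes through a host leaf")
        losses.append(
            EventRecord(
                kind=LOSS,
                parasite_node=child,
                time_index=ordering.depth[node],
                host_node=node,
            )
        )
    losses.sort(key=lambda e: e.time_index)
    return losses


def derive_loss_events(
    tg: Tanglegram,
    ordering: NodeOrdering,
    node_events: Dict[int, EventRecord],
) -> List[EventRecord]:
    """All loss events implied by the non-loss event structure (root-first)."""
    ordered = assemble_mapping(tg, ordering, node_events).events
    return [ev for ev in ordered if ev.kind == LOSS]


def _anchor_of(
    tg: Tanglegram, node_events: Dict[int, EventRecord], node: int
) -> int:
    if tg.parasite.is_leaf(node):
        return tg.phi[node]
    return node_events[node].anchor_node()


def assemble_mapping(
    tg: Tanglegram,
    ordering: NodeOrdering,
    node_events: Dict[int, EventRecord],
    op_count: int = 0,
) -> CophyloMapping:
    """Build a full :class:`CophyloMapping` from per-internal-node events.

    ``node_events`` maps every parasite internal node to its codivergence,
    duplication or host-switch record.  Losses are derived per lineage
    segment and interleaved so that the event list stays root-first and a
    segment's losses appear between the parent's and the child's events.
    """
    parasite = tg.parasite
    host = tg.host
    for v in parasite.internal_nodes():
        if v not in node_events:
            raise InputError(f"no event supplied for parasite internal node {v}")

    events: List[EventRecord] = []
    placement: Dict[int, int] = {}

    def emit(node: int) -> None:
        if parasite.is_leaf(node):
            placement[node] = tg.phi[node]
            return
        ev = node_events[node]
        placement[node] = ev.anchor_node()
        events.append(ev)
        kids = parasite.children[node]
        anchors = tuple(_anchor_of(tg, node_events, c) for c in kids)
        entries = _entry_edges(host, ev, anchors, kids)  # type: ignore[arg-type]
        for c, anchor in zip(kids, anchors):
            child_ev = None if parasite.is_leaf(c) else node_events[c]
            events.extend(
                _segment_losses(host, ordering, entries[c], c, child_ev, anchor)
            )
            emit(c)

    root = parasite.root
    if not parasite.is_leaf(root):
        emit(root)
    else:
        placement[root] = tg.phi[root]
    return CophyloMapping(
        events=events,
        placement=placement,
        tanglegram=tg,
        ordering=ordering,
        op_count=op_count,
    )


# ---------------------------------------------------------------------------
# Time-consistency audit
# ---------------------------------------------------------------------------

def audit_time_consistency(mapping: CophyloMapping) -> bool:
    """Check that the event history is biologically feasible.

    (a) The ordered list respects parasite topology: no node's event
    precedes its parent's event, and times never decrease root-to-leaf.
    (b) Every host switch's time index lies in the half-open spans of both
    its takeoff and landing edges, i.e. the two edges coexist.
    """
    parasite = mapping.tanglegram.parasite
    ordering = mapping.ordering
    pos: Dict[int, int] = {}
    for i, ev in enumerate(mapping.events):
        if ev.kind != LOSS:
            if ev.parasite_node in pos:
                return False  # two events for one parasite node
            pos[ev.parasite_node] = i
    for node, i in pos.items():
        p = parasite.parent[node]
        while p is not None and p not in pos:
            p = parasite.parent[p]
        if p is not None:
            if pos[p] > i:
                return False
            ev_p = mapping.events[pos[p]]
            ev_n = mapping.events[i]
            if ev_p.time_index > ev_n.time_index:
                return False
    for ev in mapping.events:
        if ev.kind != HOST_SWITCH:
            continue
        assert ev.takeoff_edge is not None and ev.landing_edge is not None
        lo1, hi1 = mapping.ordering.edge_span(ev.takeoff_edge)
        lo2, hi2 = mapping.ordering.edge_span(ev.landing_edge)
        t = ev.time_index
        if not (lo1 <= t < hi1 and lo2 <= t < hi2):
            return False
    return True
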
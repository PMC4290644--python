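"""Readers and writers: Newick trees, TSV leaf associations, JSON reports."""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Tuple

import dendropy

from .model import (
    CophyloMapping,
    CostScheme,
    EventCounts,
    InputError,
    JUNGLE,
    PhyloTree,
    StructureError,
    Tanglegram,
    total_cost,
)

__all__ = [
    "read_newick",
    "write_newick",
    "read_association_tsv",
    "read_tanglegram",
    "write_report",
]


def read_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick statement into a :class:`PhyloTree`.

    Branch lengths and internal labels are parsed and discarded: node
    identity is structural and timing comes from node orderings, never from
    branch lengths.  Polytomies and duplicate leaf labels are rejected.
    """
    text = text.strip()
    if not text:
        raise InputError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise InputError(f"Newick parse error: {exc}") from exc

    parent: List[Optional[int]] = []
    children: List[Tuple[int, ...]] = []
    labels: List[Optional[str]] = []

    def build(dnode, par: Optional[int]) -> int:
        idx = len(parent)
        parent.append(par)
        children.append(())
        labels.append(None)
        kids = dnode.child_nodes()
        if not kids:
            lab = dnode.taxon.label if dnode.taxon else dnode.label
            labels[idx] = lab
        else:
            if len(kids) != 2:
                names = ",".join(
                    (k.taxon.label if k.taxon else (k.label or "?")) for k in kids
                )
                raise StructureError(
                    f"polytomy ({len(kids)} children) at clade ({names})"
                )
            children[idx] = tuple(build(k, idx) for k in kids)
        return idx

    build(dtree.seed_node, None)
    return PhyloTree(parent, children, labels)


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree; ``read_newick(write_newick(t))`` is isomorphic to ``t``."""
    if len(tree) == 0:
        raise InputError("cannot serialize an empty tree")

    def fmt(node: int) -> str:
        if tree.is_leaf(node):
            return tree.labels[node]
        a, b = tree.children[node]
        return f"({fmt(a)},{fmt(b)})"

    return fmt(tree.root) + ";"


def read_association_tsv(text: str) -> Dict[str, str]:
    """Parse ``parasite<TAB>host`` rows; '#' lines are comments.

    Each parasite leaf must appear exactly once.
    """
    phi: Dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(
                f"association line {lineno}: expected 'parasite<TAB>host', got {raw!r}"
            )
        p, h = (s.strip() for s in parts)
        if not p or not h:
            raise InputError(f"association line {lineno}: empty label")
        if p in phi:
            raise InputError(
                f"parasite leaf {p!r} associated more than once "
                "(each parasite may inhabit only a single host)"
            )
        phi[p] = h
    return phi


def read_tanglegram(host_text: str, parasite_text: str, assoc_text: str) -> Tanglegram:
    host = read_newick(host_text)
    parasite = read_newick(parasite_text)
    rows = read_association_tsv(assoc_text)
    host_labels = set(host.leaf_labels())
    parasite_labels = set(parasite.leaf_labels())
    unknown = sorted(set(rows) - parasite_labels) + sorted(
        {h for h in rows.values() if h not in host_labels}
    )
    if unknown:
        raise InputError(f"association names unknown leaf label(s): {unknown}")
    missing = sorted(parasite_labels - set(rows))
    if missing:
        raise InputError(f"no association row for parasite leaf/leaves: {missing}")
    phi = {
        parasite.leaf_by_label(p): host.leaf_by_label(h) for p, h in rows.items()
    }
    return Tanglegram(host=host, parasite=parasite, phi=phi)


def _node_name(tree: PhyloTree, node: Optional[int], prefix: str) -> Optional[str]:
    """Stable human-readable node identifier: leaf label, or sorted leafset path."""
    if node is None:
        return None
    if tree.is_leaf(node):
        return tree.labels[node]
    stack = [node]
    labs: List[str] = []
    while stack:
        v = stack.pop()
        if tree.is_leaf(v):
            labs.append(tree.labels[v])
        else:
            stack.extend(tree.children[v])
    return prefix + "(" + "|".join(sorted(labs)) + ")"


def write_report(
    mapping: CophyloMapping,
    scheme: CostScheme = JUNGLE,
    config: Optional[Dict[str, object]] = None,
) -> str:
    """Serialize a mapping as a JSON report with stable key order.

    Counts and total cost are re-tallied from the event list, never copied
    from upstream state.
    """
    tg = mapping.tanglegram
    host, parasite = tg.host, tg.parasite

    def edge_json(edge):
        if edge is None:
            return None
        top, bottom = edge
        return {
            "top": _node_name(host, top, "host:"),
            "bottom": _node_name(host, bottom, "host:"),
        }

    events = []
    for ev in mapping.events:
        events.append(
            {
                "kind": ev.kind,
                "parasite": _node_name(parasite, ev.parasite_node, "para:"),
                "host": _node_name(host, ev.host_node, "host:"),
                "edge": edge_json(ev.edge),
                "takeoff_edge": edge_json(ev.takeoff_edge),
                "landing_edge": edge_json(ev.landing_edge),
                "time_index": ev.time_index,
            }
        )
    counts = EventCounts.tally(mapping.events)
    doc = {
        "events": events,
        "counts": {
            "codivergence": counts.n_codivergence,
            "duplication": counts.n_duplication,
            "host_switch": counts.n_host_switch,
            "loss": counts.n_loss,
        },
        "total_cost": total_cost(counts, scheme),
        "scheme": {
            "codivergence": scheme.w_codivergence,
            "duplication": scheme.w_duplication,
            "host_switch": scheme.w_host_switch,
            "loss": scheme.w_loss,
        },
        "ordering": {
            _node_name(host, node, "host:"): d
            for node, d in sorted(mapping.ordering.depth.items())
        },
        "op_count": mapping.op_count,
        "config": dict(config or {}),
    }
    return json.dumps(doc, indent=2, sort_keys=False)
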
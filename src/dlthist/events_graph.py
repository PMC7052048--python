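"""Events graphs and species-tree independence of the rDT-SL model.

In the ranked duplication-transfer model where every speciation is followed
by the loss of one lineage (rDT-SL), the number of histories of a given
size is the same for every ranked species tree with ``k`` leaves.  The
proof device is the *events graph* of a time-sliced tree: its nodes are the
sliced-tree nodes, each labeled by the set of extant leaves (numbered 1..k
left to right) reachable below it; speciation edges point to children,
every node carries a duplication self-loop, and within each time slice the
transfer edges form a complete directed graph.

A history can then be encoded as an ordered unary-binary tree whose nodes
carry ``(time slice, leftmost extant leaf)`` pairs -- loss leaves removed.
Since any slice's label sets partition {1..k}, the same encoded tree can be
decoded against the events graph of *any* ranked tree of size ``k``, which
transports histories bijectively between species trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .counting import CountTables, ModelSpec, build_count_tables
from .histories import (
    DUPLICATION,
    EXTANT,
    LOSS,
    SPECIATION,
    TRANSFER,
    History,
    HistoryNode,
    validate_history,
)
from .species_trees import SlicedNode, TimeSlicedTree, TreeError

__all__ = [
    "EventsGraph",
    "EncNode",
    "EncodedHistory",
    "build_events_graph",
    "count_dtsl",
    "encode_history",
    "decode_history",
    "transport_history",
    "grow_histories",
]


class EventsGraph:
    """Directed multigraph of possible gene moves over a time-sliced tree."""

    def __init__(
        self,
        sliced: TimeSlicedTree,
        include_duplication: bool = True,
        include_transfer: bool = True,
    ):
        self.sliced = sliced
        self.k = sliced.k
        leaves = sliced.leaves()  # left-to-right order
        self.leaf_index = {leaf.label: i + 1 for i, leaf in enumerate(leaves)}
        self.graph = nx.MultiDiGraph()
        self._leafset: dict[SlicedNode, frozenset[int]] = {}
        for node in sliced.postorder():
            if node.is_leaf:
                self._leafset[node] = frozenset({self.leaf_index[node.label]})
            else:
                self._leafset[node] = frozenset().union(
                    *(self._leafset[c] for c in node.children)
                )
        for node in sliced.postorder():
            self.graph.add_node(
                node.label,
                slice=node.slice,
                leaves=self._leafset[node],
            )
        for node in sliced.postorder():
            for child in node.children:
                self.graph.add_edge(node.label, child.label, kind="speciation")
            if include_duplication:
                self.graph.add_edge(node.label, node.label, kind="duplication")
            if include_transfer:
                for other in sliced.incomparable(node):
                    self.graph.add_edge(node.label, other.label, kind="transfer")

    def leafset(self, node: SlicedNode) -> frozenset[int]:
        return self._leafset[node]

    def node_for(self, slice_index: int, leaf: int) -> SlicedNode:
        """The unique node of a slice whose label set contains ``leaf``."""
        for node in self.sliced.slice_of(slice_index):
            if leaf in self._leafset[node]:
                return node
        raise TreeError(f"no node of slice {slice_index} contains leaf {leaf}")

    def to_dot(self) -> str:
        """GraphViz DOT export (edge style per event kind)."""
        style = {"speciation": "solid", "duplication": "dashed", "transfer": "dotted"}
        lines = ["digraph events {"]
        for label, data in self.graph.nodes(data=True):
            leaves = ",".join(map(str, sorted(data["leaves"])))
            lines.append(
                f'  "{label}" [label="{label}\\n{{{leaves}}} t={data["slice"]}"];'
            )
        for u, v, data in self.graph.edges(data=True):
            lines.append(f'  "{u}" -> "{v}" [style={style[data["kind"]]}];')
        lines.append("}")
        return "\n".join(lines)


def build_events_graph(
    sliced: TimeSlicedTree,
    include_duplication: bool = True,
    include_transfer: bool = True,
) -> EventsGraph:
    """Build the events graph (flags drop duplication or transfer edges)."""
    return EventsGraph(sliced, include_duplication, include_transfer)


def count_dtsl(sliced: TimeSlicedTree, n_max: int) -> CountTables:
    """rDT-SL counting tables (speciations keep exactly one lineage)."""
    return build_count_tables(sliced, ModelSpec("rDT-SL"), n_max)


# ---------------------------------------------------------------------------
# Encoding, decoding and transport of rDT-SL histories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EncNode:
    """Encoded history node: time slice, leftmost extant leaf, children."""

    slice: int
    leaf: int
    children: tuple["EncNode", ...] = ()


@dataclass(frozen=True)
class EncodedHistory:
    """Loss-free, graph-label encoding of an rDT-SL history."""

    root: EncNode
    k: int

    @property
    def size(self) -> int:
        def rec(n: EncNode) -> int:
            return 1 if not n.children else sum(rec(c) for c in n.children)

        return rec(self.root)


def encode_history(h: History, graph: EventsGraph) -> EncodedHistory:
    """Strip loss leaves and label each node by (slice, leftmost leaf)."""
    report = validate_history(h, graph.sliced, ModelSpec("rDT-SL"))
    if report:
        raise TreeError("invalid rDT-SL history: " + "; ".join(report))
    sliced = graph.sliced

    def rec(x: HistoryNode) -> EncNode:
        node = sliced.node(x.species)
        kids = tuple(rec(c) for c in x.children if c.event != LOSS)
        if x.event == EXTANT:
            return EncNode(sliced.k, graph.leaf_index[x.species])
        leftmost = kids[0].leaf
        return EncNode(node.slice, leftmost, kids)

    return EncodedHistory(rec(h.root), sliced.k)


def decode_history(enc: EncodedHistory, graph: EventsGraph) -> History:
    """Rebuild the rDT-SL history encoded by ``enc`` over ``graph``'s tree.

    Loss leaves are reinserted deterministically: a speciation at a binary
    sliced node loses exactly the child not containing the surviving
    lineage.
    """
    if enc.k != graph.k:
        raise TreeError(f"size mismatch: encoding k={enc.k}, graph k={graph.k}")
    sliced = graph.sliced

    def rec(x: EncNode) -> HistoryNode:
        node = graph.node_for(x.slice, x.leaf)
        if not x.children:
            if x.slice != sliced.k:
                raise TreeError("extant leaf not in the leaf slice")
            return HistoryNode(EXTANT, node.label, ())
        if len(x.children) == 1:
            (c,) = x.children
            if c.slice != x.slice + 1:
                raise TreeError("speciation child not in the next time slice")
            target = graph.node_for(c.slice, c.leaf)
            if target.parent is not node:
                raise TreeError(
                    f"{target.label} is not a child of {node.label}; "
                    "not a speciation edge"
                )
            if len(node.children) == 1:
                return HistoryNode(SPECIATION, node.label, (rec(c),))
            kids = []
            for child in node.children:
                if child is target:
                    kids.append(rec(c))
                else:
                    kids.append(HistoryNode(LOSS, child.label, ()))
            return HistoryNode(SPECIATION, node.label, tuple(kids))
        a, b = x.children
        if a.slice != x.slice or b.slice != x.slice:
            raise TreeError("binary node children must stay in the slice")
        ta = graph.node_for(a.slice, a.leaf)
        tb = graph.node_for(b.slice, b.leaf)
        if ta is not node:
            raise TreeError("original copy must stay on the donor branch")
        event = DUPLICATION if tb is node else TRANSFER
        return HistoryNode(event, node.label, (rec(a), rec(b)))

    return History(rec(enc.root))


def transport_history(
    enc: EncodedHistory, src: EventsGraph, dst: EventsGraph
) -> History:
    """Carry an encoded history of ``src``'s tree onto ``dst``'s tree.

    Slices are matched by index and leaf-set membership only; the result is
    a valid rDT-SL history for the destination tree, and transporting back
    returns the original history (the correspondence is a bijection).
    """
    if src.k != dst.k:
        raise TreeError(f"size mismatch: src k={src.k}, dst k={dst.k}")
    return decode_history(enc, dst)


# ---------------------------------------------------------------------------
# Remark-style growing oracle: enumerate histories by walking graph edges
# ---------------------------------------------------------------------------


def grow_histories(graph: EventsGraph, n: int, max_n: int = 6) -> list[History]:
    """All rDT-SL histories of size ``n``, generated over the events graph.

    Independent enumeration path used as an oracle: leaves of a partial
    history are iteratively expanded along speciation, duplication and
    transfer edges of the graph, instead of expanding the history grammar
    on the sliced tree.  Tiny sizes only.
    """
    if n > max_n:
        raise ValueError(f"growing oracle capped at n <= {max_n}")
    sliced = graph.sliced
    k = graph.k
    memo: dict[tuple, tuple[HistoryNode, ...]] = {}

    def grow(label: str, m: int) -> tuple[HistoryNode, ...]:
        key = (label, m)
        if key in memo:
            return memo[key]
        g = graph.graph
        node = sliced.node(label)
        out: list[HistoryNode] = []
        if node.slice == k and m == 1:
            out.append(HistoryNode(EXTANT, label, ()))
        for _, target, data in g.out_edges(label, data=True):
            kind = data["kind"]
            if kind == "speciation":
                # one lineage survives through this child; siblings are lost
                for sub in grow(target, m):
                    kids = []
                    for child in node.children:
                        if child.label == target:
                            kids.append(sub)
                        else:
                            kids.append(HistoryNode(LOSS, child.label, ()))
                    out.append(HistoryNode(SPECIATION, label, tuple(kids)))
            elif kind == "duplication":
                for i in range(1, m):
                    for a in grow(label, i):
                        for b in grow(label, m - i):
                            out.append(HistoryNode(DUPLICATION, label, (a, b)))
            elif kind == "transfer":
                for i in range(1, m):
                    for a in grow(label, i):
                        for b in grow(target, m - i):
                            out.append(HistoryNode(TRANSFER, label, (a, b)))
        memo[key] = tuple(out)
        return memo[key]

    return [History(r) for r in grow(sliced.root.label, n)]
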
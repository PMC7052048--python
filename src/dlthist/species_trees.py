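"""Species trees, rankings and time-sliced trees.

A species tree here is a rooted binary tree with a unique label on every
node.  The label set is totally ordered (plain string comparison) and the
two children of every internal node are stored left-to-right in increasing
label order, so the tree is effectively ordered.  A *ranking* assigns the
ranks ``1..k-1`` to the internal nodes (ancestors before descendants, the
root always rank 1) and rank ``k`` to every leaf; it models the relative
order of speciation events.  Subdividing every edge that crosses a rank
boundary yields the unary-binary *time-sliced tree*, whose slice ``i``
contains exactly ``i`` contemporaneous lineages.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Optional, Union

import dendropy

__all__ = [
    "Node",
    "SpeciesTree",
    "Ranking",
    "SlicedNode",
    "TimeSlicedTree",
    "TreeError",
    "parse_newick",
    "to_newick",
    "make_caterpillar",
    "make_complete_binary",
    "make_balanced",
    "random_topology",
    "enumerate_topologies",
    "wedderburn_etherington",
    "random_ranking",
    "enumerate_rankings",
    "count_rankings",
    "build_time_slices",
    "incomparable",
]


class TreeError(ValueError):
    """Raised for malformed trees, labels or rankings."""


class Node:
    """A node of a species tree (binary internal node or leaf)."""

    __slots__ = ("label", "children", "parent")

    def __init__(self, label: str, children: tuple["Node", ...] = ()):
        self.label = label
        self.children = children
        self.parent: Optional[Node] = None
        for c in children:
            c.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def left(self) -> "Node":
        return self.children[0]

    @property
    def right(self) -> "Node":
        return self.children[1]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r})"


class SpeciesTree:
    """Rooted binary species tree with uniquely labeled, label-ordered nodes."""

    def __init__(self, root: Node):
        self.root = root
        self._order_children(root)
        self.nodes: list[Node] = list(self._postorder(root))
        self.by_label: dict[str, Node] = {}
        for node in self.nodes:
            if node.label in self.by_label:
                raise TreeError(f"duplicate node label {node.label!r}")
            self.by_label[node.label] = node
        for node in self.nodes:
            if node.children and len(node.children) != 2:
                raise TreeError(
                    f"node {node.label!r} has {len(node.children)} children; "
                    "species trees must be binary"
                )
        self._incomparable: dict[Node, tuple[Node, ...]] = {}
        self._depth: dict[Node, int] = {}
        self._fill_depth(root, 0)

    # -- construction helpers -------------------------------------------------

    def _order_children(self, node: Node) -> None:
        if node.children:
            for c in node.children:
                self._order_children(c)
            node.children = tuple(sorted(node.children, key=lambda c: c.label))
            for c in node.children:
                c.parent = node

    @staticmethod
    def _postorder(node: Node) -> Iterator[Node]:
        stack = [(node, False)]
        while stack:
            cur, expanded = stack.pop()
            if expanded:
                yield cur
            else:
                stack.append((cur, True))
                for c in reversed(cur.children):
                    stack.append((c, False))

    def _fill_depth(self, node: Node, d: int) -> None:
        self._depth[node] = d
        for c in node.children:
            self._fill_depth(c, d + 1)

    # -- queries --------------------------------------------------------------

    @property
    def k(self) -> int:
        """Number of leaves (extant species)."""
        return sum(1 for n in self.nodes if n.is_leaf)

    def leaves(self) -> list[Node]:
        """Leaves in left-to-right tree order."""
        return [n for n in self.postorder_left_to_right() if n.is_leaf]

    def postorder(self) -> list[Node]:
        return self.nodes

    def postorder_left_to_right(self) -> list[Node]:
        out: list[Node] = []

        def rec(n: Node) -> None:
            for c in n.children:
                rec(c)
            out.append(n)

        rec(self.root)
        return out

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.nodes if not n.is_leaf]

    def node(self, label: str) -> Node:
        try:
            return self.by_label[label]
        except KeyError:
            raise TreeError(f"unknown node label {label!r}") from None

    def is_ancestor(self, u: Node, v: Node) -> bool:
        """True iff ``u`` is a (strict or equal) ancestor of ``v``."""
        while v is not None:
            if v is u:
                return True
            v = v.parent
        return False

    def incomparable(self, u: Node) -> tuple[Node, ...]:
        """All nodes neither ancestral nor descendant to ``u`` (leaves included)."""
        if u not in self._incomparable:
            self._incomparable[u] = tuple(
                v
                for v in self.nodes
                if not self.is_ancestor(u, v) and not self.is_ancestor(v, u)
            )
        return self._incomparable[u]

    def newick(self) -> str:
        return to_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({self.newick()!r})"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _auto_label(node: Node) -> None:
    """Label unlabeled internal nodes deterministically.

    The label is ``'@' + smallest leaf label + subtree leaf count``.  Two
    comparable nodes differ in leaf count and two incomparable nodes have
    disjoint leaf sets (hence distinct smallest leaves), so this never
    collides with another auto label; the ``@`` prefix keeps it clear of
    user-supplied names.
    """
    for c in node.children:
        _auto_label(c)
    if node.children and not node.label:
        labels = _leaf_labels_below(node)
        node.label = f"@{min(labels)}{len(labels)}"


def _leaf_labels_below(node: Node) -> list[str]:
    if node.is_leaf:
        return [node.label]
    out: list[str] = []
    for c in node.children:
        out.extend(_leaf_labels_below(c))
    return out


def parse_newick(text: str) -> SpeciesTree:
    """Parse a Newick string into a :class:`SpeciesTree`.

    Branch lengths are parsed but ignored; unlabeled internal nodes are
    auto-labeled (see :func:`_auto_label`).  Non-binary nodes and duplicate
    labels are rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=False,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        kids = dnode.child_nodes()
        if kids and len(kids) != 2:
            raise TreeError(
                f"non-binary node with {len(kids)} children in Newick input"
            )
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        if not kids and not label:
            raise TreeError("leaf without a label in Newick input")
        return Node(label or "", tuple(convert(c) for c in kids))

    root = convert(dtree.seed_node)
    _auto_label(root)
    return SpeciesTree(root)


def to_newick(tree: SpeciesTree) -> str:
    """Canonical Newick form (children in increasing label order)."""

    def rec(node: Node) -> str:
        if node.is_leaf:
            return node.label
        inner = ",".join(rec(c) for c in node.children)
        return f"({inner}){node.label}"

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Canonical tree families
# ---------------------------------------------------------------------------


def _leaf_labels(k: int) -> list[str]:
    if k <= 26:
        return [chr(ord("A") + i) for i in range(k)]
    width = len(str(k))
    return [f"L{i:0{width}d}" for i in range(1, k + 1)]


def _attach_labels(shape, labels: Iterator[str]) -> Node:
    """Turn a nested-pair shape into a labeled tree (leaves left to right)."""
    if shape == 1 or shape == ():
        return Node(next(labels))
    left = _attach_labels(shape[0], labels)
    right = _attach_labels(shape[1], labels)
    node = Node("", (left, right))
    return node


def _finish(root: Node) -> SpeciesTree:
    _auto_label(root)
    return SpeciesTree(root)


def make_caterpillar(k: int) -> SpeciesTree:
    """The caterpillar CT_k: CT_1 is a leaf, CT_k has left subtree CT_{k-1}."""
    if k < 1:
        raise TreeError("caterpillar size must be >= 1")
    labels = _leaf_labels(k)
    node = Node(labels[0])
    for lab in labels[1:]:
        node = Node("", (node, Node(lab)))
    return _finish(node)


def make_complete_binary(h: int) -> SpeciesTree:
    """The complete binary tree CB_h with 2**h leaves, all at depth h."""
    if h < 0:
        raise TreeError("complete binary height must be >= 0")
    labels = iter(_leaf_labels(2**h))

    def build(d: int) -> Node:
        if d == 0:
            return Node(next(labels))
        return Node("", (build(d - 1), build(d - 1)))

    return _finish(build(h))


def make_balanced(k: int) -> SpeciesTree:
    """A balanced tree: left/right leaf counts differ by at most one everywhere."""
    if k < 1:
        raise TreeError("balanced tree size must be >= 1")
    labels = iter(_leaf_labels(k))

    def build(m: int) -> Node:
        if m == 1:
            return Node(next(labels))
        left = build((m + 1) // 2)
        right = build(m // 2)
        return Node("", (left, right))

    return _finish(build(k))


# ---------------------------------------------------------------------------
# Random topologies (uniform over unordered binary shapes)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def wedderburn_etherington(n: int) -> int:
    """Number of distinct unordered binary tree shapes with ``n`` leaves."""
    if n < 1:
        return 0
    if n == 1:
        return 1
    total = 0
    for i in range(1, n // 2 + (0 if n % 2 == 0 else 1)):
        if i < n - i:
            total += wedderburn_etherington(i) * wedderburn_etherington(n - i)
    if n % 2 == 0:
        w = wedderburn_etherington(n // 2)
        total += w * (w + 1) // 2
    return total


def _unrank_shape(n: int, idx: int):
    """idx-th unordered shape with ``n`` leaves, as nested pairs (leaf = 1)."""
    if n == 1:
        return 1
    for i in range(1, n // 2 + 1):
        wi = wedderburn_etherington(i)
        wj = wedderburn_etherington(n - i)
        if i < n - i:
            block = wi * wj
            if idx < block:
                return (_unrank_shape(i, idx // wj), _unrank_shape(n - i, idx % wj))
            idx -= block
        else:  # i == n - i: unordered pair with repetition
            block = wi * (wi + 1) // 2
            if idx < block:
                # triangular unranking: pairs (a, b) with a <= b
                lo, hi = 0, wi - 1
                while lo < hi:
                    mid = (lo + hi + 1) // 2
                    below = mid * wi - mid * (mid - 1) // 2
                    if below <= idx:
                        lo = mid
                    else:
                        hi = mid - 1
                a = lo
                b = a + (idx - (a * wi - a * (a - 1) // 2))
                return (_unrank_shape(i, a), _unrank_shape(i, b))
            idx -= block
    raise ValueError("shape index out of range")


def _shape_to_tree(shape, k: int) -> SpeciesTree:
    labels = iter(_leaf_labels(k))
    return _finish(_attach_labels(shape, labels))


def random_topology(k: int, seed: int) -> SpeciesTree:
    """Uniform random unordered binary shape with ``k`` leaves.

    Deterministic for a given ``(k, seed)``; leaves are labeled A, B, ... in
    left-to-right order of the drawn shape.
    """
    if k < 1:
        raise TreeError("tree size must be >= 1")
    rng = random.Random(seed)
    idx = rng.randrange(wedderburn_etherington(k))
    return _shape_to_tree(_unrank_shape(k, idx), k)


def enumerate_topologies(k: int) -> list[SpeciesTree]:
    """All distinct unordered binary shapes with ``k`` leaves (small ``k``)."""
    return [
        _shape_to_tree(_unrank_shape(k, i), k)
        for i in range(wedderburn_etherington(k))
    ]


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------


@dataclass
class Ranking:
    """Ranks of the nodes of a species tree.

    Internal nodes carry distinct ranks ``1..k-1`` with ancestors ranked
    before descendants; every leaf has rank ``k``.
    """

    tree: SpeciesTree
    rank: dict[Node, int] = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def k(self) -> int:
        return self.tree.k

    def validate(self) -> None:
        k = self.tree.k
        internals = self.tree.internal_nodes()
        ranks = []
        for node in self.tree.nodes:
            if node not in self.rank:
                raise TreeError(f"node {node.label!r} missing from ranking")
            r = self.rank[node]
            if node.is_leaf:
                if r != k:
                    raise TreeError(f"leaf {node.label!r} must have rank {k}")
            else:
                ranks.append(r)
                if node.parent is not None and self.rank[node.parent] >= r:
                    raise TreeError(
                        f"ancestor {node.parent.label!r} must outrank "
                        f"{node.label!r}"
                    )
        if sorted(ranks) != list(range(1, len(internals) + 1)):
            raise TreeError("internal ranks must be a permutation of 1..k-1")

    def order(self) -> list[Node]:
        """Internal nodes in increasing rank order."""
        return sorted(self.tree.internal_nodes(), key=lambda n: self.rank[n])

    def to_json(self) -> str:
        """Sidecar representation: internal-node labels in rank order."""
        return json.dumps([n.label for n in self.order()])

    @classmethod
    def from_labels(cls, tree: SpeciesTree, labels: list[str]) -> "Ranking":
        rank = {leaf: tree.k for leaf in tree.nodes if leaf.is_leaf}
        for i, lab in enumerate(labels, start=1):
            rank[tree.node(lab)] = i
        return cls(tree, rank)

    @classmethod
    def from_json(cls, tree: SpeciesTree, text: str) -> "Ranking":
        return cls.from_labels(tree, json.loads(text))


def _random_extension(node: Node, rng: random.Random) -> list[Node]:
    """Uniform linear extension of the internal nodes below ``node``."""
    if node.is_leaf:
        return []
    seqs = [_random_extension(c, rng) for c in node.children]
    merged = seqs[0]
    for seq in seqs[1:]:
        out: list[Node] = []
        a, b = merged, seq
        i = j = 0
        while i < len(a) or j < len(b):
            na, nb = len(a) - i, len(b) - j
            if rng.randrange(na + nb) < na:
                out.append(a[i])
                i += 1
            else:
                out.append(b[j])
                j += 1
        merged = out
    return [node] + merged


def random_ranking(tree: SpeciesTree, seed: int) -> Ranking:
    """Uniform random ranking (linear extension of the internal-node poset)."""
    rng = random.Random(seed)
    order = _random_extension(tree.root, rng)
    rank = {leaf: tree.k for leaf in tree.nodes if leaf.is_leaf}
    for i, node in enumerate(order, start=1):
        rank[node] = i
    return Ranking(tree, rank)


def enumerate_rankings(tree: SpeciesTree) -> list[Ranking]:
    """All rankings of ``tree`` (all linear extensions); small trees only."""

    def extensions(node: Node) -> list[list[Node]]:
        if node.is_leaf:
            return [[]]
        per_child = [extensions(c) for c in node.children]
        merged = per_child[0]
        for seqs in per_child[1:]:
            merged = [
                inter
                for a in merged
                for b in seqs
                for inter in _interleavings(a, b)
            ]
        return [[node] + m for m in merged]

    out = []
    for order in extensions(tree.root):
        rank = {leaf: tree.k for leaf in tree.nodes if leaf.is_leaf}
        for i, node in enumerate(order, start=1):
            rank[node] = i
        out.append(Ranking(tree, rank))
    return out


def _interleavings(a: list, b: list) -> list[list]:
    if not a:
        return [list(b)]
    if not b:
        return [list(a)]
    return [[a[0]] + rest for rest in _interleavings(a[1:], b)] + [
        [b[0]] + rest for rest in _interleavings(a, b[1:])
    ]


def count_rankings(tree: SpeciesTree) -> int:
    """Number of rankings, by the hook-length formula for tree posets."""
    import math

    internals = tree.internal_nodes()
    total = math.factorial(len(internals))
    for node in internals:
        total //= sum(1 for d in internals if tree.is_ancestor(node, d))
    return total


# ---------------------------------------------------------------------------
# Time-sliced trees
# ---------------------------------------------------------------------------


class SlicedNode:
    """A node of a time-sliced tree (binary, unary or leaf)."""

    __slots__ = ("label", "children", "parent", "slice", "species")

    def __init__(self, label: str, slice_index: int, species: Node):
        self.label = label
        self.children: tuple[SlicedNode, ...] = ()
        self.parent: Optional[SlicedNode] = None
        self.slice = slice_index
        self.species = species

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_unary(self) -> bool:
        return len(self.children) == 1

    def __repr__(self) -> str:  # pragma: no cover
        return f"SlicedNode({self.label!r}, slice={self.slice})"


class TimeSlicedTree:
    """The unary-binary tree S^pi induced by a ranking.

    Slice ``i`` (for ``i <= k-1``) contains exactly one binary node (the
    internal species node of rank ``i``) and ``i-1`` unary nodes standing for
    the contemporaneous branches; slice ``k`` holds the ``k`` leaves.
    """

    def __init__(self, tree: SpeciesTree, ranking: Ranking):
        ranking.validate()
        if ranking.tree is not tree:
            # allow structurally identical but distinct objects only if same nodes
            raise TreeError("ranking was built for a different tree object")
        self.tree = tree
        self.ranking = ranking
        self.k = tree.k
        self.by_label: dict[str, SlicedNode] = {}
        self.slices: dict[int, list[SlicedNode]] = {
            i: [] for i in range(1, self.k + 1)
        }
        self.root = self._build()
        self.nodes: list[SlicedNode] = list(self._postorder(self.root))

    def _new(self, label: str, slice_index: int, species: Node) -> SlicedNode:
        if label in self.by_label:
            raise TreeError(f"duplicate sliced-node label {label!r}")
        node = SlicedNode(label, slice_index, species)
        self.by_label[label] = node
        self.slices[slice_index].append(node)
        return node

    def _build(self) -> SlicedNode:
        rank = self.ranking.rank
        k = self.k

        def build(v: Node) -> SlicedNode:
            rv = rank[v]
            if v.is_leaf:
                bottom = self._new(v.label, k, v)
            else:
                bottom = self._new(v.label, rv, v)
                kids = tuple(build(c) for c in v.children)
                bottom.children = kids
                for c in kids:
                    c.parent = bottom
            # unary nodes on the edge (p(v), v), one per crossed rank
            if v.parent is None:
                return bottom
            top = bottom
            for i in range(rv - 1, rank[v.parent], -1):
                unary = self._new(v.label + "'" * (i - rank[v.parent]), i, v)
                unary.children = (top,)
                top.parent = unary
                top = unary
            return top

        return build(self.tree.root)

    @staticmethod
    def _postorder(node: SlicedNode) -> Iterator[SlicedNode]:
        for c in node.children:
            yield from TimeSlicedTree._postorder(c)
        yield node

    def postorder(self) -> list[SlicedNode]:
        return self.nodes

    def leaves(self) -> list[SlicedNode]:
        out: list[SlicedNode] = []

        def rec(n: SlicedNode) -> None:
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                rec(c)

        rec(self.root)
        return out

    def node(self, label: str) -> SlicedNode:
        try:
            return self.by_label[label]
        except KeyError:
            raise TreeError(f"unknown sliced-node label {label!r}") from None

    def slice_of(self, i: int) -> list[SlicedNode]:
        return list(self.slices[i])

    def incomparable(self, u: SlicedNode) -> tuple[SlicedNode, ...]:
        """Time-slice incomparability: the other nodes of u's slice."""
        return tuple(v for v in self.slices[u.slice] if v is not u)


def build_time_slices(tree: SpeciesTree, ranking: Ranking) -> TimeSlicedTree:
    """Subdivide edges crossing rank boundaries; return the sliced tree."""
    return TimeSlicedTree(tree, ranking)


Context = Union[SpeciesTree, TimeSlicedTree]


def incomparable(context: Context, u) -> tuple:
    """Nodes incomparable with ``u``.

    For an unranked tree these are all nodes that are neither ancestors nor
    descendants of ``u``; for a time-sliced tree, the other nodes of ``u``'s
    time slice (the legal receivers of a transfer out of ``u``).
    """
    return context.incomparable(u)
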
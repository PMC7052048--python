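import math

import pytest

from dlthist.species_trees import (
    SpeciesTree,
    make_caterpillar,
    make_complete_binary,
)


def catalan(n: int) -> int:
    """Independent closed-form oracle for binary-tree counts."""
    return math.comb(2 * n, n) // (n + 1)


def structurally_equal(a: SpeciesTree, b: SpeciesTree) -> bool:
    def key(node):
        if node.is_leaf:
            return (node.label,)
        return (node.label, tuple(key(c) for c in node.children))

    return key(a.root) == key(b.root)


def shape_key(tree: SpeciesTree):
    """Label-free unordered-shape fingerprint."""

    def key(node):
        if node.is_leaf:
            return 1
        return tuple(sorted((key(c) for c in node.children), key=repr))

    return key(tree.root)


def hook_length_rankings(tree: SpeciesTree) -> int:
    """Number of linear extensions of the internal-node poset (hook lengths)."""
    internals = tree.internal_nodes()
    total = math.factorial(len(internals))
    for node in internals:
        total //= sum(1 for d in internals if tree.is_ancestor(node, d))
    return total


@pytest.fixture
def cherry() -> SpeciesTree:
    return make_caterpillar(2)


@pytest.fixture
def cb2() -> SpeciesTree:
    return make_complete_binary(2)
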
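import collections

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import hook_length_rankings, shape_key, structurally_equal

from dlthist.species_trees import (
    Ranking,
    TreeError,
    build_time_slices,
    enumerate_rankings,
    enumerate_topologies,
    incomparable,
    make_balanced,
    make_caterpillar,
    make_complete_binary,
    parse_newick,
    random_ranking,
    random_topology,
    to_newick,
    wedderburn_etherington,
)


class TestNewick:
    def test_labeled_input(self):
        t = parse_newick("((A,B)X,C)R;")
        assert t.k == 3
        assert t.root.label == "R"
        assert {leaf.label for leaf in t.leaves()} == {"A", "B", "C"}

    def test_auto_labeled_caterpillar_shape(self):
        t = parse_newick("(A,(B,C));")
        assert t.k == 3
        assert shape_key(t) == shape_key(make_caterpillar(3))

    def test_trifurcation_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((A,B),(C,D),E);")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((A,B)A,C)R;")

    @pytest.mark.parametrize(
        "tree",
        [make_caterpillar(k) for k in (1, 2, 5, 16)]
        + [make_complete_binary(h) for h in (0, 2, 4)]
        + [make_balanced(k) for k in (3, 7, 12)]
        + [random_topology(k, seed) for k, seed in [(5, 0), (9, 1), (16, 2)]],
    )
    def test_write_then_parse_round_trip(self, tree):
        assert structurally_equal(parse_newick(to_newick(tree)), tree)


class TestFamilies:
    def test_caterpillar_base_cases(self):
        assert make_caterpillar(1).k == 1
        assert make_caterpillar(1).root.is_leaf
        t2 = make_caterpillar(2)
        assert t2.k == 2 and all(c.is_leaf for c in t2.root.children)

    def test_caterpillar_left_spine(self):
        t = make_caterpillar(5)
        node, depth = t.root, 0
        while not node.is_leaf:
            assert node.children[1].is_leaf  # right child is always a leaf
            node, depth = node.children[0], depth + 1
        assert depth == 4

    def test_caterpillar_domain_error(self):
        with pytest.raises(TreeError):
            make_caterpillar(0)

    @pytest.mark.parametrize("h", [0, 2, 3])
    def test_complete_binary_leaves_at_uniform_depth(self, h):
        t = make_complete_binary(h)
        assert t.k == 2**h

        def depths(node, d=0):
            if node.is_leaf:
                yield d
            for c in node.children:
                yield from depths(c, d + 1)

        assert set(depths(t.root)) == {h}

    def test_balanced_special_cases(self):
        assert shape_key(make_balanced(4)) == shape_key(make_complete_binary(2))
        assert make_balanced(1).root.is_leaf
        t3 = make_balanced(3)
        sizes = sorted(len(c.children) for c in t3.root.children)
        assert sizes == [0, 2]  # a leaf and a cherry

    def test_balanced_invariant(self):
        def leafcount(node):
            return 1 if node.is_leaf else sum(map(leafcount, node.children))

        for k in range(1, 20):
            for node in make_balanced(k).internal_nodes():
                l, r = (leafcount(c) for c in node.children)
                assert abs(l - r) <= 1


class TestRandomTopology:
    def test_unique_shape_k3(self):
        keys = {shape_key(random_topology(3, seed)) for seed in range(20)}
        assert len(keys) == 1

    def test_determinism(self):
        assert structurally_equal(random_topology(7, 123), random_topology(7, 123))

    def test_enumeration_matches_wedderburn_etherington(self):
        # independent reference values: OEIS A001190 offsets
        assert [wedderburn_etherington(n) for n in range(1, 9)] == [
            1, 1, 1, 2, 3, 6, 11, 23,
        ]
        for k in range(1, 8):
            shapes = enumerate_topologies(k)
            assert len({shape_key(s) for s in shapes}) == len(shapes)
            assert len(shapes) == wedderburn_etherington(k)

    @pytest.mark.parametrize("k", [4, 5, 6])
    def test_uniform_over_shapes(self, k):
        from scipy.stats import chisquare

        counts = collections.Counter(
            shape_key(random_topology(k, seed)) for seed in range(10_000)
        )
        n_shapes = wedderburn_etherington(k)
        assert len(counts) == n_shapes
        res = chisquare(list(counts.values()))
        assert res.pvalue > 0.001
        if k == 4:
            for c in counts.values():
                assert abs(c / 10_000 - 0.5) < 0.02


class TestRankings:
    def test_caterpillar_has_unique_ranking(self):
        t = make_caterpillar(5)
        assert len(enumerate_rankings(t)) == 1
        r = random_ranking(t, 0)
        spine = t.root
        rank = 1
        while not spine.is_leaf:
            assert r.rank[spine] == rank
            spine, rank = spine.children[0], rank + 1

    def test_cherry_ranking(self, cherry):
        r = random_ranking(cherry, 0)
        assert r.rank[cherry.root] == 1
        assert all(r.rank[leaf] == 2 for leaf in cherry.leaves())

    @pytest.mark.parametrize("k,seed", [(4, 0), (5, 1), (6, 2), (6, 3)])
    def test_extension_count_matches_hook_formula(self, k, seed):
        t = random_topology(k, seed)
        assert len(enumerate_rankings(t)) == hook_length_rankings(t)

    def test_uniform_over_rankings_cb2(self, cb2):
        assert hook_length_rankings(cb2) == 2
        counts = collections.Counter(
            random_ranking(cb2, seed).to_json() for seed in range(10_000)
        )
        assert len(counts) == 2
        for c in counts.values():
            assert abs(c / 10_000 - 0.5) < 0.02

    def test_uniform_over_rankings_k6(self):
        from scipy.stats import chisquare

        t = random_topology(6, 5)
        support = {r.to_json() for r in enumerate_rankings(t)}
        counts = collections.Counter(
            random_ranking(t, seed).to_json() for seed in range(10_000)
        )
        assert set(counts) == support
        assert chisquare(list(counts.values())).pvalue > 0.001

    def test_invalid_ranking_rejected(self, cb2):
        order = [n.label for n in random_ranking(cb2, 0).order()]
        with pytest.raises(TreeError):
            Ranking.from_labels(cb2, list(reversed(order)))


class TestTimeSlices:
    def fig2_tree(self):
        return parse_newick("((D,E)B,(F,G)C)A;")

    def test_fig2_slices(self):
        t = self.fig2_tree()
        sliced = build_time_slices(t, Ranking.from_labels(t, ["A", "B", "C"]))
        labels = {
            i: {n.label for n in sliced.slice_of(i)} for i in range(1, 5)
        }
        assert labels == {
            1: {"A"},
            2: {"B", "C'"},
            3: {"C", "D'", "E'"},
            4: {"D", "E", "F", "G"},
        }

    def test_fig2_swapped_ranking(self):
        t = self.fig2_tree()
        sliced = build_time_slices(t, Ranking.from_labels(t, ["A", "C", "B"]))
        labels = {
            i: {n.label for n in sliced.slice_of(i)} for i in range(1, 5)
        }
        assert labels == {
            1: {"A"},
            2: {"C", "B'"},
            3: {"B", "F'", "G'"},
            4: {"D", "E", "F", "G"},
        }

    def test_cherry_adds_no_unary_nodes(self, cherry):
        sliced = build_time_slices(cherry, random_ranking(cherry, 0))
        assert all(not n.is_unary for n in sliced.postorder())

    @given(st.integers(min_value=2, max_value=10), st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_slice_sizes(self, k, seed):
        t = random_topology(k, seed)
        sliced = build_time_slices(t, random_ranking(t, seed + 1))
        for i in range(1, k):
            nodes = sliced.slice_of(i)
            assert len(nodes) == i
            assert sum(1 for n in nodes if len(n.children) == 2) == 1
        assert len(sliced.slice_of(k)) == k
        # every root-to-leaf path crosses each slice exactly once
        for leaf in sliced.leaves():
            path = []
            node = leaf
            while node is not None:
                path.append(node.slice)
                node = node.parent
            assert sorted(path) == list(range(1, k + 1))


class TestIncomparability:
    def test_unranked_cherry(self, cherry):
        a, b = cherry.leaves()
        assert incomparable(cherry, a) == (b,)
        assert incomparable(cherry, cherry.root) == ()

    def test_ranked_fig2(self):
        t = parse_newick("((D,E)B,(F,G)C)A;")
        sliced = build_time_slices(t, Ranking.from_labels(t, ["A", "B", "C"]))
        others = incomparable(sliced, sliced.node("B"))
        assert {n.label for n in others} == {"C'"}

    def test_unranked_includes_leaves_and_internals(self):
        t = parse_newick("((A,B)X,(C,D)Y)R;")
        labels = {n.label for n in incomparable(t, t.node("A"))}
        assert labels == {"B", "C", "D", "Y"}
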
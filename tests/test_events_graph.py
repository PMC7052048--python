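import pytest

from conftest import catalan

from dlthist.counting import build_count_tables, enumerate_histories
from dlthist.events_graph import (
    build_events_graph,
    count_dtsl,
    decode_history,
    encode_history,
    grow_histories,
    transport_history,
)
from dlthist.histories import validate_history
from dlthist.sampling import sample_histories
from dlthist.species_trees import (
    Ranking,
    TreeError,
    build_time_slices,
    enumerate_rankings,
    enumerate_topologies,
    make_caterpillar,
    parse_newick,
    random_ranking,
    random_topology,
)


def sliced_of(tree, which=0):
    return build_time_slices(tree, enumerate_rankings(tree)[which])


class TestEventsGraphStructure:
    def fig8_graph(self):
        t = parse_newick("((D,E)B,(F,G)C)A;")
        return build_events_graph(
            build_time_slices(t, Ranking.from_labels(t, ["A", "B", "C"]))
        )

    def test_slice_label_sets_partition_leaves(self):
        g = self.fig8_graph()
        for i in range(1, g.k + 1):
            sets = [g.leafset(n) for n in g.sliced.slice_of(i)]
            assert sum(len(s) for s in sets) == g.k
            assert frozenset().union(*sets) == frozenset(range(1, g.k + 1))

    def test_transfer_edges_complete_within_slices(self):
        g = self.fig8_graph()
        per_slice = {i: 0 for i in range(1, g.k + 1)}
        for u, v, data in g.graph.edges(data=True):
            if data["kind"] == "transfer":
                nu, nv = g.sliced.node(u), g.sliced.node(v)
                assert nu.slice == nv.slice and u != v
                per_slice[nu.slice] += 1
        for i, count in per_slice.items():
            assert count == i * (i - 1)

    def test_duplication_self_loops_everywhere(self):
        g = self.fig8_graph()
        loops = {
            u for u, v, d in g.graph.edges(data=True)
            if d["kind"] == "duplication"
        }
        assert loops == set(g.graph.nodes)
        for u, v, d in g.graph.edges(data=True):
            if d["kind"] == "duplication":
                assert u == v

    def test_paths_cross_k_minus_one_speciation_edges(self):
        g = self.fig8_graph()
        for leaf in g.sliced.leaves():
            edges = 0
            node = leaf
            while node.parent is not None:
                edges += 1
                node = node.parent
            assert edges == g.k - 1

    def test_singleton_slice_has_no_transfers(self, cherry):
        g = build_events_graph(sliced_of(cherry))
        assert all(
            g.sliced.node(u).slice != 1
            for u, v, d in g.graph.edges(data=True)
            if d["kind"] == "transfer"
        )

    def test_edge_dropping_flags(self, cb2):
        sliced = sliced_of(cb2)
        g = build_events_graph(sliced, include_duplication=False)
        assert not any(
            d["kind"] == "duplication" for _, _, d in g.graph.edges(data=True)
        )
        g = build_events_graph(sliced, include_transfer=False)
        assert not any(
            d["kind"] == "transfer" for _, _, d in g.graph.edges(data=True)
        )

    def test_dot_export_mentions_all_nodes(self, cb2):
        g = build_events_graph(sliced_of(cb2))
        dot = g.to_dot()
        assert dot.startswith("digraph") and dot.rstrip().endswith("}")
        for label in g.graph.nodes:
            assert f'"{label}"' in dot


class TestDtslCounts:
    def test_single_leaf_is_catalan(self):
        t = make_caterpillar(1)
        sliced = build_time_slices(t, random_ranking(t, 0))
        tables = count_dtsl(sliced, 10)
        for n in range(1, 11):
            assert tables.history_count(n) == catalan(n - 1)

    @pytest.mark.parametrize("k", [3, 4, 5])
    def test_species_tree_independence(self, k):
        vectors = set()
        ranked_trees = 0
        for shape in enumerate_topologies(k):
            for ranking in enumerate_rankings(shape):
                sliced = build_time_slices(shape, ranking)
                vectors.add(tuple(count_dtsl(sliced, 10).counts()))
                ranked_trees += 1
        if k >= 4:  # k=3 admits a single ranked tree
            assert ranked_trees >= 2
        assert len(vectors) == 1

    def test_cherry_small_counts_match_enumeration(self, cherry):
        sliced = sliced_of(cherry)
        tables = count_dtsl(sliced, 4)
        for n in range(1, 5):
            assert tables.history_count(n) == len(
                enumerate_histories(sliced, "rDT-SL", n)
            )


class TestGrowingOracle:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_graph_growth_equals_grammar_enumeration(self, cherry, n):
        sliced = sliced_of(cherry)
        graph = build_events_graph(sliced)
        by_growth = set(grow_histories(graph, n))
        by_grammar = set(enumerate_histories(sliced, "rDT-SL", n))
        assert by_growth == by_grammar

    def test_growth_histories_are_valid(self, cb2):
        sliced = sliced_of(cb2)
        graph = build_events_graph(sliced)
        for h in grow_histories(graph, 3):
            assert validate_history(h, sliced, "rDT-SL") == []

    def test_cap(self, cherry):
        graph = build_events_graph(sliced_of(cherry))
        with pytest.raises(ValueError):
            grow_histories(graph, 40)


class TestEncodingAndTransport:
    def two_ranked_k4(self):
        shapes = enumerate_topologies(4)
        a = build_time_slices(shapes[0], enumerate_rankings(shapes[0])[0])
        b = build_time_slices(shapes[1], enumerate_rankings(shapes[1])[-1])
        return build_events_graph(a), build_events_graph(b)

    def test_single_gene_passthrough_path(self):
        t = make_caterpillar(3)
        sliced = build_time_slices(t, random_ranking(t, 0))
        graph = build_events_graph(sliced)
        tables = count_dtsl(sliced, 1)
        h = sample_histories(tables, 1, 1, seed=0)[0]
        enc = encode_history(h, graph)
        node, depth = enc.root, 0
        while node.children:
            assert len(node.children) == 1
            assert node.children[0].leaf == node.leaf
            node, depth = node.children[0], depth + 1
        assert depth == sliced.k - 1 and enc.size == 1

    def test_round_trip_on_samples(self):
        ga, _ = self.two_ranked_k4()
        tables = count_dtsl(ga.sliced, 6)
        for h in sample_histories(tables, 6, 100, seed=13):
            assert decode_history(encode_history(h, ga), ga) == h

    def test_encoded_edges_exist_in_graph(self):
        ga, _ = self.two_ranked_k4()
        tables = count_dtsl(ga.sliced, 5)

        def edges(node):
            for c in node.children:
                yield node, c
                yield from edges(c)

        adjacency = set()
        for u, v, d in ga.graph.edges(data=True):
            adjacency.add((u, v))
        for h in sample_histories(tables, 5, 30, seed=4):
            enc = encode_history(h, ga)
            for parent, child in edges(enc.root):
                pu = ga.node_for(parent.slice, parent.leaf).label
                cu = ga.node_for(child.slice, child.leaf).label
                assert (pu, cu) in adjacency

    def test_transport_identity_when_src_is_dst(self):
        ga, _ = self.two_ranked_k4()
        tables = count_dtsl(ga.sliced, 6)
        for h in sample_histories(tables, 6, 20, seed=21):
            assert transport_history(encode_history(h, ga), ga, ga) == h

    def test_transport_round_trip(self):
        ga, gb = self.two_ranked_k4()
        tables = count_dtsl(ga.sliced, 6)
        for h in sample_histories(tables, 6, 100, seed=2):
            h2 = transport_history(encode_history(h, ga), ga, gb)
            assert validate_history(h2, gb.sliced, "rDT-SL") == []
            back = transport_history(encode_history(h2, gb), gb, ga)
            assert back == h

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_transport_bijective_on_full_sets(self, n):
        ga, gb = self.two_ranked_k4()
        src = enumerate_histories(ga.sliced, "rDT-SL", n)
        images = {
            transport_history(encode_history(h, ga), ga, gb) for h in src
        }
        assert len(images) == len(src)  # injective
        assert images == set(enumerate_histories(gb.sliced, "rDT-SL", n))

    def test_size_mismatch_rejected(self):
        ga, _ = self.two_ranked_k4()
        t3 = make_caterpillar(3)
        g3 = build_events_graph(build_time_slices(t3, random_ranking(t3, 0)))
        tables = count_dtsl(ga.sliced, 3)
        enc = encode_history(sample_histories(tables, 3, 1, seed=0)[0], ga)
        with pytest.raises(TreeError):
            transport_history(enc, ga, g3)

    def test_invalid_history_rejected_by_encoder(self):
        ga, _ = self.two_ranked_k4()
        t = random_topology(4, 0)
        dl = build_count_tables(t, "uDL", 4)
        h = sample_histories(dl, 4, 1, seed=0)[0]  # unranked uDL history
        with pytest.raises(TreeError):
            encode_history(h, ga)
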
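from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from conftest import random_graph
from metanet import (
    ParameterError,
    alignment_scores,
    global_properties,
    jaccard_similarity,
    local_properties,
    motif_census,
    similarity_tree,
)
from metanet.netcompare import (
    _classify,
    connected_induced_subgraphs,
    degree_preserving_rewire,
)


class TestJaccard:
    def test_identical_networks(self):
        g = random_graph(10, 0.3, seed=0)
        assert jaccard_similarity(g, g, on="nodes") == 1.0
        assert jaccard_similarity(g, g, on="edges") == 1.0

    def test_node_overlap_worked_example(self):
        a = nx.Graph()
        a.add_nodes_from("ABC")
        b = nx.Graph()
        b.add_nodes_from("BCD")
        assert jaccard_similarity(a, b, on="nodes") == 0.5

    def test_disjoint_is_zero_and_empty_is_one(self):
        a = nx.Graph()
        a.add_nodes_from("AB")
        b = nx.Graph()
        b.add_nodes_from("CD")
        assert jaccard_similarity(a, b, on="nodes") == 0.0
        assert jaccard_similarity(nx.Graph(), nx.Graph(), on="edges") == 1.0


class TestSimilarityTree:
    def test_identical_pair_merges_first_at_zero(self):
        g = nx.path_graph(["a", "b", "c"])
        h = g.copy()
        other = nx.complete_graph(["x", "y", "z", "w"])
        newick = similarity_tree({"g": g, "h": h, "other": other}, on="nodes")
        assert newick.endswith(";")
        assert "(g:0,h:0)" in newick or "(h:0,g:0)" in newick

    def test_parses_as_newick_with_given_leaves(self):
        import dendropy

        nets = {f"net{i}": random_graph(8, 0.3, seed=i) for i in range(4)}
        newick = similarity_tree(nets, on="edges")
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == sorted(nets)

    def test_matches_independent_average_linkage(self):
        # hand-feed the same distance matrix to scipy directly
        from scipy.cluster.hierarchy import average, to_tree
        from scipy.spatial.distance import squareform

        nets = {f"n{i}": random_graph(9, 0.25, seed=10 + i) for i in range(4)}
        names = list(nets)
        dist = np.zeros((4, 4))
        for i, j in combinations(range(4), 2):
            d = 1.0 - jaccard_similarity(nets[names[i]], nets[names[j]], on="nodes")
            dist[i, j] = dist[j, i] = d
        expected_root = to_tree(average(squareform(dist)))

        def leaves(node):
            if node.is_leaf():
                return [names[node.id]]
            return leaves(node.left) + leaves(node.right)

        newick = similarity_tree(nets, on="nodes")
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        # same leaf partition at the root split
        left, right = tree.seed_node.child_nodes()
        got = {frozenset(l.taxon.label for l in side.leaf_iter()) for side in (left, right)}
        want = {frozenset(leaves(expected_root.left)), frozenset(leaves(expected_root.right))}
        assert got == want

    def test_duplicate_names_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ParameterError):
            similarity_tree([("a", g), ("a", g)])


class TestAlignment:
    def test_identity_self_alignment_is_perfect(self):
        for seed in range(10):
            g = random_graph(12, 0.3, seed)
            scores = alignment_scores(g, g)
            assert (scores.ec, scores.ics, scores.s3) == (1.0, 1.0, 1.0)

    def test_path_into_triangle(self):
        a = nx.path_graph(["x", "y", "z"])
        b = nx.complete_graph(["x", "y", "z"])
        scores = alignment_scores(a, b)
        assert scores.ec == 1.0
        assert scores.ics == pytest.approx(2 / 3)
        assert scores.s3 == pytest.approx(2 / 3)

    def test_one_missing_edge(self):
        a = nx.path_graph(["p", "q", "r", "s"])  # 3 edges
        b = a.copy()
        b.remove_edge("p", "q")
        scores = alignment_scores(a, b)
        assert scores.ec == pytest.approx(2 / 3)

    def test_non_injective_mapping_rejected(self):
        a = nx.path_graph(["x", "y"])
        b = nx.path_graph(["u", "v"])
        with pytest.raises(ParameterError):
            alignment_scores(a, b, mapping={"x": "u", "y": "u"})

    def test_empty_source_warns_and_scores_one(self):
        a = nx.Graph()
        a.add_nodes_from("xy")
        b = nx.path_graph(["x", "y"])
        with pytest.warns(UserWarning):
            scores = alignment_scores(a, b)
        assert scores == alignment_scores(a, b.__class__(b))  # stable
        assert scores.ec == 1.0


class TestGlobalProperties:
    def test_complete_graph(self):
        p = global_properties(nx.complete_graph(5))
        assert (p.density, p.clustering_coefficient, p.avg_path_length) == (1.0, 1.0, 1.0)

    def test_three_node_path(self):
        p = global_properties(nx.path_graph(3))
        assert p.density == pytest.approx(2 / 3)
        assert p.clustering_coefficient == 0.0
        assert p.avg_path_length == pytest.approx(4 / 3)

    def test_disconnected_uses_largest_component(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert global_properties(g).avg_path_length == 1.0

    def test_empty_graph_all_zero(self):
        p = global_properties(nx.Graph())
        assert p.n_nodes == 0 and p.avg_path_length == 0.0


class TestLocalProperties:
    def test_star_center(self):
        table = local_properties(nx.star_graph(4))
        center = table.loc[0]
        assert center["degree"] == 4
        assert center["degree_centrality"] == 1.0
        assert center["betweenness"] == 6  # all six leaf-pair paths
        assert center["eigenvector_centrality"] == 1.0

    def test_cycle_is_vertex_transitive(self):
        table = local_properties(nx.cycle_graph(5))
        for col in table.columns:
            values = table[col].to_numpy(dtype=float)
            assert np.ptp(values) < 1e-9

    def test_complete_graph_coreness(self):
        table = local_properties(nx.complete_graph(5))
        assert (table["coreness"] == 4).all()


class TestMotifCensus:
    def test_cycle_and_clique_single_class(self):
        census = motif_census(nx.cycle_graph(4), n_random=5, seed=0)
        assert census.counts["cycle"] == 1 and census.n_subgraphs == 1
        assert census.frequency["cycle"] == 1.0
        census = motif_census(nx.complete_graph(4), n_random=5, seed=0)
        assert census.counts["clique"] == 1

    def test_counts_match_brute_force(self):
        for seed in range(3):
            g = random_graph(14, 0.3, seed)
            census = motif_census(g, n_random=0, seed=0)
            brute = {c: 0 for c in census.counts}
            for quad in combinations(sorted(g.nodes), 4):
                sub = g.subgraph(quad)
                if sub.number_of_edges() >= 3 and nx.is_connected(sub):
                    brute[_classify(g, quad)] += 1
            assert census.counts == brute

    def test_counts_invariant_under_relabeling(self):
        g = random_graph(12, 0.35, seed=7)
        rng = np.random.default_rng(0)
        perm = dict(zip(sorted(g.nodes), rng.permutation(sorted(g.nodes))))
        census_a = motif_census(g, n_random=0, seed=0)
        census_b = motif_census(nx.relabel_nodes(g, perm), n_random=0, seed=0)
        assert census_a.counts == census_b.counts

    def test_rewired_networks_preserve_degrees(self):
        g = random_graph(16, 0.25, seed=3)
        rng = np.random.default_rng(5)
        for _ in range(5):
            rewired = degree_preserving_rewire(g, rng)
            assert dict(rewired.degree()) == dict(g.degree())

    def test_tiny_graph_gives_empty_census(self):
        census = motif_census(nx.path_graph(3), n_random=5, seed=0)
        assert census.n_subgraphs == 0

    def test_esu_enumerates_each_subgraph_once(self):
        g = random_graph(12, 0.4, seed=11)
        quads = connected_induced_subgraphs(g, 4)
        assert len({frozenset(q) for q in quads}) == len(quads)
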
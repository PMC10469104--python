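"""Global properties, modularity, centralities, community detection,
scaffold extraction, shortest paths and k-NN overlay."""

import math

import networkx as nx
import numpy as np
import pytest

from pepspace import (
    CommunityPartition,
    MetricSpec,
    Peptide,
    centrality,
    detect_communities,
    extract_scaffold,
    find_singletons,
    global_properties,
    knn_overlay,
    make_context,
    modularity,
    pairwise_similarity,
    shortest_path,
)
from _oracles import (
    all_partitions,
    brute_betweenness,
    brute_harmonic,
    floyd_warshall,
    random_weighted_graph,
)


def two_triangles():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")], weight=1.0)
    return g


def planted_partition():
    return CommunityPartition(
        labels={"a": 0, "b": 0, "c": 0, "x": 1, "y": 1, "z": 1},
        method="planted",
    )


class TestGlobalProperties:
    def test_triangle(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")], weight=1.0)
        props = global_properties(g)
        assert props["density"] == 1.0
        assert props["n_components"] == 1

    def test_path_density(self):
        g = nx.path_graph(3)
        assert global_properties(g)["density"] == pytest.approx(2 / 3)

    def test_edgeless(self):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        props = global_properties(g)
        assert props["density"] == 0.0
        assert props["n_components"] == 5


class TestModularity:
    def test_two_triangles_planted_q(self):
        # closed form: 2 * (3/6 - (6/12)^2) = 0.5
        assert modularity(two_triangles(), planted_partition()) == pytest.approx(0.5)

    def test_single_community_zero(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            part = CommunityPartition(labels={v: 0 for v in g}, method="one")
            assert modularity(g, part) == pytest.approx(0.0, abs=1e-12)

    def test_planted_is_exhaustive_maximum(self):
        g = two_triangles()
        nodes = sorted(g.nodes)
        best = -math.inf
        count = 0
        for partition in all_partitions(nodes):
            count += 1
            labels = {v: i for i, block in enumerate(partition) for v in block}
            best = max(best, modularity(g, labels))
        assert count == 203  # Bell(6)
        assert best == pytest.approx(0.5)

    def test_agrees_with_networkx(self, rng):
        for _ in range(20):
            nodes, adj, lengths, sims = random_weighted_graph(rng, 8, p=0.5)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for (u, v), w in sims.items():
                g.add_edge(u, v, weight=w)
            if g.number_of_edges() == 0:
                continue
            labels = {v: int(rng.integers(3)) for v in nodes}
            communities = {}
            for v, c in labels.items():
                communities.setdefault(c, set()).add(v)
            expected = nx.community.modularity(
                g, communities.values(), weight="weight")
            part = CommunityPartition(labels=labels, method="random")
            assert modularity(g, part) == pytest.approx(expected, abs=1e-12)

    def test_zero_edges_defined_as_zero(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        assert modularity(g, CommunityPartition(labels={"a": 0, "b": 1},
                                                method="x")) == 0.0


class TestCentrality:
    def test_path_hand_values(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c")], weight=1.0)
        bc = centrality(g, "betweenness").scores
        assert bc["b"] == pytest.approx(1.0)
        assert bc["a"] == 0.0
        hc = centrality(g, "harmonic").scores
        assert hc["b"] == pytest.approx(2.0)
        assert hc["a"] == pytest.approx(1.5)

    def test_weighted_degree_unit_weights_equal_degree(self, rng):
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        nx.set_edge_attributes(g, 1.0, "weight")
        wd = centrality(g, "weighted_degree").scores
        for v in g:
            assert wd[v] == g.degree(v)

    def test_hub_bridge_reduces_to_degree_within_one_community(self):
        g = two_triangles()
        part = planted_partition()
        hb = centrality(g, "hub_bridge", partition=part).scores
        wd = centrality(g, "weighted_degree").scores
        for v in g:  # all neighbors share the node's community -> P = 0
            assert hb[v] == pytest.approx(wd[v])

    def test_hub_bridge_rewards_bridging(self):
        g = two_triangles()
        g.add_edge("c", "x", weight=1.0)
        part = planted_partition()
        hb = centrality(g, "hub_bridge", partition=part).scores
        wd = centrality(g, "weighted_degree").scores
        assert hb["c"] > wd["c"]
        assert hb["a"] == pytest.approx(wd["a"])

    def test_betweenness_matches_enumeration_oracle(self, rng):
        for _ in range(15):
            nodes, adj, lengths, sims = random_weighted_graph(rng, 9, p=0.35)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for (u, v), w in sims.items():
                g.add_edge(u, v, weight=w)
            expected = brute_betweenness(nodes, adj, lengths)
            got = centrality(g, "betweenness").scores
            for v in nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)

    def test_harmonic_matches_oracle(self, rng):
        for _ in range(15):
            nodes, adj, lengths, sims = random_weighted_graph(rng, 9, p=0.35)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for (u, v), w in sims.items():
                g.add_edge(u, v, weight=w)
            expected = brute_harmonic(nodes, lengths)
            got = centrality(g, "harmonic").scores
            for v in nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            centrality(two_triangles(), "pagerank")


class TestCommunities:
    def test_louvain_recovers_two_triangles(self):
        g = two_triangles()
        for seed in range(5):
            part = detect_communities(g, "louvain", seed=seed)
            assert part.n_communities == 2
            assert part.modularity == pytest.approx(0.5)
            assert part.labels["a"] == part.labels["b"] == part.labels["c"]

    def test_kmeans_separates_blobs(self, rng):
        import pandas as pd
        from pepspace.descriptors import DescriptorMatrix

        blob1 = rng.normal(0.0, 0.05, size=(10, 3))
        blob2 = rng.normal(10.0, 0.05, size=(10, 3))
        X = np.vstack([blob1, blob2])
        ids = [f"p{i}" for i in range(20)]
        m = DescriptorMatrix(pd.DataFrame(X, index=ids, columns=list("abc")))
        g = nx.Graph()
        g.add_nodes_from(ids)
        part = detect_communities(g, "kmeans", seed=0, k=2, matrix=m)
        first = {part.labels[f"p{i}"] for i in range(10)}
        second = {part.labels[f"p{i}"] for i in range(10, 20)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_hierarchical_separates_blobs(self, rng):
        import pandas as pd
        from pepspace.descriptors import DescriptorMatrix

        X = np.vstack([rng.normal(0, 0.05, (8, 2)), rng.normal(5, 0.05, (8, 2))])
        ids = [f"p{i}" for i in range(16)]
        m = DescriptorMatrix(pd.DataFrame(X, index=ids, columns=list("ab")))
        g = nx.Graph()
        g.add_nodes_from(ids)
        part = detect_communities(g, "hierarchical", seed=0, k=2, matrix=m)
        assert part.n_communities == 2
        assert len({part.labels[f"p{i}"] for i in range(8)}) == 1

    def test_uclust_theta_one_every_node_alone(self, descriptor_setup, similarity):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(similarity.ids)
        # drop exact duplicates' similarity-1 pairs by using theta just above 1
        part = detect_communities(g, "uclust", similarity=similarity, theta_c=1.0)
        # centroids join only at similarity >= 1.0: all-distinct rows stay alone
        n_dupes = (np.isclose(similarity.S, 1.0).sum() - len(similarity.ids)) // 2
        assert part.n_communities >= len(similarity.ids) - n_dupes

    def test_labels_contiguous_from_zero(self, similarity):
        g = two_triangles()
        part = detect_communities(g, "louvain", seed=1)
        assert set(part.labels.values()) == set(range(part.n_communities))

    def test_k_larger_than_n_rejected(self, descriptor_setup):
        _, _, matrix = descriptor_setup
        g = nx.Graph()
        g.add_nodes_from(matrix.ids)
        with pytest.raises(ValueError):
            detect_communities(g, "kmeans", k=len(matrix.ids) + 1, matrix=matrix)


class TestSingletonsAndScaffold:
    def test_isolated_node_is_singleton(self):
        g = two_triangles()
        g.add_node("lonely")
        part = detect_communities(g, "louvain", seed=0)
        assert "lonely" in find_singletons(g, part)

    def test_complete_graph_no_singletons(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = CommunityPartition(labels={v: 0 for v in g}, method="one")
        assert find_singletons(g, part) == []

    def test_scaffold_counts(self):
        g = two_triangles()
        g.add_node("lonely")
        part = detect_communities(g, "louvain", seed=0)
        scores = centrality(g, "weighted_degree")
        scaf = extract_scaffold(g, part, scores, top_k=1)
        assert len(scaf.ids) == 3  # one per triangle + the singleton
        assert "lonely" in scaf.singletons

    def test_star_hub_selected(self):
        g = nx.star_graph(4)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = CommunityPartition(labels={v: 0 for v in g}, method="one")
        scores = centrality(g, "weighted_degree")
        scaf = extract_scaffold(g, part, scores)
        assert scaf.representatives[0] == [0]  # the hub

    def test_top_k_exceeding_community_returns_all(self):
        g = two_triangles()
        part = planted_partition()
        scores = centrality(g, "weighted_degree")
        scaf = extract_scaffold(g, part, scores, top_k=10)
        assert sorted(scaf.ids) == sorted(g.nodes)

    def test_top_k_below_one_rejected(self):
        g = two_triangles()
        with pytest.raises(ValueError):
            extract_scaffold(g, planted_partition(),
                             centrality(g, "weighted_degree"), top_k=0)


class TestShortestPath:
    def test_source_equals_target(self):
        g = two_triangles()
        assert shortest_path(g, "a", "a") == (["a"], 0.0)

    def test_edge_length_is_reciprocal_weight(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        path, length = shortest_path(g, "a", "b")
        assert path == ["a", "b"] and length == 2.0

    def test_unreachable_gives_infinity(self):
        g = two_triangles()
        path, length = shortest_path(g, "a", "x")
        assert path == [] and math.isinf(length)

    def test_unknown_node_error(self):
        with pytest.raises(ValueError):
            shortest_path(two_triangles(), "a", "nope")

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(10):
            nodes, adj, lengths, sims = random_weighted_graph(rng, 10, p=0.35)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for (u, v), w in sims.items():
                g.add_edge(u, v, weight=w)
            dist = floyd_warshall(nodes, lengths)
            for s in nodes[:4]:
                for t in nodes[4:]:
                    _, length = shortest_path(g, s, t)
                    expected = dist[(s, t)]
                    if math.isinf(expected):
                        assert math.isinf(length)
                    else:
                        assert length == pytest.approx(expected, abs=1e-9)

    def test_triangle_inequality_over_reachable(self, rng):
        nodes, adj, lengths, sims = random_weighted_graph(rng, 10, p=0.5)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for (u, v), w in sims.items():
            g.add_edge(u, v, weight=w)
        d = {}
        for s in nodes:
            for t in nodes:
                d[(s, t)] = shortest_path(g, s, t)[1]
        for a in nodes:
            for b in nodes:
                for c in nodes:
                    if all(not math.isinf(d[k]) for k in [(a, b), (b, c), (a, c)]):
                        assert d[(a, c)] <= d[(a, b)] + d[(b, c)] + 1e-9


class TestKnnOverlay:
    def _context(self, descriptor_setup):
        peptides, calc, matrix = descriptor_setup
        spec = MetricSpec("euclidean", "reciprocal")
        S = pairwise_similarity(matrix, spec)
        return make_context(peptides, calc, matrix, spec, S.d_max)

    def test_identical_query_first_with_similarity_one(self, descriptor_setup):
        peptides, _, _ = descriptor_setup
        ctx = self._context(descriptor_setup)
        target = peptides[0]
        hits, _ = knn_overlay(ctx, target.sequence, k=3)
        assert hits[0][1] == pytest.approx(1.0)
        assert peptides[hits[0][0]].sequence == target.sequence

    def test_k_equals_n_returns_all_sorted(self, descriptor_setup):
        peptides, _, _ = descriptor_setup
        ctx = self._context(descriptor_setup)
        hits, _ = knn_overlay(ctx, "ACDEFGHIKLMNPQRST", k=len(peptides))
        assert len(hits) == len(peptides)
        sims = [s for _, s, _ in hits]
        assert sims == sorted(sims, reverse=True)

    def test_family_majority_label(self, descriptor_setup):
        peptides, _, _ = descriptor_setup
        ctx = self._context(descriptor_setup)
        held_out = peptides["famA_0"]
        hits, summary = knn_overlay(ctx, held_out, k=3)
        assert summary["family"] == "famA"

    def test_invalid_k(self, descriptor_setup):
        ctx = self._context(descriptor_setup)
        with pytest.raises(ValueError):
            knn_overlay(ctx, "ACDE", k=0)
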
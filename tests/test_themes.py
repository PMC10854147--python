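"""Walktrap theme detection and product-of-ranks ordering."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gsthemes import (
    SyntheticSpec,
    build_graph,
    order_clusters,
    pairwise_similarity,
    prune_isolated,
    simulate_collection,
    walktrap_communities,
)
from gsthemes.themes import ThemePartition


def weighted(g, w=1.0):
    nx.set_edge_attributes(g, w, "weight")
    return g


class TestWalktrapCommunities:
    def test_two_disjoint_triangles_are_two_clusters(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")])
        part = walktrap_communities(weighted(g))
        assert part.n_clusters == 2
        assert part.assignment["a"] == part.assignment["b"] == part.assignment["c"]
        assert part.assignment["x"] == part.assignment["y"] == part.assignment["z"]
        assert part.assignment["a"] != part.assignment["x"]

    def test_two_cliques_with_bridge_split_at_bridge(self):
        """Two 5-cliques joined by one edge: walktrap cuts exactly at the bridge."""
        g = nx.Graph()
        left = [f"l{i}" for i in range(5)]
        right = [f"r{i}" for i in range(5)]
        for grp in (left, right):
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(grp[i], grp[j])
        g.add_edge("l0", "r0")
        part = walktrap_communities(weighted(g))
        assert part.n_clusters == 2
        assert {frozenset(m) for m in part.clusters["members"].map(frozenset)} == {
            frozenset(left),
            frozenset(right),
        }

    def test_disconnected_components_never_merge(self):
        rng = np.random.default_rng(1)
        g = nx.Graph()
        for c in range(4):
            nodes = [f"c{c}n{i}" for i in range(6)]
            for i in range(6):
                for j in range(i + 1, 6):
                    if rng.uniform() < 0.6:
                        g.add_edge(nodes[i], nodes[j])
            g.add_nodes_from(nodes)
        g.remove_nodes_from(list(nx.isolates(g)))
        part = walktrap_communities(weighted(g))
        for comp in nx.connected_components(g):
            comps = {part.assignment[n] for n in comp}
            # clusters must not span components: every cluster id used by this
            # component is used by no other component
            for other in nx.connected_components(g):
                if other != comp:
                    assert comps.isdisjoint({part.assignment[n] for n in other})

    def test_empty_graph_empty_partition(self):
        part = walktrap_communities(nx.Graph())
        assert part.n_clusters == 0 and part.assignment == {}

    def test_partition_covers_all_nodes_exactly_once(self):
        g = weighted(nx.karate_club_graph())
        g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
        part = walktrap_communities(g)
        assert set(part.assignment) == set(g.nodes)
        sizes = part.clusters["size"].sum()
        assert sizes == g.number_of_nodes()

    def test_modularity_beats_singletons(self):
        g = weighted(nx.karate_club_graph())
        g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
        part = walktrap_communities(g)
        groups = [set(m) for m in part.clusters["members"]]
        mod = nx.community.modularity(g, groups, weight="weight")
        singles = nx.community.modularity(g, [{n} for n in g.nodes], weight="weight")
        assert mod >= singles

    def test_deterministic_for_fixed_graph(self):
        g = weighted(nx.karate_club_graph())
        g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
        a = walktrap_communities(g).assignment
        b = walktrap_communities(g).assignment
        assert a == b

    def test_planted_partition_recovery(self):
        """Median recovery ARI >= 0.9 over 20 seeds of the default generator."""
        aris = []
        for seed in range(20):
            coll, set_stats, _, truth = simulate_collection(SyntheticSpec(seed=seed))
            simmat = pairwise_similarity(coll, "ari")
            graph, _ = prune_isolated(build_graph(simmat, 0.25, node_stats=set_stats))
            part = walktrap_communities(graph)
            names = list(graph.nodes)
            aris.append(
                adjusted_rand_score(
                    [truth.set_theme[n] for n in names],
                    [part.assignment[n] for n in names],
                )
            )
        assert np.median(aris) >= 0.9


def make_partition(sizes, medians):
    rows = []
    assignment = {}
    for i, (s, m) in enumerate(zip(sizes, medians), start=1):
        members = [f"c{i}s{j}" for j in range(s)]
        for mem in members:
            assignment[mem] = i
        rows.append({"cluster": i, "members": members, "size": s, "median_statistic": m})
    return ThemePartition(assignment, pd.DataFrame(rows))


class TestOrderClusters:
    def test_worked_example(self):
        # sizes {10,5,2}, medians {1,3,2}, larger-better:
        # size ranks {1,2,3}, stat ranks {3,1,2}, products {3,2,6} -> c2,c1,c3
        part = order_clusters(make_partition([10, 5, 2], [1.0, 3.0, 2.0]))
        df = part.clusters
        assert df.set_index("cluster")["size_rank"].to_dict() == {1: 1, 2: 2, 3: 3}
        assert df.set_index("cluster")["statistic_rank"].to_dict() == {1: 3, 2: 1, 3: 2}
        assert df.set_index("cluster")["rank_product"].to_dict() == {1: 3, 2: 2, 3: 6}
        assert list(df["cluster"]) == [2, 1, 3]
        assert list(df["order"]) == [1, 2, 3]

    def test_single_cluster(self):
        part = order_clusters(make_partition([4], [1.0]))
        assert list(part.clusters["order"]) == [1]

    def test_tie_broken_by_statistic_rank_then_id(self):
        # sizes {6,3}, medians {1,2}: products both 2; c2 has stat rank 1
        part = order_clusters(make_partition([6, 3], [1.0, 2.0]))
        assert list(part.clusters["cluster"]) == [2, 1]
        # identical clusters tie fully -> cluster id decides
        part = order_clusters(make_partition([5, 5], [2.0, 2.0]))
        assert list(part.clusters["cluster"]) == [1, 2]

    def test_smaller_better_direction(self):
        part = order_clusters(
            make_partition([5, 5, 5], [0.001, 0.5, 0.01]), direction="smaller-better"
        )
        ranks = part.clusters.set_index("cluster")["statistic_rank"].to_dict()
        assert ranks == {1: 1, 3: 2, 2: 3}

    def test_absolute_value_flag(self):
        part = order_clusters(make_partition([5, 5], [-3.0, 1.0]), use_absolute=True)
        ranks = part.clusters.set_index("cluster")["statistic_rank"].to_dict()
        assert ranks == {1: 1, 2: 2}

    def test_missing_median_gets_worst_rank(self):
        part = order_clusters(make_partition([5, 5], [float("nan"), 1.0]))
        ranks = part.clusters.set_index("cluster")["statistic_rank"].to_dict()
        assert ranks[1] == 2 and ranks[2] == 1

    def test_invariant_to_relabelling(self):
        sizes, medians = [8, 3, 5, 5], [0.5, 2.0, 1.0, -1.0]
        base = order_clusters(make_partition(sizes, medians))
        perm = [2, 0, 3, 1]
        shuffled = order_clusters(
            make_partition([sizes[i] for i in perm], [medians[i] for i in perm])
        )
        base_order = [
            (r["size"], r["median_statistic"]) for _, r in base.clusters.iterrows()
        ]
        shuf_order = [
            (r["size"], r["median_statistic"]) for _, r in shuffled.clusters.iterrows()
        ]
        assert base_order == shuf_order
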
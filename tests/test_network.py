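import networkx as nx
import numpy as np
import pandas as pd
import pytest

from digestnet.network import (
    CoNetwork,
    average_path_length,
    betweenness_stats,
    build_network,
    clustering_coefficient,
    degree_stats,
    modularity_partition,
    positive_ratio,
    powerlaw_fit,
    random_baseline,
    topology_panel,
    write_edgelist_tsv,
    write_graphml,
)

from conftest import random_graphs
from oracles import (
    apl_floyd_warshall,
    betweenness_brute,
    clustering_brute,
    max_modularity_exhaustive,
    modularity_q,
)


def edges_df(pairs, signs=None):
    signs = signs or [1] * len(pairs)
    return pd.DataFrame(
        {"source": [p[0] for p in pairs], "target": [p[1] for p in pairs],
         "rho": [0.8 * s for s in signs], "p": 0.001, "sign": signs,
         "weight": [0.8] * len(pairs)})


class TestBuildNetwork:
    def test_nodes_edges_and_attributes(self):
        meta = pd.DataFrame({"abundance": [0.1, 0.2, 0.3, 0.4]},
                            index=["a", "b", "c", "d"])
        net = build_network(edges_df([("a", "b"), ("b", "c")], [1, -1]), meta, group="g")
        assert net.order == 3 and net.size == 2
        assert net.isolated_dropped == ["d"]
        assert net.graph.nodes["a"]["abundance"] == 0.1
        assert net.graph["b"]["c"]["sign"] == -1

    def test_duplicate_pair_collapsed_conflict_raises(self):
        net = build_network(edges_df([("a", "b"), ("a", "b")]))
        assert net.size == 1
        with pytest.raises(ValueError, match="conflicting"):
            build_network(edges_df([("a", "b"), ("b", "a")], [1, -1]))

    def test_empty_edge_list_warns(self):
        with pytest.warns(UserWarning, match="no edges"):
            net = build_network(edges_df([]))
        assert net.order == 0


class TestClosedFormValues:
    def test_clustering_triangle_and_star(self):
        assert clustering_coefficient(nx.complete_graph(3)) == 1.0
        assert clustering_coefficient(nx.star_graph(3)) == 0.0

    def test_apl_path_and_complete(self):
        assert average_path_length(nx.path_graph(3)) == pytest.approx(4 / 3)
        assert average_path_length(nx.complete_graph(5)) == 1.0

    def test_degree_stats_complete_and_star(self):
        assert degree_stats(nx.complete_graph(4)) == (3.0, 1.0)
        avg, norm = degree_stats(nx.star_graph(4))  # star S5: center + 4 leaves
        assert avg == pytest.approx(8 / 5)
        assert norm == pytest.approx((1.0 + 4 * 0.25) / 5)

    def test_betweenness_star_center_and_cycle_symmetry(self):
        _, btw = betweenness_stats(nx.star_graph(4))
        assert btw[0] == pytest.approx(1.0)
        assert np.allclose(btw[1:], 0.0)
        _, btw_c5 = betweenness_stats(nx.cycle_graph(5))
        assert btw_c5.nunique() == 1

    def test_positive_ratio(self):
        net = build_network(edges_df([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")],
                                     [1, 1, -1, -1]))
        assert positive_ratio(net) == 0.5
        assert positive_ratio(build_network(edges_df([("a", "b")]))) == 1.0

    def test_two_disconnected_triangles_panel(self, two_triangles):
        panel = topology_panel(two_triangles, n_reps=10, seed=0)
        assert panel.clustering_coefficient == 1.0
        assert panel.modularity == pytest.approx(0.5)
        assert panel.average_path_length == 1.0
        assert panel.average_degree == 2.0
        assert panel.order == 6 and panel.size == 6

    def test_empty_graph_errors(self):
        empty = CoNetwork(graph=nx.Graph(), group="none")
        with pytest.raises(ValueError):
            topology_panel(empty)
        with pytest.raises(ValueError):
            clustering_coefficient(empty)


class TestOracleEquivalence:
    """Production metrics vs naive brute-force implementations on random graphs."""

    @pytest.fixture(scope="class")
    def graphs(self):
        return random_graphs(30, 5, 12, seed=2024)

    def test_clustering_matches_triangle_enumeration(self, graphs):
        for g in graphs:
            assert clustering_coefficient(g) == pytest.approx(clustering_brute(g), abs=1e-12)

    def test_apl_matches_floyd_warshall(self, graphs):
        for g in graphs:
            try:
                expected = apl_floyd_warshall(g)
            except ValueError:
                continue
            assert average_path_length(g) == pytest.approx(expected, abs=1e-12)

    def test_betweenness_matches_path_enumeration(self, graphs):
        for g in graphs:
            if g.number_of_nodes() < 3:
                continue
            _, btw = betweenness_stats(g)
            oracle = betweenness_brute(g)
            for node, val in oracle.items():
                assert btw[node] == pytest.approx(val, abs=1e-9)

    def test_degree_stats_match_direct_sums(self, graphs):
        for g in graphs:
            ks = [d for _, d in g.degree()]
            avg, norm = degree_stats(g)
            assert avg == pytest.approx(sum(ks) / len(ks))
            assert avg == pytest.approx(2 * g.number_of_edges() / g.number_of_nodes())
            assert norm == pytest.approx(np.mean([k / (len(ks) - 1) for k in ks]))

    def test_modularity_q_of_returned_partition_scored_correctly(self, graphs):
        for g in graphs:
            part, q = modularity_partition(g)
            blocks: dict = {}
            for node, c in part.items():
                blocks.setdefault(c, []).append(node)
            assert q == pytest.approx(modularity_q(g, list(blocks.values())), abs=1e-12)
            assert q >= -1e-12  # never worse than the trivial one-module split


class TestModularity:
    def test_two_triangles_is_the_exhaustive_optimum(self, two_triangles):
        part, q = modularity_partition(two_triangles)
        assert q == pytest.approx(0.5)
        assert q == pytest.approx(max_modularity_exhaustive(two_triangles.graph))
        assert len({part[n] for n in (0, 1, 2)}) == 1
        assert len({part[n] for n in (3, 4, 5)}) == 1
        assert part[0] != part[3]

    def test_ring_of_cliques_recovers_cliques(self):
        g = nx.ring_of_cliques(4, 4)
        part, q = modularity_partition(g)
        for c in range(4):
            labels = {part[4 * c + i] for i in range(4)}
            assert len(labels) == 1
        assert q > 0.5

    def test_one_module_partition_scores_zero(self, two_triangles):
        assert modularity_q(two_triangles.graph, [list(two_triangles.graph.nodes)]) == \
            pytest.approx(0.0)

    def test_greedy_matches_exhaustive_on_small_graphs(self):
        graphs = random_graphs(40, 4, 8, seed=77)
        matched = 0
        for g in graphs:
            _, q = modularity_partition(g)
            if q >= max_modularity_exhaustive(g) - 1e-9:
                matched += 1
        assert matched / len(graphs) >= 0.95

    def test_louvain_is_seeded_and_deterministic(self, two_triangles):
        p1, q1 = modularity_partition(two_triangles, method="louvain", seed=5)
        p2, q2 = modularity_partition(two_triangles, method="louvain", seed=5)
        assert p1 == p2 and q1 == q2


class TestRandomBaseline:
    def test_er_mean_clustering_near_edge_density(self):
        n, p = 100, 0.15
        m = round(p * n * (n - 1) / 2)
        g = nx.gnm_random_graph(n, m, seed=1)
        mean, sd = random_baseline(g, n_reps=50, seed=0)
        assert mean == pytest.approx(p, rel=0.10)

    def test_degenerate_graphs(self):
        g_empty_edges = nx.empty_graph(5)
        g_empty_edges.add_edge(0, 1)
        g_empty_edges.remove_edge(0, 1)  # 0 edges, 5 nodes
        mean, _ = random_baseline(g_empty_edges, n_reps=5, seed=0)
        assert mean == 0.0
        mean_c, sd_c = random_baseline(nx.complete_graph(6), n_reps=5, seed=0)
        assert mean_c == 1.0 and sd_c == 0.0

    def test_seeded_reproducibility(self):
        g = nx.gnm_random_graph(40, 100, seed=3)
        assert random_baseline(g, 20, seed=9) == random_baseline(g, 20, seed=9)


class TestPowerlawFit:
    def test_recovers_zeta_exponent(self):
        rng = np.random.default_rng(12)
        degrees = rng.zipf(2.5, size=2000)
        fit = powerlaw_fit(degrees, x_min_mode=1, n_boot=20, seed=0)
        assert 2.3 <= fit.alpha <= 2.7

    def test_ks_xmin_selection_skips_corrupted_head(self):
        # power law holds only for x >= 4: below that the sample is uniform
        rng = np.random.default_rng(13)
        z = rng.zipf(2.5, size=4000)
        head = z < 4
        z[head] = rng.integers(1, 4, size=head.sum())
        fit = powerlaw_fit(z, x_min_mode="ks", n_boot=10, seed=0)
        assert 3 <= fit.x_min <= 6
        assert 2.2 <= fit.alpha <= 2.8

    def test_constant_degrees_rejected(self):
        with pytest.warns(UserWarning, match="distinct degree"):
            fit = powerlaw_fit([4] * 50, n_boot=20, seed=0)
        assert fit.p_value < 0.05 and fit.flagged

    def test_sd_of_alpha_shrinks_with_sample_size(self):
        rng = np.random.default_rng(14)
        def alphas(n, reps=12):
            return [powerlaw_fit(rng.zipf(2.5, size=n), x_min_mode=1, n_boot=1, seed=0).alpha
                    for _ in range(reps)]
        assert np.std(alphas(1200)) < np.std(alphas(300))


class TestTopologyPanelDeterminism:
    def test_identical_rows_for_identical_seed(self, bridged_cliques):
        p1 = topology_panel(bridged_cliques, n_reps=25, seed=11)
        p2 = topology_panel(bridged_cliques, n_reps=25, seed=11)
        assert p1 == p2
        assert p1.average_normalized_degree == pytest.approx(
            p1.average_degree / (p1.order - 1), abs=1e-12)

    def test_writers_emit_attributes(self, tmp_path, bridged_cliques):
        net = bridged_cliques
        net.graph.add_edge(0, 1)  # ensure attrs exist
        for u, v in net.graph.edges:
            net.graph[u][v].setdefault("sign", 1)
            net.graph[u][v].setdefault("weight", 0.9)
            net.graph[u][v].setdefault("rho", 0.9)
        write_graphml(net, tmp_path / "g.graphml")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_edges() == net.size
        assert all("module" in d for _, d in back.nodes(data=True))
        write_edgelist_tsv(net, tmp_path / "e.tsv", header_comment="stage=test")
        df = pd.read_csv(tmp_path / "e.tsv", sep="\t", comment="#")
        assert len(df) == net.size and {"sign", "weight"} <= set(df.columns)
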
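"""Centrality, hubs, shortest paths, enrichment."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import sennet
from sennet.dataset import ValidationError
from sennet.topology import graph_from_edges


def _edges(*pairs):
    return pd.DataFrame(pairs, columns=["source", "target"])


class TestHubs:
    def test_degree_boundary_is_inclusive(self):
        g = nx.star_graph(500)  # center degree 500
        assert 0 in sennet.classify_hubs(g, 500)
        g = nx.star_graph(499)
        assert sennet.classify_hubs(g, 500) == set()

    def test_empty_graph_has_no_hubs(self):
        assert sennet.classify_hubs(nx.Graph(), 5) == set()

    def test_hub_sets_nest_with_threshold(self):
        g = nx.gnp_random_graph(60, 0.2, seed=1)
        for k in range(1, 10):
            assert sennet.classify_hubs(g, k + 1) <= sennet.classify_hubs(g, k)

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            sennet.classify_hubs(nx.Graph(), 0)


class TestClustering:
    def test_triangle_and_star(self):
        assert (sennet.clustering_coefficients(nx.complete_graph(3)) == 1.0).all()
        star = sennet.clustering_coefficients(nx.star_graph(4))
        assert star[0] == 0.0

    def test_matches_exhaustive_triangle_enumeration(self):
        g = graph_from_edges(_edges(("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("d", "e")))
        got = sennet.clustering_coefficients(g)
        for node in g.nodes:
            nbrs = list(g.neighbors(node))
            deg = len(nbrs)
            tri = sum(
                1 for u, v in itertools.combinations(nbrs, 2) if g.has_edge(u, v)
            )
            expected = 2 * tri / (deg * (deg - 1)) if deg >= 2 else 0.0
            assert got[node] == pytest.approx(expected)


class TestShortestPaths:
    def test_path_graph_hand_enumeration(self):
        g = graph_from_edges(_edges(("a", "b"), ("b", "c")))
        sp = sennet.mean_shortest_paths(g)
        assert sp["b"] == pytest.approx(1.0)
        assert sp["a"] == pytest.approx(1.5) and sp["c"] == pytest.approx(1.5)

    def test_complete_graph_all_unit(self):
        sp = sennet.mean_shortest_paths(nx.complete_graph(5))
        assert (sp == 1.0).all()

    def test_unreachable_pairs_excluded(self):
        g = graph_from_edges(_edges(("a", "b"), ("c", "d")))
        assert (sennet.mean_shortest_paths(g) == 1.0).all()


def _ic_oracle(g: nx.Graph) -> dict:
    """Independent route: effective resistances from the Laplacian
    pseudoinverse, IC(i) = n / sum_j R_ij."""
    out = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        n = len(nodes)
        if n == 1:
            out[nodes[0]] = np.nan
            continue
        L = nx.laplacian_matrix(g.subgraph(nodes), nodelist=nodes).toarray().astype(float)
        Lp = np.linalg.pinv(L, hermitian=True)
        for i, u in enumerate(nodes):
            total = sum(Lp[i, i] + Lp[j, j] - 2 * Lp[i, j] for j in range(n))
            out[u] = n / total
    return out


class TestInformationCentrality:
    def test_complete_graph_values_equal(self):
        ic = sennet.information_centrality(nx.complete_graph(4))
        assert ic.max() - ic.min() == pytest.approx(0.0, abs=1e-12)

    def test_star_leaves_equal_center_greater(self):
        ic = sennet.information_centrality(nx.star_graph(4))
        leaves = ic[[1, 2, 3, 4]]
        assert leaves.max() - leaves.min() == pytest.approx(0.0, abs=1e-10)
        assert ic[0] > leaves.max()
        oracle = _ic_oracle(nx.star_graph(4))
        for node, val in oracle.items():
            assert ic[node] == pytest.approx(val, abs=1e-10)

    def test_exhaustive_small_graphs_match_resistance_oracle(self):
        """All connected graphs on <=7 nodes (graph atlas)."""
        for g in nx.graph_atlas_g()[1:]:
            if g.number_of_nodes() < 2 or not nx.is_connected(g):
                continue
            ic = sennet.information_centrality(g)
            for node, val in _ic_oracle(g).items():
                assert ic[node] == pytest.approx(val, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_graphs_match_oracle(self, seed):
        g = nx.gnp_random_graph(30, 0.15, seed=seed)
        ic = sennet.information_centrality(g)
        for node, val in _ic_oracle(g).items():
            if np.isnan(val):
                assert np.isnan(ic[node])
            else:
                assert ic[node] == pytest.approx(val, abs=1e-8)

    def test_adding_edge_never_decreases_endpoint_centrality(self):
        g = nx.path_graph(6)
        before = sennet.information_centrality(g)
        g2 = g.copy()
        g2.add_edge(0, 5)
        after = sennet.information_centrality(g2)
        assert after[0] >= before[0] - 1e-12
        assert after[5] >= before[5] - 1e-12

    def test_singleton_component_warns_nan(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        with pytest.warns(UserWarning, match="singleton"):
            ic = sennet.information_centrality(g)
        assert np.isnan(ic["c"])


class TestModuleComparison:
    def test_shifted_module_extremely_significant(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.normal(size=500), index=[f"g{i}" for i in range(500)])
        vals.iloc[:30] += 10.0
        part = sennet.ModulePartition(
            labels=pd.Series(
                ["blue"] * 30 + [sennet.coexpression.GREY] * 470, index=vals.index
            ),
            min_module_size=2,
        )
        table = sennet.compare_module_centrality(vals, part)
        assert table.iloc[0]["p"] < 1e-10

    def test_null_module_rarely_extreme(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = pd.Series(rng.normal(size=400), index=[f"g{i}" for i in range(400)])
            part = sennet.ModulePartition(
                labels=pd.Series(
                    ["red"] * 40 + [sennet.coexpression.GREY] * 360, index=vals.index
                ),
                min_module_size=2,
            )
            p = sennet.compare_module_centrality(vals, part).iloc[0]["p"]
            hits += p <= 0.01
        assert hits <= 1  # >=95% of replicates not extreme

    def test_single_member_module_errors(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        part = sennet.ModulePartition(
            labels=pd.Series(["blue", "red", "red"], index=vals.index), min_module_size=2
        )
        with pytest.raises(ValidationError):
            sennet.compare_module_centrality(vals, part)


class TestHypergeom:
    def test_known_exact_value(self):
        # all 5 draws land in the 5-member category: 1 / C(10,5)
        assert sennet.hypergeom_enrichment(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_zero_overlap_is_certain(self):
        assert sennet.hypergeom_enrichment(40, 10, 5, 0) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universes(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        total = sum(
                            comb(K, j, exact=True) * comb(N - K, n - j, exact=True)
                            for j in range(k, min(K, n) + 1)
                        )
                        expected = total / comb(N, n, exact=True)
                        got = sennet.hypergeom_enrichment(N, K, n, k)
                        assert got == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_matches_sampling_oracle(self):
        N, K, n, k = 200, 40, 30, 10
        rng = np.random.default_rng(1)
        draws = rng.hypergeometric(K, N - K, n, size=1_000_000)
        mc = (draws >= k).mean()
        se = np.sqrt(mc * (1 - mc) / draws.size)
        assert abs(sennet.hypergeom_enrichment(N, K, n, k) - mc) <= 3 * se

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            sennet.hypergeom_enrichment(10, 5, 5, 6)


def test_analyze_topology_reports_tf_enrichment(small_bundle):
    _, expr, _, tf_edges, _, truth = small_bundle
    net = sennet.build_network(expr, r2_goal=0.5)
    part = sennet.detect_modules(net.tom, net.gene_ids, min_module_size=10)
    edges = sennet.export_network(net.tom, net.gene_ids, 0.3)
    report = sennet.analyze_topology(
        edges, part, hub_k=10, tf_list=list(tf_edges["regulator"].unique())
    )
    assert {"degree", "clustering", "information_centrality"} <= set(report.per_node.columns)
    assert report.tf_enrichment["universe"] > 0
    assert 0 <= report.tf_enrichment["p_value"] <= 1
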
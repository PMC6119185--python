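"""Structural analysis of the thresholded co-expression network.

Covers node degree and hub classification (Hub^k = nodes with at least k
connections), local clustering coefficients, per-node mean shortest-path
length, Stephenson–Zelen information centrality (current-flow closeness),
module-versus-network centrality tests, and exact hypergeometric
enrichment of regulator classes among hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import GREY, ModulePartition
from .dataset import ValidationError


def graph_from_edges(edges: pd.DataFrame, nodes: list[str] | None = None) -> nx.Graph:
    """Undirected simple graph from a (source, target[, weight]) table."""
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    cols = list(edges.columns)
    for row in edges.itertuples(index=False):
        g.add_edge(getattr(row, cols[0]), getattr(row, cols[1]))
    return g


def classify_hubs(graph: nx.Graph, k: int = 500) -> set:
    """Nodes with degree >= k (inclusive)."""
    if k < 1:
        raise ValidationError("hub threshold k must be >= 1")
    return {n for n, d in graph.degree() if d >= k}


def clustering_coefficients(graph: nx.Graph) -> pd.Series:
    """Local clustering coefficient per node (0 for degree < 2)."""
    return pd.Series(nx.clustering(graph), dtype=float)


def mean_shortest_paths(graph: nx.Graph) -> pd.Series:
    """Per-node mean hop distance to the nodes reachable from it.

    Isolated nodes get NaN (no reachable partner).
    """
    out = {}
    for node in graph.nodes:
        dists = nx.single_source_shortest_path_length(graph, node)
        del dists[node]
        out[node] = float(np.mean(list(dists.values()))) if dists else np.nan
    return pd.Series(out, dtype=float)


def information_centrality(graph: nx.Graph) -> pd.Series:
    """Stephenson–Zelen information centrality, computed per component.

    For a component with Laplacian L and all-ones matrix J, let
    ``C = (L + J)^{-1}``; then ``IC(i) = n / Σ_j (C_ii + C_jj - 2 C_ij)``
    over the component's n nodes. Singleton components get NaN with a
    warning. Values are strictly positive and relabeling-invariant.
    """
    out: dict = {}
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        n = len(nodes)
        if n == 1:
            warnings.warn(f"singleton component {nodes[0]}: information centrality undefined")
            out[nodes[0]] = np.nan
            continue
        L = nx.laplacian_matrix(graph.subgraph(nodes), nodelist=nodes).toarray().astype(float)
        C = np.linalg.inv(L + np.ones((n, n)))
        diag = np.diag(C)
        denom = n * diag + diag.sum() - 2.0 * C.sum(axis=1)
        ic = n / denom
        for node, val in zip(nodes, ic):
            out[node] = float(val)
    return pd.Series(out, dtype=float)


def compare_module_centrality(
    centrality: pd.Series, partition: ModulePartition
) -> pd.DataFrame:
    """Welch t-test of each module's centralities against the whole network.

    Returns a table (module, n, mean, t, p) sorted by module name.
    """
    network_vals = centrality.dropna().to_numpy()
    rows = []
    for mod, genes in sorted(partition.modules().items()):
        if mod == GREY:
            continue
        vals = centrality.reindex(genes).dropna().to_numpy()
        if len(vals) < 2:
            raise ValidationError(f"module {mod} has <2 members with defined centrality")
        if np.ptp(vals) == 0 and np.ptp(network_vals) == 0:
            warnings.warn(f"module {mod}: degenerate (constant) centralities; p=1")
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(vals, network_vals, equal_var=False)
        rows.append(
            {"module": mod, "n": len(vals), "mean": float(vals.mean()), "t": float(t), "p": float(p)}
        )
    return pd.DataFrame(rows)


def hypergeom_enrichment(
    universe_size: int, category_size: int, sample_size: int, overlap: int
) -> float:
    """Exact upper-tail hypergeometric enrichment p-value, P(X >= overlap)."""
    N, K, n, k = universe_size, category_size, sample_size, overlap
    if min(N, K, n, k) < 0 or K > N or n > N or k > min(K, n):
        raise ValidationError("inconsistent hypergeometric counts")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class TopologyReport:
    per_node: pd.DataFrame  # degree, clustering, mean_shortest_path, information_centrality, component
    hub_threshold: int
    hubs: set
    per_module: pd.DataFrame
    module_vs_network: pd.DataFrame
    tf_enrichment: dict


def analyze_topology(
    edges: pd.DataFrame,
    partition: ModulePartition | None = None,
    hub_k: int = 500,
    tf_list: list[str] | None = None,
    nodes: list[str] | None = None,
) -> TopologyReport:
    """Full structural report on a thresholded network edge list."""
    g = graph_from_edges(edges, nodes=nodes)
    comp_of = {}
    for cid, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_of[node] = cid
    per_node = pd.DataFrame(
        {
            "degree": pd.Series(dict(g.degree()), dtype=float),
            "clustering": clustering_coefficients(g),
            "mean_shortest_path": mean_shortest_paths(g),
            "information_centrality": information_centrality(g),
            "component": pd.Series(comp_of),
        }
    )
    hubs = classify_hubs(g, hub_k)
    per_module = pd.DataFrame()
    comparison = pd.DataFrame()
    if partition is not None:
        labels = partition.labels.reindex(per_node.index)
        grouped = per_node.groupby(labels)
        per_module = grouped[["degree", "clustering", "information_centrality"]].mean()
        per_module["n"] = grouped.size()
        ic = per_node["information_centrality"]
        sub = ModulePartition(
            labels=labels[labels.notna()].astype(str), min_module_size=partition.min_module_size
        )
        comparison = compare_module_centrality(ic, sub)
    enrichment: dict = {}
    if tf_list is not None:
        universe = set(g.nodes)
        tfs = universe & set(tf_list)
        overlap = len(hubs & tfs)
        p = hypergeom_enrichment(len(universe), len(tfs), len(hubs), overlap)
        enrichment = {
            "universe": len(universe),
            "tfs_in_network": len(tfs),
            "hubs": len(hubs),
            "tf_hubs": overlap,
            "p_value": p,
        }
    return TopologyReport(
        per_node=per_node,
        hub_threshold=hub_k,
        hubs=hubs,
        per_module=per_module,
        module_vs_network=comparison,
        tf_enrichment=enrichment,
    )
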
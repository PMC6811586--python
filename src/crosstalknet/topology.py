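"""Integrated-network construction and topological characterization.

``integrate_network`` expands receptor subnetworks by one neighborhood in
the background network (every background node adjacent, in either
direction, to a subnetwork node joins, with all induced signed edges).
The integrated network is then characterized by betweenness centrality
(fraction of shortest paths through a node, normalized by (n-1)(n-2)),
stress centrality (the raw count of shortest paths through a node), and a
power-law fit of the degree distribution on log-log axes — the
scale-free-topology diagnostic, reported as amplitude a, exponent b and the
R² of the log-log least-squares line.

Centralities default to the directed graph with unit edge lengths; pass
``directed=False`` to analyze the underlying undirected graph.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import BackgroundNetwork

__all__ = ["integrate_network", "betweenness", "stress", "powerlaw_fit", "centrality_report"]


def integrate_network(subnetwork_nodes, net: BackgroundNetwork) -> tuple[nx.DiGraph, dict]:
    """1-neighborhood expansion of subnetwork nodes within the background.

    Returns the induced signed subgraph on the subnetwork nodes plus every
    background node adjacent to one (either direction), and a summary dict
    with node/edge and sign counts.
    """
    core = set(subnetwork_nodes)
    stray = core - net.nodes
    if stray:
        raise ValueError(f"subnetwork nodes not in background network: {sorted(stray)}")
    expanded = set(core)
    for v in core:
        expanded.update(net.graph.successors(v))
        expanded.update(net.graph.predecessors(v))
    if not expanded:
        raise ValueError("empty integrated network")
    graph = net.graph.subgraph(expanded).copy()
    signs = {"activates": 0, "inhibits": 0}
    for _, _, d in graph.edges(data=True):
        signs[d["sign"]] += 1
    summary = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_activating": signs["activates"],
        "n_inhibitory": signs["inhibits"],
    }
    return graph, summary


def _as_graph(net, directed: bool):
    graph = net.graph if isinstance(net, BackgroundNetwork) else net
    if not directed:
        graph = graph.to_undirected(as_view=False)
    return graph


def betweenness(net, directed: bool = True) -> pd.Series:
    """Normalized betweenness centrality (unit edge lengths).

    For each ordered pair (s, t) with at least one shortest path, the
    fraction passing through interior node v is accumulated and divided by
    (n-1)(n-2) (ordered pairs for directed graphs; unordered for
    undirected).
    """
    graph = _as_graph(net, directed)
    if graph.number_of_nodes() < 3:
        raise ValueError("betweenness needs >= 3 nodes")
    bc = nx.betweenness_centrality(graph, normalized=True)
    return pd.Series(bc).sort_index()


def _bfs_dist_sigma(graph: nx.DiGraph, nodes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs unweighted distances and shortest-path counts."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        queue = [s]
        while queue:
            nxt = []
            for u in queue:
                ui = idx[u]
                for w in graph.successors(u) if graph.is_directed() else graph.neighbors(u):
                    wi = idx[w]
                    if np.isinf(dist[si, wi]):
                        dist[si, wi] = dist[si, ui] + 1
                        nxt.append(w)
                    if dist[si, wi] == dist[si, ui] + 1:
                        sigma[si, wi] += sigma[si, ui]
            queue = nxt
    return dist, sigma


def stress(net, directed: bool = True) -> pd.Series:
    """Stress centrality: count of shortest paths through each interior node.

    For every ordered pair (s, t), s != v != t, the number of shortest
    s->t paths passing through v is sigma(s,v) * sigma(v,t) whenever
    d(s,v) + d(v,t) = d(s,t); stress(v) sums these counts.
    """
    graph = _as_graph(net, directed)
    if graph.number_of_nodes() < 3:
        raise ValueError("stress needs >= 3 nodes")
    nodes = sorted(graph.nodes)
    dist, sigma = _bfs_dist_sigma(graph, nodes)
    n = len(nodes)
    out = np.zeros(n)
    for vi in range(n):
        with np.errstate(invalid="ignore"):
            on_path = dist[:, vi][:, None] + dist[vi, :][None, :] == dist
        counts = sigma[:, vi][:, None] * sigma[vi, :][None, :]
        on_path[vi, :] = False
        on_path[:, vi] = False
        np.fill_diagonal(on_path, False)
        out[vi] = counts[on_path].sum()
    if not graph.is_directed():
        out = out / 2  # unordered pairs
    return pd.Series(out.astype(int), index=nodes)


def fit_degree_powerlaw(degrees) -> tuple[float, float, float]:
    """Least-squares power-law fit a * degree^b to a degree multiset.

    The line is fit on (log10 degree, log10 count) over positive degrees
    with count >= 1. Returns (a, b, R²); R² is that of the log-log
    regression.
    """
    degrees = np.asarray(list(degrees))
    degrees = degrees[degrees > 0]
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 2:
        raise ValueError("need >= 2 distinct positive degrees for a power-law fit")
    x = np.log10(values.astype(float))
    y = np.log10(counts.astype(float))
    b, loga = np.polyfit(x, y, 1)
    yhat = loga + b * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(10**loga), float(b), r2


def powerlaw_fit(net, directed: bool = True) -> tuple[float, float, float]:
    """Power-law fit of a network's total-degree distribution.

    Total degree (in + out for directed graphs) is used regardless of the
    centrality mode; see :func:`fit_degree_powerlaw` for the fit itself.
    """
    graph = _as_graph(net, True)
    return fit_degree_powerlaw([d for _, d in graph.degree()])


def centrality_report(net, directed: bool = True) -> tuple[pd.DataFrame, dict]:
    """Per-node degree/betweenness/stress table plus the power-law summary."""
    graph = _as_graph(net, directed)
    nodes = sorted(graph.nodes)
    bc = betweenness(net, directed=directed)
    st = stress(net, directed=directed)
    if graph.is_directed():
        table = pd.DataFrame(
            {
                "in_degree": [graph.in_degree(v) for v in nodes],
                "out_degree": [graph.out_degree(v) for v in nodes],
                "degree": [graph.in_degree(v) + graph.out_degree(v) for v in nodes],
                "betweenness": bc.reindex(nodes),
                "stress": st.reindex(nodes),
            },
            index=nodes,
        )
    else:
        table = pd.DataFrame(
            {
                "degree": [graph.degree(v) for v in nodes],
                "betweenness": bc.reindex(nodes),
                "stress": st.reindex(nodes),
            },
            index=nodes,
        )
    a, b, r2 = powerlaw_fit(net, directed=directed)
    return table, {"powerlaw_a": a, "powerlaw_b": b, "powerlaw_r2": r2}
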
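"""Network topology metrics, per-node centralities and keystone taxa.

Conventions follow the NetworkAnalyzer tool: the clustering coefficient
averages only nodes of degree >= 2, the diameter and shortest-path count
consider finite distances only (disconnected pairs are ignored), and
betweenness is normalized within each connected component.
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyReport",
    "KeystoneCriteria",
    "KEYSTONE_PRESETS",
    "topology_report",
    "node_centralities",
    "keystone_taxa",
    "size_gate",
]


@dataclass
class TopologyReport:
    """The seven headline metrics of one network."""

    nodes: int
    edges: int
    clustering_coefficient: float
    network_diameter: int
    shortest_paths: int
    avg_neighbors: float
    graph_density: float


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.graph


def topology_report(network, clustering_all_nodes: bool = False) -> TopologyReport:
    """Compute the headline metrics of a simple undirected graph.

    ``shortest_paths`` counts ordered connected pairs (u, v), u != v;
    an empty or edgeless graph reports diameter 0 and the clustering
    coefficient over an empty node set is 0.  With
    ``clustering_all_nodes`` degree-<2 nodes enter the clustering
    average as 0 instead of being dropped.
    """
    g = _as_graph(network)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return TopologyReport(0, 0, 0.0, 0, 0, 0.0, 0.0)

    clust = nx.clustering(g)
    if clustering_all_nodes:
        eligible = list(g.nodes)
    else:
        eligible = [v for v in g.nodes if g.degree(v) >= 2]
    cc = sum(clust[v] for v in eligible) / len(eligible) if eligible else 0.0

    diameter = 0
    n_paths = 0
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            if dst == src:
                continue
            n_paths += 1
            if d > diameter:
                diameter = d

    avg_neighbors = 2.0 * e / n
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    return TopologyReport(
        nodes=n,
        edges=e,
        clustering_coefficient=cc,
        network_diameter=diameter,
        shortest_paths=n_paths,
        avg_neighbors=avg_neighbors,
        graph_density=density,
    )


def node_centralities(network) -> pd.DataFrame:
    """Degree, closeness and betweenness per node.

    closeness(v) = (# nodes reachable from v) / (sum of distances from
    v), i.e. component-local; isolated nodes get 0.  Betweenness is
    normalized by 2 / ((N'-1)(N'-2)) within each component of size N'
    (components of size <= 2 get 0), with pair dependencies split
    equally among shortest paths.
    """
    g = _as_graph(network)
    rows = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        n_comp = len(comp)
        if n_comp > 2:
            btw = nx.betweenness_centrality(sub, normalized=True)
        else:
            btw = {v: 0.0 for v in comp}
        for v in comp:
            dists = nx.single_source_shortest_path_length(sub, v)
            total = sum(dists.values())
            reachable = len(dists) - 1
            clo = reachable / total if total > 0 else 0.0
            rows[v] = {
                "degree": g.degree(v),
                "closeness": clo,
                "betweenness": btw[v],
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        df = pd.DataFrame(columns=["degree", "closeness", "betweenness"])
    return df.reindex(list(g.nodes))


_OPS = {
    ">": operator.gt,
    ">=": operator.ge,
    "<": operator.lt,
    "<=": operator.le,
    "==": operator.eq,
}


@dataclass
class KeystoneCriteria:
    """Joint degree/closeness/betweenness thresholds with comparison modes.

    Comparison modes are operator strings (``">"``, ``">="``, ``"<"``,
    ``"<="``, ``"=="``), letting the same machinery express both
    equality-style and strict-threshold keystone rules.
    """

    degree: float
    closeness: float
    betweenness: float
    degree_op: str = ">"
    closeness_op: str = ">"
    betweenness_op: str = "<"

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree threshold must be >= 0")
        if not (0 <= self.closeness <= 1):
            raise ValueError("closeness threshold must lie in [0, 1]")
        if not (0 <= self.betweenness <= 1):
            raise ValueError("betweenness threshold must lie in [0, 1]")
        for op in (self.degree_op, self.closeness_op, self.betweenness_op):
            if op not in _OPS:
                raise ValueError(f"unknown comparison mode {op!r}")

    def matches(self, degree: float, closeness: float, betweenness: float) -> bool:
        return (
            _OPS[self.degree_op](degree, self.degree)
            and _OPS[self.closeness_op](closeness, self.closeness)
            and _OPS[self.betweenness_op](betweenness, self.betweenness)
        )


KEYSTONE_PRESETS: dict[str, KeystoneCriteria] = {
    "AOA": KeystoneCriteria(5, 1.0, 0.0, "==", "==", "=="),
    "nirS": KeystoneCriteria(10, 0.354, 0.103, ">", ">", "<"),
    "nosZ": KeystoneCriteria(10, 0.311, 0.096, ">", ">", "<"),
}


def keystone_taxa(network, criteria: KeystoneCriteria) -> list[dict]:
    """Nodes passing all three centrality criteria (metadata nodes excluded)."""
    g = _as_graph(network)
    cents = node_centralities(g)
    out = []
    for node, row in cents.iterrows():
        if g.nodes[node].get("node_class", "taxon") == "metadata":
            continue
        if criteria.matches(row["degree"], row["closeness"], row["betweenness"]):
            out.append({
                "node": node,
                "degree": float(row["degree"]),
                "closeness": float(row["closeness"]),
                "betweenness": float(row["betweenness"]),
            })
    return out


def size_gate(network, min_nodes: int = 10) -> bool:
    """False (excluded from topology analysis) iff the network has
    fewer than ``min_nodes`` nodes."""
    g = _as_graph(network)
    ok = g.number_of_nodes() >= min_nodes
    if not ok:
        logger.info(
            "network with %d nodes excluded (< %d nodes)",
            g.number_of_nodes(), min_nodes,
        )
    return ok
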
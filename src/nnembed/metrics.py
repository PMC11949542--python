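"""Per-node network metrics: seven centrality, three noncentrality, five new.

The catalogue (in fixed column order) is:

centrality
    out-degree, in-degree, betweenness (directed shortest paths,
    unnormalised), subgraph centrality (diagonal of the matrix exponential
    of the adjacency), core number (undirected projection), PageRank
    (directed), closeness (directed);
noncentrality
    local efficiency defined as the nodal mean of inverse forward
    shortest-path distances to all other nodes (unreachable pairs
    contribute 0), participation coefficient against seeded Louvain
    communities of the symmetrised graph, clustering coefficient
    ``2e/(k(k-1))`` on the undirected projection (0 when ``k < 2``);
new metrics
    indirect-adjacent degree ``<D2(i)>/<D1(i)>`` — the mean degree of the
    nodes exactly two steps away over the mean degree of the direct
    neighbours — and the N-th neighbor hub ratio for N = 1..4, the
    fraction of hub nodes among nodes at shortest-path distance exactly N.

Hubs are the top 20% of nodes by degree (out-degree by default), i.e.
``floor(0.2 n)`` nodes with a minimum of one; ties at the cutoff are
broken by ascending node index with a logged warning.  The new metrics
use directed *forward* distance by default, matching the row-as-outgoing
sample convention (running the pipeline on the transposed network probes
the backward direction); a flag switches the convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .exceptions import ConfigurationError, EmptyNetworkError
from .netio import DirectedBinaryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "METRIC_NAMES",
    "METRIC_CATEGORIES",
    "MetricTable",
    "HubSet",
    "hub_set",
    "clustering_coefficient",
    "nth_neighbor_hub_ratio",
    "indirect_adjacent_degree",
    "compute_standard_metrics",
    "compute_all_metrics",
]

METRIC_NAMES: tuple[str, ...] = (
    "out_degree",
    "in_degree",
    "betweenness",
    "subgraph_centrality",
    "core_number",
    "pagerank",
    "closeness",
    "local_efficiency",
    "participation_coefficient",
    "clustering_coefficient",
    "indirect_adjacent_degree",
    "neighbor_hub_ratio_1",
    "neighbor_hub_ratio_2",
    "neighbor_hub_ratio_3",
    "neighbor_hub_ratio_4",
)

METRIC_CATEGORIES: dict[str, str] = {
    **{m: "centrality" for m in METRIC_NAMES[:7]},
    **{m: "noncentrality" for m in METRIC_NAMES[7:10]},
    **{m: "new" for m in METRIC_NAMES[10:]},
}


@dataclass
class MetricTable:
    """Nodes x metrics table with the category of every column attached."""

    values: pd.DataFrame  # index: node ids, columns: metric names
    categories: dict[str, str]

    @property
    def n_nodes(self) -> int:
        return len(self.values)

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.categories.values():
            counts[c] = counts.get(c, 0) + 1
        return counts


@dataclass
class HubSet:
    """Indices of hub nodes: top ``threshold_fraction`` by degree."""

    nodes: frozenset[int]
    threshold_fraction: float
    degree_kind: str


def _degrees(net: DirectedBinaryNetwork, kind: str) -> np.ndarray:
    if kind == "out":
        return net.out_degrees()
    if kind == "in":
        return net.in_degrees()
    if kind == "total":
        return net.out_degrees() + net.in_degrees()
    raise ConfigurationError(f"unknown degree kind {kind!r}")


def hub_set(
    net: DirectedBinaryNetwork,
    threshold_fraction: float = 0.2,
    degree_kind: str = "out",
) -> HubSet:
    """Top-degree nodes: ``floor(threshold_fraction * n)``, minimum 1.

    Ties at the cutoff are resolved toward lower node index,
    deterministically, with a logged warning.
    """
    n = net.n_nodes
    if n == 0:
        raise EmptyNetworkError("cannot take hubs of an empty network")
    deg = _degrees(net, degree_kind)
    h = max(1, math.floor(threshold_fraction * n))
    order = np.lexsort((np.arange(n), -deg))  # by descending degree, then index
    chosen = order[:h]
    if h < n and deg[order[h - 1]] == deg[order[h]]:
        logger.warning(
            "hub cutoff ties at degree %d broken by node index", int(deg[order[h]])
        )
    return HubSet(frozenset(int(i) for i in chosen), threshold_fraction, degree_kind)


def _distance_matrix(net: DirectedBinaryNetwork, direction: str) -> np.ndarray:
    """Directed shortest-path lengths (np.inf when unreachable)."""
    a = net.adjacency if direction == "forward" else net.adjacency.T
    g = nx.from_numpy_array(a, create_using=nx.DiGraph)
    n = net.n_nodes
    d = np.full((n, n), np.inf)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for tgt, dist in lengths.items():
            d[src, tgt] = dist
    return d


def clustering_coefficient(net: DirectedBinaryNetwork, node: int) -> float:
    """``2e/(k(k-1))`` on the undirected projection; 0 when ``k < 2``."""
    g = nx.from_numpy_array(net.adjacency, create_using=nx.DiGraph).to_undirected()
    return float(nx.clustering(g, node))


def nth_neighbor_hub_ratio(
    net: DirectedBinaryNetwork,
    node: int,
    n_steps: int,
    hubs: HubSet,
    direction: str = "forward",
    _dist: np.ndarray | None = None,
) -> float:
    """Fraction of hubs among nodes exactly ``n_steps`` away; empty set -> 0."""
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    d = _dist if _dist is not None else _distance_matrix(net, direction)
    shell = np.nonzero(d[node] == n_steps)[0]
    if shell.size == 0:
        return 0.0
    return float(sum(int(i) in hubs.nodes for i in shell) / shell.size)


def indirect_adjacent_degree(
    net: DirectedBinaryNetwork,
    node: int,
    degree_kind: str = "out",
    direction: str = "forward",
    _dist: np.ndarray | None = None,
    _deg: np.ndarray | None = None,
) -> float:
    """``<D2(i)> / <D1(i)>``: mean degree two steps away over one step away.

    Scores highly for nodes sitting two steps from hubs.  Policy for
    degenerate inputs: empty distance-2 shell -> 0; mean neighbour degree
    of zero, or no out-neighbours at all -> 0 with a warning.
    """
    d = _dist if _dist is not None else _distance_matrix(net, direction)
    deg = _deg if _deg is not None else _degrees(net, degree_kind)
    s1 = np.nonzero(d[node] == 1)[0]
    if s1.size == 0:
        logger.warning("node %d has no out-neighbours; indirect-adjacent degree 0", node)
        return 0.0
    s2 = np.nonzero(d[node] == 2)[0]
    if s2.size == 0:
        return 0.0
    d1 = float(deg[s1].mean())
    if d1 == 0:
        logger.warning("node %d: mean neighbour degree 0; returning 0", node)
        return 0.0
    return float(deg[s2].mean() / d1)


def _participation_coefficient(
    g_und: nx.Graph, communities: list[set[int]]
) -> dict[int, float]:
    comm_of = {}
    for c, members in enumerate(communities):
        for m in members:
            comm_of[m] = c
    pc = {}
    for node in g_und.nodes:
        k = g_und.degree(node)
        if k == 0:
            pc[node] = 0.0
            continue
        counts: dict[int, int] = {}
        for nb in g_und.neighbors(node):
            c = comm_of[nb]
            counts[c] = counts.get(c, 0) + 1
        pc[node] = 1.0 - sum((v / k) ** 2 for v in counts.values())
    return pc


def compute_standard_metrics(
    net: DirectedBinaryNetwork,
    direction: str = "forward",
    seed: int = 0,
) -> pd.DataFrame:
    """The ten established metrics (centrality + noncentrality columns)."""
    a = net.adjacency.astype(float)
    g_dir = nx.from_numpy_array(a, create_using=nx.DiGraph)
    g_und = g_dir.to_undirected()
    n = net.n_nodes
    nodes = range(n)

    betw = nx.betweenness_centrality(g_dir, normalized=False)
    sc = expm(a).diagonal()
    core = nx.core_number(g_und)
    pr = nx.pagerank(g_dir)
    clo = nx.closeness_centrality(g_dir)
    d = _distance_matrix(net, direction)
    with np.errstate(divide="ignore"):
        inv_d = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    local_eff = inv_d.sum(axis=1) / max(n - 1, 1)
    communities = nx.community.louvain_communities(g_und, seed=seed)
    pc = _participation_coefficient(g_und, communities)
    clus = nx.clustering(g_und)

    return pd.DataFrame(
        {
            "out_degree": net.out_degrees().astype(float),
            "in_degree": net.in_degrees().astype(float),
            "betweenness": [betw[i] for i in nodes],
            "subgraph_centrality": sc,
            "core_number": [float(core[i]) for i in nodes],
            "pagerank": [pr[i] for i in nodes],
            "closeness": [clo[i] for i in nodes],
            "local_efficiency": local_eff,
            "participation_coefficient": [pc[i] for i in nodes],
            "clustering_coefficient": [clus[i] for i in nodes],
        },
        index=net.node_ids,
    )


def compute_all_metrics(
    net: DirectedBinaryNetwork,
    hub_fraction: float = 0.2,
    degree_kind: str = "out",
    direction: str = "forward",
    seed: int = 0,
) -> MetricTable:
    """Assemble the full 15-column table (7 centrality / 3 noncentrality / 5 new)."""
    df = compute_standard_metrics(net, direction=direction, seed=seed)
    hubs = hub_set(net, hub_fraction, degree_kind)
    d = _distance_matrix(net, direction)
    deg = _degrees(net, degree_kind)
    df["indirect_adjacent_degree"] = [
        indirect_adjacent_degree(net, i, degree_kind, direction, _dist=d, _deg=deg)
        for i in range(net.n_nodes)
    ]
    for n_steps in (1, 2, 3, 4):
        df[f"neighbor_hub_ratio_{n_steps}"] = [
            nth_neighbor_hub_ratio(net, i, n_steps, hubs, direction, _dist=d)
            for i in range(net.n_nodes)
        ]
    df = df[list(METRIC_NAMES)]
    assert np.isfinite(df.to_numpy()).all()
    return MetricTable(df, dict(METRIC_CATEGORIES))
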
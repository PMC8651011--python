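"""Topology statistics of inferred association networks.

Signs and weights are ignored for topology: degree, betweenness,
components and path lengths are computed on the underlying undirected
simple graph. Average shortest path length is averaged over node pairs
within the same component only, so it stays finite on the fragmented
networks this pipeline produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, floor

import networkx as nx

from .network_inference import AssociationNetwork


@dataclass
class DegreeDistribution:
    """Node-degree histogram as percentages of total nodes."""

    frequencies: dict  # degree -> percent of nodes
    n_nodes: int


@dataclass
class NetworkProperties:
    """One table row of network statistics."""

    total_nodes: int
    total_edges: int
    positive_edges: int
    negative_edges: int
    positive_pct: int | None
    negative_pct: int | None
    components: int
    shortest_avg_path_length: float | None


def degree_distribution(net: AssociationNetwork) -> DegreeDistribution:
    g = net.to_networkx()
    n = g.number_of_nodes()
    freq: dict[int, float] = {}
    for _, deg in g.degree():
        freq[deg] = freq.get(deg, 0) + 1
    return DegreeDistribution(
        frequencies={k: 100.0 * v / n for k, v in sorted(freq.items())}, n_nodes=n
    )


def betweenness(net: AssociationNetwork) -> dict:
    """Unnormalized, unweighted shortest-path betweenness per node."""
    return dict(nx.betweenness_centrality(net.to_networkx(), normalized=False))


def components(net: AssociationNetwork) -> tuple[int, dict]:
    """Connected-component count and node -> component-index map.

    Components are indexed in order of their lexicographically smallest
    member, so the map is independent of node insertion order.
    """
    comps = [sorted(c) for c in nx.connected_components(net.to_networkx())]
    comps.sort(key=lambda c: c[0])
    membership = {node: i for i, c in enumerate(comps) for node in c}
    return len(comps), membership


def avg_shortest_path(net: AssociationNetwork) -> float | None:
    """Mean shortest-path length over same-component node pairs.

    Missing (None) when no two nodes share a component (i.e. no edges).
    """
    g = net.to_networkx()
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for node, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
        pairs += comb(len(comp), 2)
    if pairs == 0:
        return None
    return total / 2.0 / pairs  # each pair counted in both directions


def _pct(count: int, total: int) -> int | None:
    if total == 0:
        return None
    return int(floor(100.0 * count / total + 0.5))  # round half-up


def network_properties(net: AssociationNetwork) -> NetworkProperties:
    pos = sum(1 for sign, _ in net.edges.values() if sign > 0)
    neg = net.n_edges - pos
    n_comp, _ = components(net)
    return NetworkProperties(
        total_nodes=net.n_nodes,
        total_edges=net.n_edges,
        positive_edges=pos,
        negative_edges=neg,
        positive_pct=_pct(pos, net.n_edges),
        negative_pct=_pct(neg, net.n_edges),
        components=n_comp,
        shortest_avg_path_length=avg_shortest_path(net),
    )
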
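"""Graph statistics vs a brute-force BFS/path-counting oracle."""

from collections import deque
from itertools import combinations

import numpy as np
import pytest

import micronet as mn
from conftest import random_network


# ---------------------------------------------------------------------------
# Brute-force oracle (adjacency dict + BFS shortest-path counting)
# ---------------------------------------------------------------------------


def bfs_paths(adj, source):
    """Distances and shortest-path counts from source."""
    dist = {source: 0}
    sigma = {source: 1}
    order = []
    q = deque([source])
    while q:
        v = q.popleft()
        order.append(v)
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma, order


def brute_betweenness(net):
    adj = {n: set() for n in net.nodes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    btw = {n: 0.0 for n in net.nodes}
    for s, t in combinations(net.nodes, 2):
        dist, sigma, _ = bfs_paths(adj, s)
        if t not in dist:
            continue
        for v in net.nodes:
            if v in (s, t) or v not in dist:
                continue
            if dist[v] + _bfs_dist(adj, v, t) == dist[t]:
                _, sigma_v, _ = bfs_paths(adj, v)
                btw[v] += sigma[v] * sigma_v[t] / sigma[t]
    return btw


def _bfs_dist(adj, a, b):
    dist, _, _ = bfs_paths(adj, a)
    return dist.get(b, float("inf"))


def brute_components(net):
    adj = {n: set() for n in net.nodes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for n in net.nodes:
        if n in seen:
            continue
        comp = set()
        q = deque([n])
        while q:
            v = q.popleft()
            if v in comp:
                continue
            comp.add(v)
            q.extend(adj[v] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def brute_avg_path(net):
    adj = {n: set() for n in net.nodes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    total, pairs = 0, 0
    for s, t in combinations(net.nodes, 2):
        d = _bfs_dist(adj, s, t)
        if d != float("inf"):
            total += d
            pairs += 1
    return total / pairs if pairs else None


# ---------------------------------------------------------------------------
# Hand-checkable cases
# ---------------------------------------------------------------------------


def make_net(n, pairs):
    nodes = [f"n{i}" for i in range(n)]
    return mn.AssociationNetwork(
        nodes, {(f"n{i}", f"n{j}"): (1, 1.0) for i, j in pairs}
    )


class TestDegreeDistribution:
    def test_isolated_nodes(self):
        dd = mn.degree_distribution(make_net(5, []))
        assert dd.frequencies == {0: 100.0}

    def test_triangle(self):
        dd = mn.degree_distribution(make_net(3, [(0, 1), (1, 2), (0, 2)]))
        assert dd.frequencies == {2: 100.0}

    def test_star(self):
        dd = mn.degree_distribution(make_net(5, [(0, j) for j in range(1, 5)]))
        assert dd.frequencies == {1: 80.0, 4: 20.0}

    def test_frequencies_sum_to_100(self):
        rng = np.random.default_rng(0)
        dd = mn.degree_distribution(random_network(12, 0.3, rng))
        assert sum(dd.frequencies.values()) == pytest.approx(100.0, abs=1e-9)


class TestBetweenness:
    def test_path_graph(self):
        btw = mn.betweenness(make_net(3, [(0, 1), (1, 2)]))
        assert btw == {"n0": 0.0, "n1": 1.0, "n2": 0.0}

    def test_star_center(self):
        btw = mn.betweenness(make_net(5, [(0, j) for j in range(1, 5)]))
        assert btw["n0"] == 6.0  # C(4,2) leaf pairs route via the center
        assert all(btw[f"n{j}"] == 0.0 for j in range(1, 5))

    def test_complete_graph_zero(self):
        net = make_net(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        assert all(v == 0.0 for v in mn.betweenness(net).values())


class TestComponents:
    def test_tree_connected(self):
        assert mn.components(make_net(10, [(i, i + 1) for i in range(9)]))[0] == 1

    def test_two_triangles_plus_isolate(self):
        net = make_net(7, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert mn.components(net)[0] == 3

    def test_bridge_removal_splits_one_component(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            net = random_network(8, 0.25, rng)
            comps_before = len(brute_components(net))
            for edge in list(net.edges):
                reduced = mn.AssociationNetwork(
                    list(net.nodes), {k: v for k, v in net.edges.items() if k != edge}
                )
                delta = mn.components(reduced)[0] - comps_before
                assert delta in (0, 1)  # bridge -> +1, cycle edge -> 0


class TestAvgShortestPath:
    def test_path_p4(self):
        assert mn.avg_shortest_path(
            make_net(4, [(0, 1), (1, 2), (2, 3)])
        ) == pytest.approx(10 / 6)

    def test_complete_graph_one(self):
        net = make_net(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert mn.avg_shortest_path(net) == 1.0

    def test_two_disjoint_edges(self):
        assert mn.avg_shortest_path(make_net(4, [(0, 1), (2, 3)])) == 1.0

    def test_no_edges_missing(self):
        assert mn.avg_shortest_path(make_net(3, [])) is None


class TestNetworkProperties:
    def test_percentages_round_half_up(self):
        # 285 of 452 positive edges -> 63%
        rng = np.random.default_rng(2)
        nodes = [f"n{i:03d}" for i in range(300)]
        pairs = list(combinations(range(300), 2))
        pick = rng.choice(len(pairs), 452, replace=False)
        edges = {}
        for k, idx in enumerate(pick):
            i, j = pairs[idx]
            edges[(nodes[i], nodes[j])] = (1 if k < 285 else -1, 1.0)
        props = mn.network_properties(mn.AssociationNetwork(nodes, edges))
        assert props.positive_edges == 285 and props.negative_edges == 167
        assert props.positive_pct == 63 and props.negative_pct == 37

    def test_empty_network_boundary(self):
        props = mn.network_properties(make_net(4, []))
        assert props.total_edges == 0
        assert props.positive_pct is None and props.negative_pct is None
        assert props.components == 4

    def test_degree_sum_is_twice_edges(self):
        rng = np.random.default_rng(3)
        net = random_network(12, 0.3, rng)
        g = net.to_networkx()
        assert sum(d for _, d in g.degree()) == 2 * net.n_edges


class TestBruteForceAgreement:
    def test_all_statistics_match_oracle_on_random_graphs(self):
        """Degree distribution, betweenness, components and average shortest
        path agree exactly with a brute-force BFS oracle on 200 random
        graphs of up to 12 nodes."""
        rng = np.random.default_rng(1234)
        for g in range(200):
            n = int(rng.integers(2, 13))
            net = random_network(n, float(rng.uniform(0.05, 0.6)), rng)
            # betweenness
            ours = mn.betweenness(net)
            oracle = brute_betweenness(net)
            for node in net.nodes:
                assert ours[node] == pytest.approx(oracle[node], abs=1e-9)
            # components
            assert mn.components(net)[0] == len(brute_components(net))
            # average shortest path
            expected = brute_avg_path(net)
            got = mn.avg_shortest_path(net)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-9)
            # degree distribution from raw degrees
            degs = {}
            for a, b in net.edges:
                degs[a] = degs.get(a, 0) + 1
                degs[b] = degs.get(b, 0) + 1
            freq = {}
            for node in net.nodes:
                d = degs.get(node, 0)
                freq[d] = freq.get(d, 0) + 100.0 / net.n_nodes
            got_dd = mn.degree_distribution(net).frequencies
            assert set(got_dd) == set(freq)
            for k in freq:
                assert got_dd[k] == pytest.approx(freq[k], abs=1e-9)
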
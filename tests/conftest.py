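"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from collections import deque

import networkx as nx
import numpy as np
import pytest

import cinet


@pytest.fixture
def barbell():
    """The hand-traceable 7-node network with its expected removal log."""
    return cinet.worked_example_fixture()


@pytest.fixture
def path5():
    return nx.path_graph(["A", "B", "C", "D", "E"])


def random_string_graph(n_nodes: int, p: float, seed: int) -> nx.Graph:
    """Seeded Erdős–Rényi graph over string node IDs."""
    g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with cinet)


def bfs_distances(graph: nx.Graph, source) -> dict:
    """Plain breadth-first distances, written from scratch."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in graph.adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def ci_score_oracle(graph: nx.Graph, node, ell: int) -> float:
    """Literal evaluation of (k_i−1)·Σ_{dist(i,j)=ell}(k_j−1) via BFS."""
    dist = bfs_distances(graph, node)
    shell = [v for v, d in dist.items() if d == ell]
    return float((graph.degree(node) - 1) * sum(graph.degree(j) - 1 for j in shell))


def enumerate_geodesics(graph: nx.Graph, s, t) -> list[list]:
    """Every shortest s–t path, by exhaustive depth-first enumeration."""
    dist = bfs_distances(graph, s)
    if t not in dist:
        return []
    paths = []

    def extend(partial):
        head = partial[-1]
        if head == t:
            paths.append(list(partial))
            return
        for v in graph.adj[head]:
            if dist.get(v) == dist[head] + 1 and dist[v] <= dist[t]:
                partial.append(v)
                extend(partial)
                partial.pop()

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def betweenness_oracle(graph: nx.Graph) -> dict:
    """c_B by explicit enumeration of every shortest path (unordered pairs)."""
    scores = {v: 0.0 for v in graph}
    nodes = sorted(graph.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            geodesics = enumerate_geodesics(graph, s, t)
            if not geodesics:
                continue
            for path in geodesics:
                for v in path[1:-1]:
                    scores[v] += 1.0 / len(geodesics)
    return scores


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p by summing hypergeometric terms directly."""
    row1, col1, total = a + b, a + c, a + b + c + d
    denom = math.comb(total, col1)
    p = 0.0
    for x in range(a, min(row1, col1) + 1):
        if col1 - x > total - row1:
            continue
        p += math.comb(row1, x) * math.comb(total - row1, col1 - x) / denom
    return min(p, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
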
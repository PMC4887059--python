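"""Independent brute-force oracles used to check the package's algorithms.

Everything here recomputes quantities by a different route than the
implementation: exhaustive path enumeration, recursive tree construction,
exact rational arithmetic, dense linear solves, and networkx.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np

from stagenet.io_formats import Graph


def to_networkx(graph: Graph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for u, v, w, _t in graph.edges():
        g.add_edge(u, v, weight=w)
    return g


def from_edges(nodes, edges) -> Graph:
    g = Graph()
    for n in nodes:
        g.add_node(n)
    for u, v in edges:
        g.add_edge(u, v)
    return g


def brute_betweenness(graph: Graph) -> dict[str, float]:
    """Betweenness by exhaustive simple-path enumeration (tiny graphs only)."""
    nxg = to_networkx(graph)
    nodes = sorted(graph.nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(nxg, s, t):
            continue
        paths = list(nx.all_shortest_paths(nxg, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def brute_closeness(graph: Graph) -> dict[str, float]:
    nxg = to_networkx(graph)
    out = {}
    for v in graph.nodes:
        dist = nx.single_source_shortest_path_length(nxg, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total else 0.0
    return out


def brute_bottleneck(graph: Graph) -> dict[str, float]:
    """Bottleneck by explicit recursive subtree counting on each BFS tree."""
    nxg = to_networkx(graph)
    bn = {v: 0.0 for v in graph.nodes}
    for s in sorted(graph.nodes):
        dist = nx.single_source_shortest_path_length(nxg, s)
        children: dict[str, list[str]] = {v: [] for v in dist}
        for v in dist:
            if v == s:
                continue
            parent = min(u for u in nxg.neighbors(v)
                         if dist.get(u, -2) == dist[v] - 1)
            children[parent].append(v)

        def subtree(v: str) -> int:
            return 1 + sum(subtree(c) for c in children[v])

        n_s = len(dist) - 1
        for v in dist:
            if v != s and subtree(v) > n_s / 4.0:
                bn[v] += 1.0
    return bn


def brute_diameter(graph: Graph) -> int:
    """Diameter of the largest component by all-pairs BFS."""
    nxg = to_networkx(graph)
    giant = max(nx.connected_components(nxg), key=len)
    if len(giant) == 1:
        return 0
    sub = nxg.subgraph(giant)
    return max(d for v in giant
               for d in nx.single_source_shortest_path_length(sub, v).values())


def exact_hypergeom_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational via binomial coefficients."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return acc


def bh_stepup(pvalues: list[float]) -> list[float]:
    """BH by the literal step-up recursion, restoring input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        q = min(prev, pvalues[i] * m / rank)
        q_sorted[rank - 1] = q
        prev = q
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out


def solve_influence(graph: Graph, restart: float = 0.15) -> np.ndarray:
    """Influence matrix by a dense linear solve: X = r (I - (1-r) W)^(-1)."""
    order = graph.sorted_nodes()
    n = len(order)
    idx = {v: i for i, v in enumerate(order)}
    W = np.zeros((n, n))
    for u, v, _w, _t in graph.edges():
        W[idx[u], idx[v]] = W[idx[v], idx[u]] = 1.0
    deg = W.sum(axis=1)
    for i in range(n):
        if deg[i]:
            W[i] /= deg[i]
        else:
            W[i, i] = 1.0
    return restart * np.linalg.inv(np.eye(n) - (1.0 - restart) * W)


def connected_labeled_graphs(n: int):
    """Yield every labeled connected graph on nodes A.. (n <= 5 sensible)."""
    nodes = [chr(ord("A") + i) for i in range(n)]
    pairs = list(itertools.combinations(nodes, 2))
    for mask in range(1 << len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        g = from_edges(nodes, edges)
        if len(g.connected_components()) == 1:
            yield g


def random_graph(rng: np.random.Generator, n_max: int = 12) -> Graph:
    """A random labeled graph (possibly disconnected), |V| in [2, n_max]."""
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"N{i:02d}" for i in range(n)]
    p = float(rng.uniform(0.15, 0.7))
    edges = [(u, v) for u, v in itertools.combinations(nodes, 2)
             if rng.random() < p]
    return from_edges(nodes, edges)
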
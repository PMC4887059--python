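"""Stage-network construction by seed expansion, plus topology diagnostics.

Each stage's novel driver genes seed a local expansion of the interactome:
candidate partners (non-seed interactome genes) are scored by their total
edge weight to the seed set and the strongest ``n_partners`` (default 20,
the conventional "related genes" count of seed-expansion servers) are added.
The stage network is the interactome subgraph induced on seeds plus
partners, optionally restricted to a configured set of interaction types.

Topology diagnostics mirror what network analyzers report for such
networks: the degree histogram with a log-log power-law fit (and a plain
linear fit for comparison), component structure, clustering, diameter and
mean shortest-path length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .centrality import _bfs_distances
from .io_formats import Graph

__all__ = [
    "StageNetwork",
    "DegreeFit",
    "TopologySummary",
    "build_stage_network",
    "degree_distribution",
    "fit_power_law",
    "topology_summary",
]


@dataclass
class StageNetwork:
    """A stage-specific network with per-node seed provenance."""

    stage: str
    graph: Graph
    seeds: set[str]
    partners: set[str]
    missing_seeds: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        return self.graph.nodes


def build_stage_network(seeds: Iterable[str], interactome: Graph,
                        n_partners: int = 20,
                        interaction_types: Iterable[str] | None = None,
                        stage: str = "") -> StageNetwork:
    """Expand driver seeds into a stage network.

    Partners are the ``n_partners`` non-seed genes with the largest total
    edge weight to the seed set (ties broken lexicographically).  Seeds
    absent from the interactome are kept as isolated, flagged nodes.  When
    ``interaction_types`` is given, edges of other types are dropped first.
    """
    seeds = {s.strip().upper() for s in seeds}
    if not seeds:
        raise ValueError("seed set is empty")
    if interactome.number_of_nodes() == 0:
        raise ValueError("interactome is empty")

    if interaction_types is not None:
        allowed = set(interaction_types)
        filtered = Graph()
        for n in interactome.nodes:
            filtered.add_node(n)
        for u, v, w, t in interactome.edges():
            if t in allowed:
                filtered.add_edge(u, v, w, t)
        interactome = filtered

    present = seeds & interactome.nodes
    missing = seeds - present
    if not present:
        raise ValueError("no seed gene present in the interactome")

    score: dict[str, float] = {}
    for s in present:
        for nbr in interactome.neighbors(s):
            if nbr not in seeds:
                score[nbr] = score.get(nbr, 0.0) + interactome.edge_weight(s, nbr)
    ranked = sorted(score, key=lambda g: (-score[g], g))
    partners = set(ranked[:n_partners])

    graph = interactome.subgraph(present | partners)
    for m in sorted(missing):
        graph.add_node(m)
    return StageNetwork(stage=stage, graph=graph, seeds=seeds,
                        partners=partners, missing_seeds=missing)


def degree_distribution(graph: Graph) -> dict[int, int]:
    """Histogram degree -> node count over all nodes."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    hist: dict[int, int] = {}
    for n in graph.nodes:
        d = graph.degree(n)
        hist[d] = hist.get(d, 0) + 1
    return hist


@dataclass
class DegreeFit:
    """Log-log OLS power-law fit of a degree histogram, with the plain
    linear fit of the same points for the power-vs-linear comparison."""

    exponent: float
    intercept: float
    r_squared: float
    linear_r_squared: float
    histogram: dict[int, int]
    degenerate: bool = False


def fit_power_law(histogram: Mapping[int, int]) -> DegreeFit:
    """OLS of log10(count) on log10(degree); zero-degree bins excluded.

    A zero-variance response (all counts equal) makes R^2 undefined; it is
    reported as 1.0 with ``degenerate=True`` so ranking logic never sees a
    missing value.
    """
    pts = sorted((k, c) for k, c in histogram.items() if k > 0 and c > 0)
    if len(pts) < 2:
        raise ValueError("need >= 2 distinct nonzero degrees to fit")
    deg = np.array([k for k, _ in pts], dtype=float)
    cnt = np.array([c for _, c in pts], dtype=float)
    x, y = np.log10(deg), np.log10(cnt)

    lin = stats.linregress(deg, cnt)
    linear_r2 = float(lin.rvalue ** 2) if not math.isnan(lin.rvalue) else 1.0

    if np.allclose(y, y[0]):
        return DegreeFit(exponent=0.0, intercept=float(y[0]), r_squared=1.0,
                         linear_r_squared=linear_r2,
                         histogram=dict(histogram), degenerate=True)
    res = stats.linregress(x, y)
    return DegreeFit(exponent=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2),
                     linear_r_squared=linear_r2,
                     histogram=dict(histogram))


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    n_components: int
    largest_component: int
    avg_clustering: float
    diameter: int
    avg_path_length: float


def _local_clustering(graph: Graph, node: str) -> float:
    nbrs = sorted(graph.neighbors(node))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(1 for i in range(k) for j in range(i + 1, k)
                if graph.has_edge(nbrs[i], nbrs[j]))
    return 2.0 * links / (k * (k - 1))


def topology_summary(graph: Graph) -> TopologySummary:
    """Component structure, mean local clustering, and the diameter and
    mean shortest-path length of the largest component."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = graph.connected_components()
    if len(comps) > 1:
        warnings.warn(f"graph has {len(comps)} components", stacklevel=2)
    giant = comps[0]
    diameter = 0
    total_dist = 0
    n_pairs = 0
    for v in giant:
        dist = _bfs_distances(graph, v)
        if len(giant) > 1:
            diameter = max(diameter, max(dist.values()))
            total_dist += sum(dist.values())
            n_pairs += len(dist) - 1
    avg_path = total_dist / n_pairs if n_pairs else 0.0
    clustering = sum(_local_clustering(graph, n) for n in graph.nodes)
    return TopologySummary(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        n_components=len(comps),
        largest_component=len(giant),
        avg_clustering=clustering / graph.number_of_nodes(),
        diameter=diameter,
        avg_path_length=avg_path,
    )
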
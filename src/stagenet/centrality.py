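"""Node centrality metrics and consensus hub calling.

Three complementary metrics rank the nodes of each stage network:

* **betweenness** — the number of shortest paths between node pairs that pass
  through a node (Brandes' accumulation, unnormalized, each unordered pair
  counted once);
* **closeness** — (reachable - 1) / (sum of distances to reachable nodes),
  computed within the node's connected component;
* **bottleneck** — for each root ``s``, build the BFS shortest-path tree
  (deterministic: each node's parent is the lexicographically smallest
  equal-distance predecessor); a node ``v != s`` is a bottleneck for ``s``
  when its subtree holds more than a quarter of the ``n_s`` non-root tree
  nodes; the score is the number of roots for which ``v`` is a bottleneck.

The top-k (default 15) lists of the three rankings are intersected to call
**consensus hubs**, and hubs that are also stage driver seeds are the
**hub driver** genes.  All shortest paths are unweighted: edge weights carry
evidence provenance, not distance.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import Graph

__all__ = [
    "CentralityReport",
    "betweenness",
    "closeness",
    "bottleneck",
    "top_k",
    "consensus_hubs",
    "hub_drivers",
    "centrality_report",
]


def betweenness(graph: Graph) -> dict[str, float]:
    """Exact unweighted betweenness via Brandes' algorithm.

    Scores count each unordered pair once and are not normalized (the
    downstream use is ranking, which normalization cannot change).
    """
    bc = {v: 0.0 for v in graph.nodes}
    for s in graph.sorted_nodes():
        # single-source shortest-path counts
        stack: list[str] = []
        preds: dict[str, list[str]] = {v: [] for v in bc}
        sigma = {v: 0.0 for v in bc}
        dist = {v: -1 for v in bc}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in graph.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = {v: 0.0 for v in bc}
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: x / 2.0 for v, x in bc.items()}


def _bfs_distances(graph: Graph, source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in graph.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def closeness(graph: Graph) -> dict[str, float]:
    """Within-component closeness: (reachable-1)/sum(distances); isolated -> 0."""
    out: dict[str, float] = {}
    for v in graph.nodes:
        dist = _bfs_distances(graph, v)
        total = sum(dist.values())
        reachable = len(dist) - 1
        out[v] = reachable / total if total > 0 else 0.0
    return out


def _shortest_path_tree(graph: Graph, root: str) -> dict[str, str]:
    """Deterministic BFS tree: parent = lexicographically smallest
    predecessor at distance-1.  Returns child -> parent over reachable nodes."""
    dist = _bfs_distances(graph, root)
    parent: dict[str, str] = {}
    for v in dist:
        if v == root:
            continue
        parent[v] = min(u for u in graph.neighbors(v)
                        if dist.get(u, -2) == dist[v] - 1)
    return parent


def bottleneck(graph: Graph, strict: bool = True,
               count_root: bool = False) -> dict[str, float]:
    """Bottleneck centrality from deterministic BFS shortest-path trees.

    For each root the subtree size of every non-root node is compared with
    ``n_s / 4`` where ``n_s`` counts the reachable nodes excluding the root
    (include it with ``count_root=True``); the comparison is strict by
    default.  A node's score is the number of roots electing it.
    """
    bn = {v: 0.0 for v in graph.nodes}
    for s in graph.sorted_nodes():
        parent = _shortest_path_tree(graph, s)
        if not parent:
            continue
        sub = {v: 1 for v in parent}
        sub[s] = 1
        # accumulate child counts bottom-up: order children by decreasing depth
        dist = _bfs_distances(graph, s)
        for v in sorted(parent, key=lambda x: -dist[x]):
            sub[parent[v]] += sub[v]
        n_s = len(parent) + (1 if count_root else 0)
        threshold = n_s / 4.0
        for v in parent:
            size = sub[v]
            if (size > threshold) if strict else (size >= threshold):
                bn[v] += 1.0
    return bn


def top_k(scores: Mapping[str, float], k: int = 15) -> list[str]:
    """Top-k genes by descending score, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(scores, key=lambda g: (-scores[g], g))
    return ranked[:k]


def consensus_hubs(*ranked_lists: Sequence[str]) -> set[str]:
    """Intersection of the member sets of the supplied ranked lists."""
    if not ranked_lists:
        return set()
    out = set(ranked_lists[0])
    for lst in ranked_lists[1:]:
        out &= set(lst)
    return out


def hub_drivers(hubs: Iterable[str], stage_driver_seeds: Iterable[str]) -> set[str]:
    """Genes that are both consensus hubs and stage driver seeds."""
    return set(hubs) & set(stage_driver_seeds)


@dataclass
class CentralityReport:
    """Scores, rankings and hub calls for one stage network."""

    scores: dict[str, dict[str, float]]       # metric -> gene -> score
    top: dict[str, list[str]] = field(default_factory=dict)
    hubs: set[str] = field(default_factory=set)
    hub_driver_genes: set[str] = field(default_factory=set)
    k: int = 15


def centrality_report(graph: Graph, driver_seeds: Iterable[str] = (),
                      k: int = 15) -> CentralityReport:
    """Compute all three metrics, top-k lists, consensus hubs, hub drivers."""
    scores = {
        "betweenness": betweenness(graph),
        "closeness": closeness(graph),
        "bottleneck": bottleneck(graph),
    }
    top = {m: top_k(s, k) for m, s in scores.items()}
    hubs = consensus_hubs(*top.values())
    return CentralityReport(
        scores=scores, top=top, hubs=hubs,
        hub_driver_genes=hub_drivers(hubs, driver_seeds), k=k)
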
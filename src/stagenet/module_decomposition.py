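"""Overlapping module decomposition via a community landscape.

The decomposition follows the community-landscape idea behind overlapping
module detectors: every node spreads influence over the network, the total
incoming influence defines a scalar "landscape" height per node, local
maxima of the landscape are module centers, and each node divides its
membership among the centers in proportion to the influence each center
exerts on it.  Concretely:

* **influence** — row ``i`` of the influence matrix is the stationary
  restart-weighted spreading vector from node ``i`` (personalized
  random-walk with restart over the degree-normalized adjacency);
* **landscape height** of node ``j`` = total influence received,
  ``sum_i influence(i -> j)``;
* **centers** — nodes whose height is >= every neighbour's with strict
  excess over at least one (plateaus keep only their lexicographically
  smallest member, so a perfectly symmetric clique yields one center);
* **membership** ``m(j, c)`` = influence of center ``c`` on ``j``,
  normalized over centers so each covered node's memberships sum to 1;
* **effective size** of a module = participation ratio
  ``(sum m)^2 / sum m^2`` of its membership column — the number of nodes a
  module "effectively" contains once fractional membership is accounted for.

The procedure is deterministic and equivariant under node relabeling (up to
the lexicographic tie rules, which exist precisely to pin down ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io_formats import Graph

__all__ = [
    "ModuleDecomposition",
    "Module",
    "influence_matrix",
    "community_landscape",
    "find_centers",
    "memberships",
    "effective_size",
    "decompose",
]


def influence_matrix(graph: Graph, restart: float = 0.15,
                     tol: float = 1e-8, max_iter: int = 10_000
                     ) -> tuple[np.ndarray, list[str]]:
    """Pairwise influence by personalized random-walk with restart.

    Returns ``(matrix, node_order)`` with nodes sorted lexicographically;
    row ``i`` sums to 1 and is the stationary distribution of a walk that
    restarts at node ``i`` with probability ``restart`` and otherwise steps
    to a uniformly random neighbour.  Isolated nodes keep all influence on
    themselves.
    """
    if not 0.0 < restart <= 1.0:
        raise ValueError("restart must be in (0, 1]")
    order = graph.sorted_nodes()
    n = len(order)
    idx = {v: i for i, v in enumerate(order)}
    W = np.zeros((n, n))
    for u, v, _w, _t in graph.edges():
        W[idx[u], idx[v]] = 1.0
        W[idx[v], idx[u]] = 1.0
    deg = W.sum(axis=1)
    nz = deg > 0
    W[nz] /= deg[nz, None]
    W[~nz] = 0.0
    # isolated nodes: walk stays put
    for i in np.where(~nz)[0]:
        W[i, i] = 1.0

    X = np.eye(n)
    for _ in range(max_iter):
        X_next = restart * np.eye(n) + (1.0 - restart) * X @ W
        if np.max(np.abs(X_next - X)) < tol:
            return X_next, order
        X = X_next
    raise ArithmeticError(
        f"influence iteration did not converge within {max_iter} steps")


def community_landscape(influence: np.ndarray) -> np.ndarray:
    """Height of node j = total influence received, sum_i influence[i, j]."""
    return influence.sum(axis=0)


def find_centers(graph: Graph, heights: Mapping[str, float] | np.ndarray,
                 order: list[str] | None = None) -> list[str]:
    """Local maxima of the landscape, one center per tied plateau.

    A node qualifies when its height is >= all neighbours' and either
    strictly exceeds at least one neighbour or the node is isolated.  Nodes
    on a flat plateau (connected through equal-height neighbours, none
    higher) contribute a single center: the lexicographically smallest.
    """
    if isinstance(heights, np.ndarray):
        if order is None:
            raise ValueError("order required with array heights")
        h = {v: float(heights[i]) for i, v in enumerate(order)}
    else:
        h = dict(heights)
    eps = 1e-12

    centers: set[str] = set()
    for v in graph.nodes:
        nbrs = graph.neighbors(v)
        if all(h[v] >= h[u] - eps for u in nbrs) and (
                not nbrs or any(h[v] > h[u] + eps for u in nbrs)):
            centers.add(v)

    # a flat maximum plateau (equal heights, no higher neighbour anywhere)
    # yields no strict-excess center; grant it one: its smallest label
    seen: set[str] = set()
    for v in graph.sorted_nodes():
        if v in seen:
            continue
        plateau = {v}
        stack = [v]
        while stack:
            cur = stack.pop()
            for u in graph.neighbors(cur):
                if u not in plateau and abs(h[u] - h[v]) <= eps:
                    plateau.add(u)
                    stack.append(u)
        seen |= plateau
        if plateau & centers or len(plateau) == 1:
            continue
        is_max = all(h[u] <= h[v] + eps
                     for p in plateau for u in graph.neighbors(p))
        if is_max:
            centers.add(min(plateau))
    return sorted(centers)


def memberships(influence: np.ndarray, order: list[str],
                centers: list[str]) -> np.ndarray:
    """Membership matrix m[j, c] = influence(center c -> node j), normalized
    across centers for each node j (rows sum to 1)."""
    if not centers:
        raise ValueError("need at least one center")
    idx = {v: i for i, v in enumerate(order)}
    M = np.stack([influence[idx[c]] for c in centers], axis=1)  # n x k
    totals = M.sum(axis=1, keepdims=True)
    nz = totals[:, 0] > 0
    M[nz] /= totals[nz]
    return M


def effective_size(column: np.ndarray) -> float:
    """Participation ratio (sum m)^2 / sum m^2 of one membership column."""
    col = np.asarray(column, dtype=float)
    denom = float((col ** 2).sum())
    if denom == 0.0:
        raise ValueError("all-zero membership column")
    return float(col.sum() ** 2 / denom)


@dataclass
class Module:
    center: str
    effective_size: float
    members: list[str]               # membership >= threshold, sorted
    driver_members: list[str] = field(default_factory=list)
    hub_members: list[str] = field(default_factory=list)


@dataclass
class ModuleDecomposition:
    modules: list[Module]            # sorted by decreasing effective size
    centers: list[str]
    membership: np.ndarray           # n x k, rows normalized
    node_order: list[str]
    threshold: float
    center_graph_edges: list[tuple[str, str]] = field(default_factory=list)

    def module_for(self, center: str) -> Module:
        for m in self.modules:
            if m.center == center:
                return m
        raise KeyError(center)


def decompose(graph: Graph, driver_seeds: Iterable[str] = (),
              hubs: Iterable[str] = (), restart: float = 0.15,
              threshold: float = 0.3) -> ModuleDecomposition:
    """Full overlapping decomposition of a stage network.

    Members of a module are the nodes with membership >= ``threshold`` in
    its column; driver and hub cross-references are attached per module, and
    centers whose modules share members are linked in the center graph.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    drivers = {d.strip().upper() for d in driver_seeds}
    hubset = {h.strip().upper() for h in hubs}

    infl, order = influence_matrix(graph, restart=restart)
    heights = community_landscape(infl)
    centers = find_centers(graph, heights, order)
    M = memberships(infl, order, centers)

    modules = []
    member_sets: dict[str, set[str]] = {}
    for ci, center in enumerate(centers):
        col = M[:, ci]
        mem = sorted(order[j] for j in np.flatnonzero(col >= threshold))
        member_sets[center] = set(mem)
        modules.append(Module(
            center=center,
            effective_size=effective_size(col),
            members=mem,
            driver_members=sorted(set(mem) & drivers),
            hub_members=sorted(set(mem) & hubset),
        ))
    modules.sort(key=lambda m: (-m.effective_size, m.center))

    center_edges = [
        (a, b)
        for i, a in enumerate(centers) for b in centers[i + 1:]
        if member_sets[a] & member_sets[b]
    ]
    return ModuleDecomposition(
        modules=modules, centers=centers, membership=M, node_order=order,
        threshold=threshold, center_graph_edges=center_edges)
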
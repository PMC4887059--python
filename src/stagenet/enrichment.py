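"""Hypergeometric over-representation of annotation terms in a network.

For a network of ``n`` annotated genes drawn from a universe of ``N`` genes
of which ``K`` carry a given term, the over-representation p-value of seeing
``k`` or more term genes in the network is the hypergeometric upper tail
``P(X >= k)``.  P-values over all tested terms (those with at least one
network gene) are corrected with the Benjamini-Hochberg step-up procedure to
q-values.  Each record also carries the coverage flag used in stage-network
reports: "Y" when the network contains more than 20% of the term's genes.

The universe defaults to every gene appearing in the annotation collection
(the "complete annotation" convention); a custom reference set may be
supplied.  Annotations are assumed pre-flattened (term -> gene set); no
ontology-graph propagation is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EnrichmentRecord",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
]

COVERAGE_CUTOFF = 0.2


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # survival function is computed stably in log space by scipy
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg q-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


@dataclass
class EnrichmentRecord:
    term: str
    description: str
    p_value: float
    q_value: float
    k: int                    # network genes with the term
    K: int                    # universe genes with the term
    n: int                    # annotated network genes
    N: int                    # universe size
    coverage_flag: str        # "Y" if k/K > 0.2 else "N"
    significant: bool
    hub_members: list[str] = field(default_factory=list)
    other_members: list[str] = field(default_factory=list)


def enrich(network_genes: Iterable[str],
           annotations: Mapping[str, set[str]],
           universe: Iterable[str] | None = None,
           q_threshold: float = 0.05,
           hubs: Iterable[str] = (),
           descriptions: Mapping[str, str] | None = None
           ) -> list[EnrichmentRecord]:
    """Test every term with at least one network gene; BH-correct; sort by q.

    ``universe`` defaults to the union of all annotated genes; network genes
    outside the universe are ignored for counting.
    """
    if universe is None:
        uni: set[str] = set()
        for genes in annotations.values():
            uni |= genes
    else:
        uni = set(universe)
    if not uni:
        raise ValueError("empty annotation universe")

    net = set(network_genes) & uni
    hubset = set(hubs)
    N = len(uni)
    n = len(net)

    tested: list[tuple[str, int, int, set[str]]] = []
    for term in sorted(annotations):
        term_genes = annotations[term] & uni
        overlap = term_genes & net
        if overlap:
            tested.append((term, len(overlap), len(term_genes), overlap))
    if not tested:
        return []

    pvals = [hypergeom_upper_tail(k, K, n, N) for _, k, K, _ in tested]
    qvals = bh_adjust(pvals)

    records = []
    for (term, k, K, overlap), p, q in zip(tested, pvals, qvals):
        records.append(EnrichmentRecord(
            term=term,
            description=(descriptions or {}).get(term, ""),
            p_value=p,
            q_value=q,
            k=k, K=K, n=n, N=N,
            coverage_flag="Y" if k / K > COVERAGE_CUTOFF else "N",
            significant=q <= q_threshold,
            hub_members=sorted(overlap & hubset),
            other_members=sorted(overlap - hubset),
        ))
    records.sort(key=lambda r: (r.q_value, r.p_value, r.term))
    return records
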
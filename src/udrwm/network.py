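"""Gene-network statistics: seed subnetwork extraction, Jaccard similarity,
and Fisher exact gene-set overlap.

Subnetwork extraction keeps every edge with at least one endpoint in the
seed set (e.g. disorder risk genes or autoencoder-derived associated
genes) and returns the largest connected component of the result; ties go
to the component with more edges, then to the lexicographically smallest
node set, so the rule is fully deterministic.

Enrichment between two subnetworks is the Jaccard similarity of their node
sets, |A n B| / |A u B| (larger = more enriched).  Gene-set overlap
significance is the one-sided Fisher exact test (over-representation)
against a configurable gene universe.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy import stats

__all__ = ["extract_subnetwork", "jaccard", "overlap_fisher", "bonferroni"]


def extract_subnetwork(net: nx.Graph, seeds: set[str]) -> nx.Graph:
    """Largest connected component of the edges touching the seed set."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    seeds = set(seeds)
    kept = [(a, b) for a, b in net.edges() if a in seeds or b in seeds]
    sub = nx.Graph()
    sub.add_edges_from(kept)
    if sub.number_of_nodes() == 0:
        return sub  # seeds touch no edge: empty network (documented contract)
    components = list(nx.connected_components(sub))
    max_size = max(len(c) for c in components)
    cands = [c for c in components if len(c) == max_size]
    max_edges = max(sub.subgraph(c).number_of_edges() for c in cands)
    cands = [c for c in cands if sub.subgraph(c).number_of_edges() == max_edges]
    best = min(cands, key=lambda c: tuple(sorted(c)))
    return nx.Graph(sub.subgraph(best))


def jaccard(A: set, B: set) -> float:
    """|A n B| / |A u B|; symmetric, in [0,1], equal to 1 iff A == B."""
    A, B = set(A), set(B)
    union = A | B
    if not union:
        raise ValueError("both sets empty")
    return len(A & B) / len(union)


def overlap_fisher(
    set_a: set,
    set_b: set,
    universe: set,
    alternative: str = "greater",
) -> tuple[float, float, tuple[int, int, int, int]]:
    """One-sided Fisher exact test for over-representation of A in B.

    Returns ``(odds_ratio, p_value, (both, a_only, b_only, neither))``.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        outside = (set_a | set_b) - universe
        raise ValueError(f"members outside the universe: {sorted(outside)[:5]}")
    both = len(set_a & set_b)
    a_only = len(set_a - set_b)
    b_only = len(set_b - set_a)
    neither = len(universe) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]])
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return float(odds), float(p), (both, a_only, b_only, neither)


def bonferroni(p_values, n_tests: int | None = None):
    """min(1, m * p) for each p; m defaults to the number of p-values."""
    p = np.asarray(list(p_values), dtype=np.float64)
    m = n_tests if n_tests is not None else p.size
    return np.minimum(1.0, m * p)
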
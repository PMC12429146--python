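"""Gene-set over-representation with hypergeometric tests and BH FDR."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .core import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrichment",
    "bh_adjust",
    "significant_sets",
]

MIN_SET_SIZE = 3  # sets smaller than this after universe intersection are skipped


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    n_query: int
    n_set: int
    n_overlap: int
    n_universe: int
    p_value: float
    q_value: float | None = None


def hypergeom_enrichment(
    query_genes,
    collection: GeneSetCollection,
    universe,
    min_set_size: int = MIN_SET_SIZE,
) -> list[EnrichmentResult]:
    """Over-representation of ``query_genes`` in each set of ``collection``.

    Each set is intersected with the universe first; the query must be a
    subset of the universe. p = P(X >= overlap), X ~ Hypergeom(universe,
    set, query). Results carry BH-adjusted q values and come back sorted by
    p ascending (set name breaks ties).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query_genes)
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe (e.g. {extra})")
    n_u, n_q = len(universe), len(query)
    results = []
    for name, members in collection.items():
        in_universe = members & universe
        if len(in_universe) < min_set_size:
            warnings.warn(
                f"gene set {name!r} has < {min_set_size} members in the "
                f"universe; skipped",
                stacklevel=2,
            )
            continue
        k = len(query & in_universe)
        p = float(hypergeom.sf(k - 1, n_u, len(in_universe), n_q))
        results.append(
            EnrichmentResult(name, n_q, len(in_universe), k, n_u, min(p, 1.0))
        )
    if results:
        qs = bh_adjust([r.p_value for r in results])
        results = [
            EnrichmentResult(
                r.set_name, r.n_query, r.n_set, r.n_overlap, r.n_universe,
                r.p_value, float(q),
            )
            for r, q in zip(results, qs)
        ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def significant_sets(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Sets with BH-adjusted q below alpha."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return [r for r in results if r.q_value is not None and r.q_value < alpha]
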
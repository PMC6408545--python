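"""Hypergeometric over-representation analysis with BH-FDR control.

Tests whether a query gene list (a signature, a disease network, or the
cross-disease overlap) shares more members with predefined gene sets
than expected by chance when drawing from a declared universe.  Only
over-representation (upper tail) is tested; q-values come from the
Benjamini–Hochberg step-up rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneSetCollection

logger = logging.getLogger("comonet")


@dataclass
class EnrichmentResult:
    name: str
    universe_size: int   # N
    set_size: int        # K, within the universe
    query_size: int      # n, within the universe
    overlap: int         # k
    p_value: float
    q_value: float
    overlap_symbols: tuple[str, ...]
    significant: bool


def hypergeometric_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q(i) = min over j ≥ i in sorted order of m·p(j)/j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    fdr: float = 0.05,
    min_set_size: int = 5,
    max_set_size: int = 2000,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` against each set.

    Query symbols outside the universe are dropped (count logged); sets
    are restricted to their members within the universe and must have
    between ``min_set_size`` and ``max_set_size`` of them to be tested.
    Results with at least one overlapping gene are returned sorted by
    p-value ascending, flagged significant when q ≤ ``fdr``.
    """
    universe_set = {g.upper() for g in universe}
    if not universe_set:
        raise ValueError("empty universe")
    raw_query = [g.upper() for g in query]
    query_set = {g for g in raw_query if g in universe_set}
    dropped = len(set(raw_query)) - len(query_set)
    if dropped:
        logger.info("enrich: dropped %d query symbols outside the universe", dropped)
    N, n = len(universe_set), len(query_set)

    results: list[EnrichmentResult] = []
    for gs in sets:
        members = set(gs.members) & universe_set
        if not min_set_size <= len(members) <= max_set_size:
            continue
        overlap = sorted(members & query_set)
        if not overlap:
            continue
        p = hypergeometric_pvalue(N, len(members), n, len(overlap))
        results.append(
            EnrichmentResult(
                name=gs.name,
                universe_size=N,
                set_size=len(members),
                query_size=n,
                overlap=len(overlap),
                p_value=p,
                q_value=np.nan,
                overlap_symbols=tuple(overlap),
                significant=False,
            )
        )
    qvals = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qvals):
        r.q_value = q
        r.significant = q <= fdr
    results.sort(key=lambda r: (r.p_value, r.name))
    return results
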
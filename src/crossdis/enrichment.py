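"""Over-representation analysis (ORA) of gene lists against gene-set libraries.

One-sided Fisher/hypergeometric upper-tail test per term, BH adjustment
across the library, a hit-count + significance filter, and the set of terms
shared between two diseases' filtered results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

from .deg import bh_adjust
from .io_formats import GeneSetLibrary

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    set_size: int
    hit_count: int
    hit_genes: frozenset[str]
    p: float
    adj_p: float


def ora(query: set[str], library: GeneSetLibrary, universe: set[str]) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``query`` in each library set.

    p = P(X ≥ hit_count) for X hypergeometric(|universe|, |term ∩ universe|,
    |query|). Query genes outside the universe are dropped with a warning;
    terms are intersected with the universe. BH across all library terms.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("empty universe")
    query = {g.upper() for g in query}
    outside = query - universe
    if outside:
        logger.warning("dropping %d query gene(s) outside the universe", len(outside))
        query &= universe

    rows = []
    for term_id, gs in library.items():
        term_genes = gs.genes & universe
        hits = query & term_genes
        k, M, K, n = len(hits), len(universe), len(term_genes), len(query)
        p = float(hypergeom.sf(k - 1, M, K, n)) if k > 0 else 1.0
        rows.append(EnrichmentRow(term_id, gs.name, K, k, frozenset(hits),
                                  min(p, 1.0), 1.0))
    adj = bh_adjust([r.p for r in rows])
    for r, a in zip(rows, adj):
        r.adj_p = float(a)
    return rows


def filter_terms(rows: list[EnrichmentRow], min_genes: int = 5, alpha: float = 0.05,
                 use_adjusted: bool = True) -> list[EnrichmentRow]:
    """Keep terms with ≥ min_genes hits and (adjusted) p ≤ alpha, sorted by p.

    Both boundaries are inclusive. ``use_adjusted=False`` filters on the raw
    p (the convention sometimes applied to pathway libraries, versus
    adjusted p for GO terms).
    """
    kept = [r for r in rows
            if r.hit_count >= min_genes
            and (r.adj_p if use_adjusted else r.p) <= alpha]
    return sorted(kept, key=lambda r: (r.p, r.term_id))


@dataclass
class SharedTerm:
    term_id: str
    hit_genes_a: frozenset[str]
    hit_genes_b: frozenset[str]
    shared_genes: frozenset[str]


def shared_terms(rows_a: list[EnrichmentRow], rows_b: list[EnrichmentRow]) -> list[SharedTerm]:
    """Terms enriched in both diseases, with each side's hits and their overlap."""
    by_b = {r.term_id: r for r in rows_b}
    out = []
    for ra in rows_a:
        rb = by_b.get(ra.term_id)
        if rb is None:
            continue
        out.append(SharedTerm(ra.term_id, ra.hit_genes, rb.hit_genes,
                              ra.hit_genes & rb.hit_genes))
    return out
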
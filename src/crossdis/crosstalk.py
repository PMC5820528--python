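"""Pathway crosstalk scoring between the two diseases' enriched pathways.

Two enriched pathways crosstalk when each carries at least ``min_deg`` DEG
hits (at the enrichment significance threshold), they share at least one
DEG and at least one PPI edge, and their Jaccard coefficient is at least
``jc_min``. Pairs are scored by the average of the Jaccard coefficient
JC = |A∩B|/|A∪B| and the overlap (Szymkiewicz–Simpson) coefficient
OC = |A∩B|/min(|A|,|B|), classified by OC, and flagged strong when more
than 3 DEGs are shared.

By default the sets A, B are each pathway's DEG *hit* set (the crosstalk
eligibility rules count DEGs); full pathway membership is available via
``use_full_membership``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .enrichment import EnrichmentRow
from .io_formats import GeneSetLibrary


@dataclass
class CrosstalkPair:
    term_a: str
    term_b: str
    shared_genes: frozenset[str]
    shared_edges: frozenset[frozenset[str]]
    jc: float
    oc: float
    score: float
    strong: bool
    overlap_class: str


def jaccard(a: set[str], b: set[str]) -> float:
    """|A∩B| / |A∪B|."""
    if not a or not b:
        raise ValueError("jaccard requires non-empty sets")
    return len(a & b) / len(a | b)


def overlap_coefficient(a: set[str], b: set[str]) -> float:
    """|A∩B| / min(|A|, |B|); 1 whenever one set contains the other."""
    if not a or not b:
        raise ValueError("overlap_coefficient requires non-empty sets")
    return len(a & b) / min(len(a), len(b))


def classify_overlap(oc: float) -> str:
    """Bin an overlap coefficient: complete / high / moderate / low / none.

    complete at OC = 1; high for 0.5 ≤ OC < 1; moderate for 0.2 ≤ OC < 0.5;
    low for 0 < OC < 0.2; none at 0.
    """
    if not 0.0 <= oc <= 1.0:
        raise ValueError(f"overlap coefficient out of range: {oc}")
    if oc == 1.0:
        return "complete"
    if oc >= 0.5:
        return "high"
    if oc >= 0.2:
        return "moderate"
    if oc > 0.0:
        return "low"
    return "none"


def pathway_edge_set(term_genes: set[str], g: nx.Graph) -> frozenset[frozenset[str]]:
    """Network edges with both endpoints inside the pathway."""
    term_genes = {x.upper() for x in term_genes}
    return frozenset(frozenset((a, b)) for a, b in g.edges
                     if a in term_genes and b in term_genes)


def find_crosstalk(enriched_a: list[EnrichmentRow], enriched_b: list[EnrichmentRow],
                   network: nx.Graph, library: GeneSetLibrary | None = None,
                   min_deg: int = 5, alpha: float = 0.05, jc_min: float = 0.01,
                   use_full_membership: bool = False) -> list[CrosstalkPair]:
    """Score all cross-disease pathway pairs and rank them.

    Candidate pairs take one term from each disease's (pre-filtered)
    enrichment result, including the same term enriched in both. Eligible
    pairs satisfy: ≥ min_deg DEG hits in each term, ≥1 shared DEG, ≥1
    shared PPI edge between the two terms' edge sets, and JC ≥ jc_min.
    Output sorted by descending score, then |shared genes|, then term ids.
    """
    if use_full_membership and library is None:
        raise ValueError("full-membership mode requires the gene-set library")

    def eligible(rows: list[EnrichmentRow]) -> list[EnrichmentRow]:
        return [r for r in rows if r.hit_count >= min_deg and r.adj_p <= alpha]

    def gene_set(row: EnrichmentRow) -> set[str]:
        if use_full_membership:
            if row.term_id not in library:
                raise ValueError(f"term {row.term_id} missing from library")
            return set(library.genes(row.term_id))
        return set(row.hit_genes)

    edge_cache: dict[str, frozenset[frozenset[str]]] = {}

    def edges_of(row: EnrichmentRow) -> frozenset[frozenset[str]]:
        if row.term_id not in edge_cache:
            # edge overlap is always judged on the term's DEG hits in the
            # zero-order network, matching how overlapping edges are counted
            edge_cache[row.term_id] = pathway_edge_set(set(row.hit_genes), network)
        return edge_cache[row.term_id]

    pairs: list[CrosstalkPair] = []
    for ra in eligible(enriched_a):
        for rb in eligible(enriched_b):
            shared = frozenset(ra.hit_genes & rb.hit_genes)
            if not shared:
                continue
            shared_edges = edges_of(ra) & edges_of(rb)
            if not shared_edges:
                continue
            a_set, b_set = gene_set(ra), gene_set(rb)
            jc = jaccard(a_set, b_set)
            if jc < jc_min:
                continue
            oc = overlap_coefficient(a_set, b_set)
            pairs.append(CrosstalkPair(
                term_a=ra.term_id, term_b=rb.term_id,
                shared_genes=shared, shared_edges=shared_edges,
                jc=jc, oc=oc, score=(jc + oc) / 2.0,
                strong=len(shared) > 3,
                overlap_class=classify_overlap(oc),
            ))
    pairs.sort(key=lambda p: (-p.score, -len(p.shared_genes), p.term_a, p.term_b))
    return pairs
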
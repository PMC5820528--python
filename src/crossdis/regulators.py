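"""Upstream transcription-factor and kinase enrichment with a combined score.

Given the shared up- or down-regulated genes, each candidate regulator
(TF→target or kinase→substrate set) gets a one-sided Fisher/hypergeometric
over-representation p-value and a rank-deviation z-score: the regulator's
rank (by p) for the real query is standardized against the distribution of
its ranks over seeded random queries of the same size. Regulators are
ranked by the combined score

    C = −ln(p) · |z|

A Genes2Networks-style expansion then connects the top regulators to their
targets through PPI intermediates, and kinase enrichment is run on the
expanded subnetwork's nodes with identical statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .io_formats import GeneSetLibrary

logger = logging.getLogger(__name__)

DEFAULT_N_BACKGROUND = 100
DEFAULT_TOP_K = 10


@dataclass
class RegulatorRow:
    regulator_id: str
    p: float
    z: float
    combined: float
    targets_hit: frozenset[str]
    rank: int = 0


def combined_score(p: float, z: float) -> float:
    """C-score −ln(p)·|z| used to rank upstream regulators."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return -math.log(p) * abs(z)


def _overlap_pvals(indicator: np.ndarray, set_sizes: np.ndarray,
                   query_idx: np.ndarray, n_universe: int) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric upper-tail p per regulator for one query (by index)."""
    hits = indicator[:, query_idx].sum(axis=1)
    p = hypergeom.sf(hits - 1, n_universe, set_sizes, query_idx.size)
    p = np.where(hits > 0, p, 1.0)
    return np.minimum(p, 1.0), hits


def regulator_enrichment(query: set[str], library: GeneSetLibrary, universe: set[str],
                         n_background: int = DEFAULT_N_BACKGROUND,
                         seed: int = 0, top_k: int | None = DEFAULT_TOP_K) -> list[RegulatorRow]:
    """Score every regulator in the library against a query gene set.

    z is the standardized rank deviation: rank regulators by p for the real
    query and for ``n_background`` random queries of equal size drawn from
    the universe (seeded); z = (real rank − mean background rank) / sd.
    Better-than-background regulators therefore get negative z, and the
    combined score uses |z|. Regulators with no targets in the universe are
    excluded. ``top_k=None`` returns the full ranking.
    """
    universe_list = sorted({g.upper() for g in universe})
    if not universe_list:
        raise ValueError("empty universe")
    idx_of = {g: i for i, g in enumerate(universe_list)}
    query = {g.upper() for g in query} & set(universe_list)

    regs, rows_ind = [], []
    for term_id, gs in library.items():
        in_universe = [idx_of[g] for g in gs.genes if g in idx_of]
        if not in_universe:
            logger.warning("regulator %s has no targets in the universe; excluded",
                           term_id)
            continue
        ind = np.zeros(len(universe_list), dtype=bool)
        ind[in_universe] = True
        regs.append(term_id)
        rows_ind.append(ind)
    if not regs:
        return []
    indicator = np.vstack(rows_ind)
    set_sizes = indicator.sum(axis=1)

    query_idx = np.array(sorted(idx_of[g] for g in query), dtype=int)
    if query_idx.size == 0:
        p_real = np.ones(len(regs))
        hits = np.zeros(len(regs), dtype=int)
    else:
        p_real, hits = _overlap_pvals(indicator, set_sizes, query_idx, len(universe_list))

    # rank 1 = smallest p; average ranks for ties so iteration order is moot
    def ranks(p: np.ndarray) -> np.ndarray:
        order = np.argsort(p, kind="stable")
        r = np.empty_like(p)
        r[order] = np.arange(1, p.size + 1)
        # tie-average
        for val in np.unique(p):
            mask = p == val
            if mask.sum() > 1:
                r[mask] = r[mask].mean()
        return r

    real_rank = ranks(p_real)
    rng = np.random.default_rng(seed)
    bg_ranks = np.empty((n_background, len(regs)))
    qsize = max(query_idx.size, 1)
    for b in range(n_background):
        bg_idx = rng.choice(len(universe_list), size=min(qsize, len(universe_list)),
                            replace=False)
        p_bg, _ = _overlap_pvals(indicator, set_sizes, np.sort(bg_idx), len(universe_list))
        bg_ranks[b] = ranks(p_bg)

    mu = bg_ranks.mean(axis=0)
    sd = bg_ranks.std(axis=0, ddof=1) if n_background > 1 else np.zeros(len(regs))
    z = np.where(sd > 0, (real_rank - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    out = []
    for i, term_id in enumerate(regs):
        p = float(max(p_real[i], np.finfo(float).tiny))
        out.append(RegulatorRow(
            regulator_id=term_id, p=p, z=float(z[i]),
            combined=combined_score(p, float(z[i])),
            targets_hit=frozenset(g for g in query if indicator[i, idx_of[g]]),
        ))
    out.sort(key=lambda r: (-r.combined, r.p, r.regulator_id))
    for rank, r in enumerate(out, start=1):
        r.rank = rank
    return out[:top_k] if top_k is not None else out


@dataclass
class ExpandedNetwork:
    graph: nx.Graph
    regulators: frozenset[str]
    targets: frozenset[str]
    intermediates: frozenset[str]
    direct_counts: dict[str, int] = field(default_factory=dict)
    indirect_counts: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def expand_g2n(top_regulators: set[str], targets: set[str], ppi: nx.Graph,
               max_path_length: int = 2,
               max_intermediates: int | None = None) -> ExpandedNetwork:
    """Connect regulators to their targets through PPI intermediates.

    With max_path_length = 1 only direct regulator–target edges are kept;
    with 2 (default), intermediate proteins adjacent to at least one
    regulator and one target are added, capped at ``max_intermediates``
    (highest PPI degree first). Regulators absent from the PPI remain as
    isolated nodes. Per-regulator direct (edges to targets) and indirect
    (via an intermediate) interaction counts are reported.
    """
    regs = {r.upper() for r in top_regulators}
    targets = {t.upper() for t in targets}
    base = regs | targets

    intermediates: set[str] = set()
    if max_path_length >= 2:
        for v in ppi.nodes:
            if v in base:
                continue
            nbrs = set(ppi.neighbors(v))
            if nbrs & regs and nbrs & targets:
                intermediates.add(v)
        if max_intermediates is not None and len(intermediates) > max_intermediates:
            ranked = sorted(intermediates, key=lambda v: (-ppi.degree(v), v))
            intermediates = set(ranked[:max_intermediates])

    keep = base | intermediates
    g = nx.Graph(ppi.subgraph(keep & set(ppi.nodes)))
    g.add_nodes_from(base)  # isolated regulators/targets retained
    if max_path_length == 1:
        g.remove_edges_from([e for e in list(g.edges)
                             if not (e[0] in regs and e[1] in targets
                                     or e[1] in regs and e[0] in targets)])

    direct = {r: sum(1 for nb in g.neighbors(r) if nb in targets) if r in g else 0
              for r in regs}
    indirect = {}
    for r in regs:
        n_ind = 0
        if r in g:
            for v in intermediates:
                if g.has_edge(r, v) and any(nb in targets for nb in g.neighbors(v)):
                    n_ind += 1
        indirect[r] = n_ind
    return ExpandedNetwork(g, frozenset(regs), frozenset(targets),
                           frozenset(intermediates), direct, indirect)


def kinase_enrichment(expanded_nodes: set[str], kinase_library: GeneSetLibrary,
                      universe: set[str], n_background: int = DEFAULT_N_BACKGROUND,
                      seed: int = 0, top_k: int | None = DEFAULT_TOP_K) -> list[RegulatorRow]:
    """Kinase→substrate enrichment over the expanded subnetwork's nodes."""
    return regulator_enrichment(expanded_nodes, kinase_library, universe,
                                n_background=n_background, seed=seed, top_k=top_k)
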
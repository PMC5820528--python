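"""Zero-order PPI subnetwork construction, topology and module detection.

The zero-order network is the PPI subgraph induced on the DEG seed genes
only (no intermediate proteins), which avoids the hairball effect of
first-order expansions. On it we compute degree and unnormalized
betweenness centrality, call hubs (degree ≥ 10 by default), detect
disjoint connected modules with random-walk community detection, score
module cohesion with a one-sided rank-sum test, and enrich module members.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
from scipy.stats import mannwhitneyu

from .enrichment import EnrichmentRow, filter_terms, ora
from .io_formats import GeneSetLibrary

DEFAULT_HUB_DEGREE = 10


@dataclass
class NodeMetrics:
    gene: str
    degree: int
    betweenness: float
    origin: str = ""
    module_id: int | None = None


@dataclass
class Module:
    module_id: int
    members: frozenset[str]
    p: float = 1.0

    @property
    def n_seed(self) -> int:
        # in a zero-order network every node is a seed protein
        return len(self.members)


def build_zero_order(seeds: set[str], ppi: nx.Graph) -> nx.Graph:
    """Induce the PPI subgraph on the seed genes.

    Seeds absent from the PPI are dropped; seeds present but unconnected
    remain as degree-0 nodes. Components are enumerated largest-first via
    :func:`components`.
    """
    seeds = {g.upper() for g in seeds}
    return nx.Graph(ppi.subgraph(seeds & set(ppi.nodes)))


def components(g: nx.Graph) -> list[set[str]]:
    """Connected components, largest first (ties broken by smallest member)."""
    return sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))


def node_metrics(g: nx.Graph, origins: dict[str, str] | None = None,
                 modules: list[Module] | None = None) -> list[NodeMetrics]:
    """Degree and raw betweenness per node.

    Betweenness follows the unnormalized undirected convention: each
    unordered pair (s, t) contributes σ_st(v)/σ_st to every intermediate v,
    endpoints excluded — the scale on which published hub/bottleneck tables
    report values in the thousands.
    """
    if g.number_of_nodes() == 0:
        return []
    btw = nx.betweenness_centrality(g, normalized=False)
    module_of: dict[str, int] = {}
    for m in modules or []:
        for gene in m.members:
            module_of[gene] = m.module_id
    origins = origins or {}
    return [NodeMetrics(n, g.degree(n), float(btw[n]),
                        origins.get(n, ""), module_of.get(n))
            for n in sorted(g.nodes)]


def call_hubs(metrics: list[NodeMetrics], degree_min: int = DEFAULT_HUB_DEGREE) -> set[str]:
    """Genes with degree ≥ degree_min (boundary inclusive)."""
    return {m.gene for m in metrics if m.degree >= degree_min}


def rank_bottlenecks(metrics: list[NodeMetrics]) -> list[NodeMetrics]:
    """Nodes ordered by descending betweenness (bottleneck inspection)."""
    return sorted(metrics, key=lambda m: (-m.betweenness, m.gene))


def detect_modules(g: nx.Graph, seed: int = 0, walk_length: int = 4,
                   min_size: int = 2) -> list[Module]:
    """Random-walk (walktrap-style) community detection.

    Deterministic for a given graph; ``seed`` is accepted for interface
    stability (the agglomeration itself is deterministic). Clusters are
    split into connected components so every module induces a connected
    subgraph; modules are disjoint and sorted by size descending (in a
    zero-order network, size = number of encompassed seed proteins).
    """
    nodes = sorted(g.nodes)
    if not nodes:
        return []
    h = ig.Graph()
    h.add_vertices(nodes)
    h.add_edges([tuple(sorted(e)) for e in g.edges])
    clustering = h.community_walktrap(steps=walk_length).as_clustering()
    raw: list[set[str]] = []
    for cluster in clustering:
        members = {nodes[i] for i in cluster}
        for comp in nx.connected_components(g.subgraph(members)):
            raw.append(set(comp))
    raw = [m for m in raw if len(m) >= min_size]
    raw.sort(key=lambda m: (-len(m), min(m)))
    return [Module(i, frozenset(m)) for i, m in enumerate(raw)]


def module_significance(g: nx.Graph, module: Module) -> float:
    """One-sided rank-sum test for module cohesion.

    Per member node, the intra-module neighbor count is compared against
    its inter-module neighbor count (Wilcoxon rank-sum, alternative:
    intra > inter). Exact for small tie-free samples, normal approximation
    with tie correction otherwise. Degenerate modules (<2 members) get p = 1.
    """
    members = module.members
    if len(members) < 2:
        return 1.0
    intra = [sum(1 for nb in g.neighbors(v) if nb in members) for v in members]
    inter = [sum(1 for nb in g.neighbors(v) if nb not in members) for v in members]
    if intra == inter:
        pass  # identical samples: test is well defined, p ≈ 0.5
    try:
        return float(mannwhitneyu(intra, inter, alternative="greater").pvalue)
    except ValueError:  # all values identical on both sides
        return 1.0


def score_modules(g: nx.Graph, modules: list[Module]) -> list[Module]:
    for m in modules:
        m.p = module_significance(g, m)
    return modules


def module_enrichment(modules: list[Module], deg_genes: set[str],
                      library: GeneSetLibrary, universe: set[str],
                      min_deg: int = 10, alpha: float = 0.05,
                      use_adjusted: bool = False) -> dict[int, list[EnrichmentRow]]:
    """ORA of each module's DEG members; modules with < min_deg DEGs skipped."""
    deg_genes = {g.upper() for g in deg_genes}
    out: dict[int, list[EnrichmentRow]] = {}
    if len(library) == 0:
        return out
    for m in modules:
        hits = m.members & deg_genes
        if len(hits) < min_deg:
            continue
        rows = ora(set(hits), library, universe)
        out[m.module_id] = filter_terms(rows, min_genes=1, alpha=alpha,
                                        use_adjusted=use_adjusted)
    return out
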
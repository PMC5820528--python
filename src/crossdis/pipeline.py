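"""End-to-end orchestration: DEGs → shared DEGs → enrichment → network →
modules → crosstalk → regulators, from files or from the synthetic generator.

The run report collects every stage's bookkeeping counts (up/down DEGs per
disease, shared DEGs, enriched and shared terms, network nodes/edges and
degree breakdown, hubs, modules, crosstalk pairs, top regulators) and, in
synthetic mode, a truth-vs-found recovery summary (sensitivity/FDR for
planted shared DEGs, pathway / crosstalk / hub / regulator recovery).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from . import crosstalk as ct
from . import deg as deg_mod
from . import enrichment as enr
from . import network as net
from . import regulators as reg
from .io_formats import GeneSetLibrary, read_edge_list, read_expression, read_gmt
from .synthetic_data import (DISEASES, SimulationConfig, generate_collection,
                             generate_pathway_library, generate_ppi,
                             generate_regulator_libraries)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Thresholds (paper-default), input paths or a synthetic config, and seed."""

    fdr_max: float = 0.05
    effect_min: float = 1.5
    min_genes: int = 5          # ORA term filter
    alpha: float = 0.05
    use_adjusted: bool = True
    hub_degree: int = 10
    module_min_deg: int = 10
    min_deg_crosstalk: int = 5
    jc_min: float = 0.01
    top_k_regulators: int = 10
    n_background: int = 100
    seed: int = 0
    out_dir: str | None = None
    synthetic: SimulationConfig | None = None
    # file-mode inputs: {disease: [(matrix, groups, probe_map), ...]}
    studies: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    pathway_gmt: str | None = None
    ppi_path: str | None = None
    tf_gmt: str | None = None
    kinase_gmt: str | None = None

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["pathway_size_range"] = list(self.synthetic.pathway_size_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("synthetic") is not None:
            syn = d["synthetic"]
            syn["pathway_size_range"] = tuple(syn["pathway_size_range"])
            d["synthetic"] = SimulationConfig(**syn)
        d["studies"] = {k: [tuple(t) for t in v] for k, v in (d.get("studies") or {}).items()}
        return cls(**d)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from the global seed."""
    import zlib
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def network_percentages(n_nodes: int, n_deg_a: int, n_deg_b: int, n_shared: int,
                        n_degree_one: int) -> dict[str, float]:
    """Bookkeeping percentages for the zero-order network.

    Nodes as a percentage of distinct DEGs (|A| + |B| − |shared|), and the
    degree-one vs degree->1 split of the network's nodes.
    """
    n_deg_union = n_deg_a + n_deg_b - n_shared
    pct = lambda num, den: round(100.0 * num / den, 2) if den else 0.0
    return {
        "pct_degs_in_network": pct(n_nodes, n_deg_union),
        "pct_degree_one": pct(n_degree_one, n_nodes),
        "pct_degree_gt_one": pct(n_nodes - n_degree_one, n_nodes),
    }


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=stage_seed(config.seed, "synthetic")
                                  if config.synthetic.seed == 0 else config.synthetic.seed)
        studies, truth = generate_collection(syn)
        pathways = generate_pathway_library(syn, truth)
        ppi = generate_ppi(syn, truth)
        tf_lib, kin_lib = generate_regulator_libraries(syn, truth, ppi)
        by_disease: dict[str, list] = {d: [] for d in DISEASES}
        for s in studies:
            by_disease[s.disease].append(s)
        return by_disease, pathways, ppi, tf_lib, kin_lib, truth
    if not config.studies:
        raise PipelineError("inputs", "no studies configured and synthetic mode off")
    by_disease = {}
    for disease, paths in config.studies.items():
        by_disease[disease] = [read_expression(m, g, p, disease=disease,
                                               study_id=f"{disease}_s{i}")
                               for i, (m, g, p) in enumerate(paths)]
    pathways = read_gmt(config.pathway_gmt) if config.pathway_gmt else GeneSetLibrary()
    ppi = read_edge_list(config.ppi_path) if config.ppi_path else nx.Graph()
    tf_lib = read_gmt(config.tf_gmt) if config.tf_gmt else None
    kin_lib = read_gmt(config.kinase_gmt) if config.kinase_gmt else None
    return by_disease, pathways, ppi, tf_lib, kin_lib, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (JSON-serializable)."""
    by_disease, pathways, ppi, tf_lib, kin_lib, truth = _load_inputs(config)
    diseases = sorted(by_disease)
    if len(diseases) != 2:
        raise PipelineError("inputs", f"need exactly 2 diseases, got {diseases}")
    d_a, d_b = diseases

    # --- per-study DE, collapse, per-disease merge -------------------------
    tables: dict[str, deg_mod.DEGTable] = {}
    universes: dict[str, set[str]] = {}
    report: dict = {"config": {"seed": config.seed}, "stages": {}}
    for d in diseases:
        gene_tables = []
        measured: set[str] = set()
        for study in by_disease[d]:
            res = deg_mod.run_study(study, fdr_max=config.fdr_max,
                                    effect_min=config.effect_min)
            gene_tables.append(res.rows)
            measured |= set(study.probe_map.dropna().unique())
            logger.info("%s: %d DEG genes, %d conflicts, %d unmapped probes",
                        study.study_id, len(res.rows), len(res.discarded), res.unmapped)
        table, conflicts = deg_mod.merge_studies(gene_tables, disease=d)
        tables[d] = table
        universes[d] = measured
        report["stages"][f"deg_{d}"] = {
            "n_up": table.n_up, "n_down": table.n_down, "n_total": len(table),
            "n_direction_conflicts": len(conflicts),
        }

    shared = deg_mod.shared_degs(tables[d_a], tables[d_b])
    shared_genes = set(shared["gene"])
    report["stages"]["shared_degs"] = {
        "n_shared": len(shared_genes),
        "n_direction_conflicts": int(shared["direction_conflict"].sum()),
    }

    # --- enrichment per disease + shared terms -----------------------------
    enriched: dict[str, list[enr.EnrichmentRow]] = {}
    for d in diseases:
        rows = enr.ora(tables[d].genes, pathways, universes[d]) if len(pathways) else []
        enriched[d] = enr.filter_terms(rows, min_genes=config.min_genes,
                                       alpha=config.alpha,
                                       use_adjusted=config.use_adjusted)
        report["stages"][f"enrichment_{d}"] = {"n_enriched": len(enriched[d])}
    shared_terms = enr.shared_terms(enriched[d_a], enriched[d_b])
    report["stages"]["shared_terms"] = {"n_shared_terms": len(shared_terms)}

    # --- zero-order network, topology, modules -----------------------------
    seeds = tables[d_a].genes | tables[d_b].genes
    zero = net.build_zero_order(seeds, ppi)
    origins = {g: ("shared" if g in shared_genes else
                   d_a if g in tables[d_a].genes else d_b)
               for g in zero.nodes}
    modules = net.score_modules(zero, net.detect_modules(
        zero, seed=stage_seed(config.seed, "modules")))
    metrics = net.node_metrics(zero, origins, modules)
    hubs = net.call_hubs(metrics, degree_min=config.hub_degree)
    n_deg1 = sum(1 for m in metrics if m.degree == 1)
    comps = net.components(zero)
    report["stages"]["network"] = {
        "n_nodes": zero.number_of_nodes(), "n_edges": zero.number_of_edges(),
        "n_components": len(comps),
        "largest_component": len(comps[0]) if comps else 0,
        "n_degree_one": n_deg1,
        "hubs": sorted(hubs),
        **network_percentages(zero.number_of_nodes(), len(tables[d_a]),
                              len(tables[d_b]), len(shared_genes), n_deg1),
    }
    mod_enrich = net.module_enrichment(modules, seeds, pathways,
                                       universe=set(zero.nodes) or {"_"},
                                       min_deg=config.module_min_deg,
                                       alpha=config.alpha) if len(pathways) else {}
    report["stages"]["modules"] = {
        "n_modules": len(modules),
        "module_table": [{"module_id": m.module_id, "size": len(m.members),
                          "p": m.p} for m in modules],
        "n_modules_enriched": len(mod_enrich),
    }

    # --- crosstalk ---------------------------------------------------------
    pairs = ct.find_crosstalk(enriched[d_a], enriched[d_b], zero,
                              library=pathways,
                              min_deg=config.min_deg_crosstalk,
                              alpha=config.alpha, jc_min=config.jc_min)
    report["stages"]["crosstalk"] = {
        "n_pairs": len(pairs),
        "pairs": [{"term_a": p.term_a, "term_b": p.term_b, "jc": round(p.jc, 4),
                   "oc": round(p.oc, 4), "score": round(p.score, 4),
                   "strong": p.strong, "class": p.overlap_class,
                   "n_shared_genes": len(p.shared_genes),
                   "n_shared_edges": len(p.shared_edges)} for p in pairs],
    }

    # --- upstream regulators ----------------------------------------------
    reg_report = {}
    top_tfs_union: set[str] = set()
    top_kin_union: set[str] = set()
    if tf_lib is not None and len(tf_lib):
        universe = universes[d_a] | universes[d_b]
        queries = {
            "up": set(shared.loc[shared["direction_a"] == "up", "gene"]),
            "down": set(shared.loc[shared["direction_a"] == "down", "gene"]),
            "all": shared_genes,
        }
        for name, query in queries.items():
            tf_rows = reg.regulator_enrichment(
                query, tf_lib, universe, n_background=config.n_background,
                seed=stage_seed(config.seed, f"tf_{name}"),
                top_k=config.top_k_regulators)
            entry = {"tfs": [{"id": r.regulator_id, "p": r.p, "z": round(r.z, 3),
                              "combined": round(r.combined, 3), "rank": r.rank}
                             for r in tf_rows]}
            top_tfs_union |= {r.regulator_id for r in tf_rows}
            if kin_lib is not None and len(kin_lib) and tf_rows:
                expanded = reg.expand_g2n({r.regulator_id for r in tf_rows[:3]},
                                          query, ppi)
                kin_rows = reg.kinase_enrichment(
                    expanded.nodes, kin_lib, universe | expanded.nodes,
                    n_background=config.n_background,
                    seed=stage_seed(config.seed, f"kinase_{name}"),
                    top_k=config.top_k_regulators)
                entry["kinases"] = [{"id": r.regulator_id, "p": r.p,
                                     "z": round(r.z, 3),
                                     "combined": round(r.combined, 3),
                                     "rank": r.rank} for r in kin_rows]
                top_kin_union |= {r.regulator_id for r in kin_rows}
            reg_report[name] = entry
    report["stages"]["regulators"] = reg_report

    # --- recovery vs planted truth (synthetic mode) ------------------------
    if truth is not None:
        report["recovery"] = _recovery_summary(
            truth, shared_genes, enriched, pairs, hubs, top_tfs_union,
            top_kin_union, d_a, d_b)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for d in diseases:
            tables[d].rows.assign(disease=d).to_csv(out / f"deg_{d}.tsv",
                                                    sep="\t", index=False)
        shared.to_csv(out / "shared_degs.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
    return report


def _recovery_summary(truth, found_shared, enriched, pairs, hubs,
                      top_tfs, top_kinases, d_a, d_b) -> dict:
    planted = truth.shared_deg_genes
    tp = len(found_shared & planted)
    sens = tp / len(planted) if planted else 1.0
    fdr = (len(found_shared) - tp) / len(found_shared) if found_shared else 0.0

    path_rec = {}
    for d in (d_a, d_b):
        planted_pw = truth.enriched_pathways_by_disease.get(d, set())
        found_pw = {r.term_id for r in enriched[d]}
        path_rec[d] = (len(found_pw & planted_pw) / len(planted_pw)
                       if planted_pw else 1.0)

    emitted = {(p.term_a, p.term_b) for p in pairs}
    planted_pairs = set(truth.crosstalk_pairs)
    top_pair_planted = bool(pairs) and (pairs[0].term_a, pairs[0].term_b) in planted_pairs

    def frac(found: set, planted_set: set) -> float:
        return len(found & planted_set) / len(planted_set) if planted_set else 1.0

    return {
        "shared_deg_sensitivity": round(sens, 4),
        "shared_deg_fdr": round(fdr, 4),
        "pathway_sensitivity": {d: round(v, 4) for d, v in path_rec.items()},
        "crosstalk_all_planted_emitted": planted_pairs <= emitted,
        "crosstalk_top_pair_planted": top_pair_planted,
        "hub_recovery": round(frac(hubs, truth.hub_genes), 4),
        "tf_recovery": round(frac(top_tfs, truth.active_tfs), 4),
        "kinase_recovery": round(frac(top_kinases, truth.active_kinases), 4),
    }


def run_demo(seed: int = 7, out_dir: str | None = None,
             synthetic: SimulationConfig | None = None) -> dict:
    """Single-command synthetic demonstration at the default study design."""
    syn = synthetic or SimulationConfig(seed=seed)
    return run_pipeline(PipelineConfig(seed=seed, out_dir=out_dir, synthetic=syn))
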
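"""Synthetic multi-study, two-disease expression collections with planted truth.

The generator emulates the statistical structure the analysis assumes:
several already-normalized log2 expression studies per disease on
"platforms" with many-to-one probe→gene maps, a planted set of
differentially expressed genes per disease with a planted overlap between
the diseases, occasional direction-conflict genes (opposite signs across
studies, which the merge must discard), pathway libraries seeded so that
chosen pathway pairs crosstalk, a hub-rich preferential-attachment PPI,
and TF/kinase libraries with planted active regulators.

Every output is a pure function of the configuration (including its seed):
``generate_study(config, d, i)`` called twice returns identical matrices,
and ``generate_collection`` merely iterates it.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import (GeneSet, GeneSetLibrary, StudyDataset, write_edge_list,
                         write_expression, write_gmt)

DISEASE_A = "disease_a"
DISEASE_B = "disease_b"
DISEASES = (DISEASE_A, DISEASE_B)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed fully determines every output."""

    n_genes: int = 2000
    n_probes_per_gene_max: int = 3
    studies_per_disease: int = 3
    samples_per_group: int = 10
    frac_deg_per_disease: float = 0.1
    frac_shared_deg: float = 0.02
    logfc_mean: float = 2.0       # log2 units
    logfc_sd: float = 0.3
    noise_sd: float = 0.5
    frac_direction_conflict: float = 0.005
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (10, 30)
    n_planted_crosstalk_pairs: int = 3
    ppi_attachment: int = 2
    n_tfs: int = 15
    n_kinases: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_deg_per_disease", "frac_shared_deg", "frac_direction_conflict"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_shared_deg > self.frac_deg_per_disease:
            raise ConfigError("frac_shared_deg cannot exceed frac_deg_per_disease")
        if self.samples_per_group <= 0:
            raise ConfigError("samples_per_group must be positive")
        if self.pathway_size_range[0] < 5:
            raise ConfigError("pathway_size_range minimum must be >= 5")
        if self.pathway_size_range[0] > self.pathway_size_range[1]:
            raise ConfigError("pathway_size_range must be (min, max) with min <= max")
        if self.ppi_attachment < 1:
            raise ConfigError("ppi_attachment must be >= 1")
        if self.noise_sd <= 0 or self.logfc_sd < 0:
            raise ConfigError("noise_sd must be positive and logfc_sd non-negative")


@dataclass
class PlantedTruth:
    """Ground truth of one generated collection, for recovery scoring."""

    deg_genes_by_disease: dict[str, set[str]]
    shared_deg_genes: set[str]
    conflict_genes: set[str]
    enriched_pathways_by_disease: dict[str, set[str]]
    crosstalk_pairs: list[tuple[str, str]]
    strong_pairs: set[tuple[str, str]]
    pair_shared_blocks: dict[tuple[str, str], list[str]]
    hub_genes: set[str]
    active_tfs: set[str]
    active_kinases: set[str]
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline: dict[str, float] = field(default_factory=dict)


def gene_names(config: SimulationConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(config.n_genes)]


def _rng(config: SimulationConfig, *key: object) -> np.random.Generator:
    # independent, reproducible stream per generator stage; crc32 keeps the
    # derivation stable across processes (unlike builtin hash)
    tag = zlib.crc32(repr(key).encode()) % (2**31)
    ss = np.random.SeedSequence([config.seed % (2**31), tag])
    return np.random.default_rng(ss)


N_HUBS = 5
N_ACTIVE_REGULATORS = 3
N_EXTRA_ENRICHED = 2  # extra planted enriched pathways per disease


def generate_truth(config: SimulationConfig) -> PlantedTruth:
    """Draw the planted truth deterministically from the config alone."""
    rng = _rng(config, "truth")
    genes = gene_names(config)
    perm = [genes[i] for i in rng.permutation(config.n_genes)]

    n_deg = round(config.frac_deg_per_disease * config.n_genes)
    n_shared = round(config.frac_shared_deg * config.n_genes)
    n_spec = n_deg - n_shared
    n_conflict = round(config.frac_direction_conflict * config.n_genes)

    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = perm[cursor:cursor + n]
        cursor += n
        return out

    shared = take(n_shared)
    spec = {d: take(n_spec) for d in DISEASES}
    conflict = take(n_conflict)

    def magnitude(n: int) -> np.ndarray:
        return np.maximum(rng.normal(config.logfc_mean, config.logfc_sd, n), 0.25)

    effects: dict[str, dict[str, float]] = {d: {} for d in DISEASES}
    shared_mag = magnitude(n_shared)
    shared_sign = rng.choice([-1.0, 1.0], n_shared)
    for g, m, s in zip(shared, shared_mag, shared_sign):
        for d in DISEASES:  # same direction in both diseases
            effects[d][g] = float(s * m)
    for d in DISEASES:
        mags = magnitude(len(spec[d]))
        signs = rng.choice([-1.0, 1.0], len(spec[d]))
        for g, m, s in zip(spec[d], mags, signs):
            effects[d][g] = float(s * m)
    # conflict genes live in the first disease; their sign flips per study
    for g, m in zip(conflict, magnitude(n_conflict)):
        effects[DISEASE_A][g] = float(m)

    deg_by_disease = {d: set(shared) | set(spec[d]) for d in DISEASES}

    # hubs are planted on the most strongly shifted shared genes so that a
    # planted hub is guaranteed to sit inside the zero-order DEG network
    hub_pool = sorted(shared, key=lambda g: -abs(effects[DISEASE_A][g])) or \
        sorted(spec[DISEASE_A] + spec[DISEASE_B],
               key=lambda g: -abs(effects[DISEASE_A].get(g, effects[DISEASE_B].get(g, 0.0))))
    hubs = set(hub_pool[:N_HUBS])

    # reserve pathway ids: one per disease per crosstalk pair, then extras
    pw = [f"PW{i:03d}" for i in range(config.n_pathways)]
    n_pairs = config.n_planted_crosstalk_pairs
    needed = 2 * n_pairs + 2 * N_EXTRA_ENRICHED
    if config.n_pathways < needed:
        raise ConfigError(f"n_pathways must be >= {needed} for the planted design")
    pairs, blocks, strong = [], {}, set()
    block_pool = list(shared)
    for i in range(n_pairs):
        a, b = pw[2 * i], pw[2 * i + 1]
        is_strong = i % 2 == 0
        size = 4 if is_strong else 2
        if len(block_pool) < size:
            break  # not enough shared DEGs left; plant fewer pairs
        block = block_pool[:size]
        block_pool = block_pool[size:]
        pairs.append((a, b))
        blocks[(a, b)] = block
        if is_strong:
            strong.add((a, b))
    extras_a = set(pw[2 * n_pairs:2 * n_pairs + N_EXTRA_ENRICHED]) if n_deg else set()
    extras_b = set(pw[2 * n_pairs + N_EXTRA_ENRICHED:needed]) if n_deg else set()
    enriched = {
        DISEASE_A: {p[0] for p in pairs} | extras_a,
        DISEASE_B: {p[1] for p in pairs} | extras_b,
    }

    tfs = [f"TF{i:02d}" for i in range(config.n_tfs)]
    kinases = [f"KIN{i:02d}" for i in range(config.n_kinases)]
    active_tfs = set(tfs[:min(N_ACTIVE_REGULATORS, config.n_tfs)]) if n_shared else set()
    active_kin = set(kinases[:min(N_ACTIVE_REGULATORS, config.n_kinases)]) if n_shared else set()

    baseline = dict(zip(genes, rng.normal(8.0, 1.5, config.n_genes)))

    return PlantedTruth(
        deg_genes_by_disease=deg_by_disease,
        shared_deg_genes=set(shared),
        conflict_genes=set(conflict),
        enriched_pathways_by_disease=enriched,
        crosstalk_pairs=pairs,
        strong_pairs=strong,
        pair_shared_blocks=blocks,
        hub_genes=hubs,
        active_tfs=active_tfs,
        active_kinases=active_kin,
        effects=effects,
        baseline=baseline,
    )


def generate_study(config: SimulationConfig, disease_label: str,
                   study_index: int) -> StudyDataset:
    """Generate one study's probe-level matrix for a disease.

    Control columns are baseline + Normal(0, noise_sd); disease columns of
    probes belonging to planted DEGs are additionally shifted by the gene's
    drawn logFC. Conflict genes flip their sign on odd study indices.
    Probe multiplicity is Uniform{1..n_probes_per_gene_max} per gene, and a
    small block of unannotated noise probes is appended.
    """
    if disease_label not in DISEASES:
        raise ConfigError(f"unknown disease label: {disease_label}")
    if not 0 <= study_index < config.studies_per_disease:
        raise ConfigError(f"study_index {study_index} out of range")
    truth = generate_truth(config)
    rng = _rng(config, "study", disease_label, study_index)
    genes = gene_names(config)

    mult = rng.integers(1, config.n_probes_per_gene_max + 1, size=config.n_genes)
    probes, probe_genes = [], []
    for g, k in zip(genes, mult):
        for j in range(k):
            probes.append(f"{g}:p{j}")
            probe_genes.append(g)
    n_unmapped = max(1, config.n_genes // 100)
    for j in range(n_unmapped):
        probes.append(f"UNMAPPED:p{j}")
        probe_genes.append(None)

    n = config.samples_per_group
    samples = [f"{disease_label[-1]}{study_index}_C{i}" for i in range(n)] + \
              [f"{disease_label[-1]}{study_index}_D{i}" for i in range(n)]
    base = np.array([truth.baseline.get(g, 6.0) if g else 6.0 for g in probe_genes])
    mat = base[:, None] + rng.normal(0.0, config.noise_sd, (len(probes), 2 * n))

    eff = truth.effects[disease_label]
    flip = -1.0 if study_index % 2 == 1 else 1.0
    shift = np.zeros(len(probes))
    for i, g in enumerate(probe_genes):
        if g in eff:
            e = eff[g]
            if g in truth.conflict_genes:
                e *= flip
            shift[i] = e
    mat[:, n:] += shift[:, None]

    expr = pd.DataFrame(mat, index=pd.Index(probes, name="probe_id"), columns=samples)
    groups = pd.Series(["control"] * n + ["disease"] * n, index=samples, name="group")
    probe_map = pd.Series(probe_genes, index=expr.index, name="gene", dtype=object)
    return StudyDataset(expr, groups, probe_map, disease=disease_label,
                        study_id=f"{disease_label}_s{study_index}")


def generate_collection(config: SimulationConfig) -> tuple[list[StudyDataset], PlantedTruth]:
    """All studies for both diseases plus the planted truth."""
    truth = generate_truth(config)
    studies = [generate_study(config, d, i)
               for d in DISEASES for i in range(config.studies_per_disease)]
    return studies, truth


def generate_pathway_library(config: SimulationConfig, truth: PlantedTruth) -> GeneSetLibrary:
    """Pathway sets with planted enrichment and crosstalk structure.

    Each pathway named in a crosstalk pair carries its pair's common block
    of shared DEGs (4 for strong pairs, 2 otherwise); every planted
    enriched pathway additionally carries disease-specific DEGs amounting
    to ~40% of its size (at least 6), topped up with non-DEG filler.
    Remaining pathways are random draws from the non-DEG pool.
    """
    rng = _rng(config, "pathways")
    genes = gene_names(config)
    all_deg = set().union(*truth.deg_genes_by_disease.values()) | truth.conflict_genes
    non_deg = [g for g in genes if g not in all_deg]
    lo, hi = config.pathway_size_range

    disease_of_pathway: dict[str, str] = {}
    for d, pws in truth.enriched_pathways_by_disease.items():
        for p in pws:
            disease_of_pathway[p] = d
    pair_block_of: dict[str, list[str]] = {}
    for (a, b), block in truth.pair_shared_blocks.items():
        pair_block_of[a] = block
        pair_block_of[b] = block

    lib = GeneSetLibrary()
    for i in range(config.n_pathways):
        pid = f"PW{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        members: list[str] = []
        if pid in disease_of_pathway:
            d = disease_of_pathway[pid]
            members += pair_block_of.get(pid, [])
            own = sorted(truth.deg_genes_by_disease[d] - truth.shared_deg_genes)
            # seed enough disease DEGs that enrichment scales with set size
            n_own = max(6, round(0.4 * size) - len(pair_block_of.get(pid, [])))
            if own:
                members += list(rng.choice(own, size=min(n_own, len(own)), replace=False))
        fill = max(size - len(members), 0)
        if fill and non_deg:
            members += list(rng.choice(non_deg, size=min(fill, len(non_deg)), replace=False))
        lib.add(pid, f"synthetic pathway {i}", dict.fromkeys(members))
    return lib


def generate_ppi(config: SimulationConfig, truth: PlantedTruth) -> nx.Graph:
    """Hub-rich preferential-attachment PPI over all genes (+ regulator nodes).

    A Barabási–Albert backbone (ppi_attachment edges per new node) gives a
    heavy-tailed degree distribution; planted hub genes get extra edges to
    planted DEGs so they stay hubs inside the zero-order DEG network; each
    planted crosstalk pair gets one edge between two genes of its common
    block; TF/kinase ids are wired in so the regulator-network expansion
    has substance.
    """
    rng = _rng(config, "ppi")
    genes = gene_names(config)
    m = min(config.ppi_attachment, config.n_genes - 1)
    backbone = nx.barabasi_albert_graph(config.n_genes, m,
                                        seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(backbone, dict(enumerate(genes)))

    all_deg = sorted(set().union(*truth.deg_genes_by_disease.values()))
    for hub in sorted(truth.hub_genes):
        others = [x for x in all_deg if x != hub and not g.has_edge(hub, x)]
        if others:
            extra = rng.choice(others, size=min(15, len(others)), replace=False)
            g.add_edges_from((hub, x) for x in extra)

    for block in truth.pair_shared_blocks.values():
        if len(block) >= 2:
            g.add_edge(block[0], block[1])

    shared = sorted(truth.shared_deg_genes)
    for t in range(config.n_tfs):
        tf = f"TF{t:02d}"
        if tf in truth.active_tfs and shared:
            targets = rng.choice(shared, size=min(8, len(shared)), replace=False)
        else:
            targets = rng.choice(genes, size=3, replace=False)
        g.add_node(tf)
        g.add_edges_from((tf, x) for x in targets)
    for k in range(config.n_kinases):
        kin = f"KIN{k:02d}"
        g.add_node(kin)
        g.add_edges_from((kin, x) for x in rng.choice(genes, size=2, replace=False))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def generate_regulator_libraries(config: SimulationConfig, truth: PlantedTruth,
                                 ppi: nx.Graph | None = None) -> tuple[GeneSetLibrary, GeneSetLibrary]:
    """TF→target and kinase→substrate libraries with planted active regulators.

    Active TFs draw half their targets from the shared DEGs; active kinases
    draw most substrates from the active TFs plus their PPI neighborhood
    (falling back to the TFs' planted targets when no PPI is supplied).
    Inactive regulators get uniformly random targets.
    """
    rng = _rng(config, "regulators")
    genes = gene_names(config)
    shared = sorted(truth.shared_deg_genes)

    tf_lib = GeneSetLibrary()
    tf_targets: dict[str, list[str]] = {}
    for t in range(config.n_tfs):
        tf = f"TF{t:02d}"
        if tf in truth.active_tfs and shared:
            n_hit = min(12, len(shared))
            targets = list(rng.choice(shared, size=n_hit, replace=False))
            targets += list(rng.choice(genes, size=12, replace=False))
        else:
            targets = list(rng.choice(genes, size=24, replace=False))
        targets = list(dict.fromkeys(targets))
        tf_targets[tf] = targets
        tf_lib.add(tf, f"synthetic TF {t}", targets)

    kin_lib = GeneSetLibrary()
    pool: set[str] = set(truth.active_tfs)
    for tf in truth.active_tfs:
        if ppi is not None and tf in ppi:
            pool |= set(ppi.neighbors(tf))
        else:
            pool |= set(tf_targets[tf][:8])
    pool_list = sorted(pool)
    for k in range(config.n_kinases):
        kin = f"KIN{k:02d}"
        if kin in truth.active_kinases and pool_list:
            n_hit = min(16, len(pool_list))
            subs = list(rng.choice(pool_list, size=n_hit, replace=False))
            subs += list(rng.choice(genes, size=4, replace=False))
        else:
            subs = list(rng.choice(genes, size=20, replace=False))
        kin_lib.add(kin, f"synthetic kinase {k}", dict.fromkeys(subs))
    return tf_lib, kin_lib


def write_collection(config: SimulationConfig, out_dir) -> None:
    """Write a full synthetic resource bundle as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    studies, truth = generate_collection(config)
    for s in studies:
        stem = out / s.study_id
        write_expression(s, f"{stem}.matrix.tsv", f"{stem}.groups.tsv",
                         f"{stem}.probes.tsv")
    write_gmt(generate_pathway_library(config, truth), out / "pathways.gmt")
    ppi = generate_ppi(config, truth)
    write_edge_list(ppi, out / "ppi.tsv")
    tf_lib, kin_lib = generate_regulator_libraries(config, truth, ppi)
    write_gmt(tf_lib, out / "tf_targets.gmt")
    write_gmt(kin_lib, out / "kinase_substrates.gmt")
    truth_json = {
        "deg_genes_by_disease": {d: sorted(v) for d, v in truth.deg_genes_by_disease.items()},
        "shared_deg_genes": sorted(truth.shared_deg_genes),
        "conflict_genes": sorted(truth.conflict_genes),
        "enriched_pathways_by_disease": {d: sorted(v) for d, v in
                                         truth.enriched_pathways_by_disease.items()},
        "crosstalk_pairs": truth.crosstalk_pairs,
        "hub_genes": sorted(truth.hub_genes),
        "active_tfs": sorted(truth.active_tfs),
        "active_kinases": sorted(truth.active_kinases),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
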
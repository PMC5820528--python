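"""Readers, writers and container types for the pipeline's file formats.

Everything downstream is keyed on a single caller-chosen gene identifier
space (symbols are upper-cased at ingest and never converted between
identifier systems). Supported formats: TSV expression matrices with a
sidecar sample→group file and a probe→gene map, GMT gene-set libraries,
two-column TSV / SIF edge lists, and a JSON study manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("control", "disease")


class FormatError(ValueError):
    """Structurally invalid input file."""


@dataclass
class StudyDataset:
    """One study: normalized log2 expression plus sample and probe metadata.

    expression : probes × samples (columns are sample ids)
    groups     : sample id → "control" | "disease"
    probe_map  : probe id → gene symbol (None for unannotated probes)
    """

    expression: pd.DataFrame
    groups: pd.Series
    probe_map: pd.Series
    disease: str = ""
    study_id: str = ""

    def __post_init__(self) -> None:
        bad = set(self.groups.unique()) - set(VALID_GROUPS)
        if bad:
            raise FormatError(f"invalid group label(s): {sorted(bad)}")
        missing = set(self.expression.columns) - set(self.groups.index)
        if missing:
            raise FormatError(f"samples without a group label: {sorted(missing)}")
        if not self.expression.index.equals(self.probe_map.index):
            raise FormatError("expression rows and probe map rows do not match")

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.expression.columns if self.groups[s] == "control"]

    @property
    def disease_samples(self) -> list[str]:
        return [s for s in self.expression.columns if self.groups[s] == "disease"]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    genes: frozenset[str]


class GeneSetLibrary:
    """Named gene sets (pathways, GO terms, TF targets, kinase substrates)."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s.term_id, s.name, s.genes)

    def add(self, term_id: str, name: str, genes: Iterable[str]) -> None:
        if term_id in self._sets:
            raise FormatError(f"duplicate term id: {term_id}")
        genes = frozenset(g.upper() for g in genes)
        if not genes:
            raise FormatError(f"empty gene set: {term_id}")
        self._sets[term_id] = GeneSet(term_id, name, genes)

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._sets

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._sets[term_id]

    def items(self) -> Iterable[tuple[str, GeneSet]]:
        return self._sets.items()

    def genes(self, term_id: str) -> frozenset[str]:
        return self._sets[term_id].genes

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self._sets.values():
            out |= s.genes
        return out


@dataclass(frozen=True)
class ManifestEntry:
    accession: str
    disease: str
    n_control: int
    n_disease: int
    stage: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise FormatError("manifest entry with empty accession")
        if self.n_control < 0 or self.n_disease < 0:
            raise FormatError(f"negative sample count in {self.accession}")


@dataclass
class Manifest:
    """Study bookkeeping: one entry per (accession, tissue/stage) comparison.

    The same accession may legitimately appear in several entries when a
    series was split into per-stage comparisons.
    """

    entries: list[ManifestEntry] = field(default_factory=list)


@dataclass
class ManifestSummary:
    per_disease_totals: dict[str, dict[str, int]]
    n_unique_accessions: int
    unique_accessions_per_disease: dict[str, int]


# ---------------------------------------------------------------------------
# expression matrices


def write_expression(dataset: StudyDataset, matrix_path, groups_path, probe_map_path) -> None:
    dataset.expression.to_csv(matrix_path, sep="\t", index_label="probe_id")
    dataset.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")
    pm = dataset.probe_map.fillna("").rename("gene")
    pm.to_csv(probe_map_path, sep="\t", index_label="probe_id")


def read_expression(matrix_path, groups_path, probe_map_path,
                    disease: str = "", study_id: str = "") -> StudyDataset:
    """Load one study from its three TSV files.

    Rejects duplicate probe ids, missing values, unlabeled samples and any
    group label other than control/disease.
    """
    expr = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate probe id(s) in matrix: {dups[:5]}")
    if expr.isna().any().any():
        raise FormatError("missing values in expression matrix")
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"].astype(str)
    pm = pd.read_csv(probe_map_path, sep="\t", index_col=0, keep_default_na=False)["gene"]
    pm = pm.map(lambda g: str(g).upper() if str(g) else None)
    if set(expr.index) != set(pm.index):
        raise FormatError("probe map does not cover the matrix probes exactly")
    pm = pm.reindex(expr.index)
    return StudyDataset(expr, groups, pm, disease=disease, study_id=study_id)


# ---------------------------------------------------------------------------
# GMT gene-set libraries


def read_gmt(path) -> GeneSetLibrary:
    """Parse a standard GMT file (term, description, genes...).

    Duplicate genes within a set are deduplicated; a duplicate term id or a
    line with fewer than three fields is an error.
    """
    lib = GeneSetLibrary()
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        logger.warning("empty GMT file: %s", path)
        return lib
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{i}: GMT line has {len(fields)} field(s), need >=3")
        term_id, name, *genes = fields
        lib.add(term_id, name, [g for g in genes if g])
    return lib


def write_gmt(lib: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for term_id, s in lib.items():
            fh.write("\t".join([term_id, s.name, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path, dialect: str = "tsv") -> nx.Graph:
    """Read an undirected, unweighted interaction network.

    dialect "tsv": two tab-separated node columns per row.
    dialect "sif": ``node relation node [node ...]`` (one edge per trailing
    node). Self-loops are dropped with a warning; duplicate edges in either
    orientation collapse.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list dialect: {dialect}")
    g = nx.Graph()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if dialect == "tsv":
                if len(fields) < 2:
                    raise FormatError(f"{path}:{i}: edge row has a single column")
                pairs = [(fields[0], fields[1])]
            else:
                if len(fields) < 3:
                    raise FormatError(f"{path}:{i}: SIF row needs source, relation, target(s)")
                src = fields[0]
                pairs = [(src, tgt) for tgt in fields[2:]]
            for a, b in pairs:
                a, b = a.upper(), b.upper()
                if a == b:
                    logger.warning("%s:%d: dropping self-loop %s", path, i, a)
                    continue
                g.add_edge(a, b)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path) -> Manifest:
    with open(path) as fh:
        raw = json.load(fh)
    entries = [ManifestEntry(**e) for e in raw["entries"]]
    return Manifest(entries)


def write_manifest(manifest: Manifest, path) -> None:
    with open(path, "w") as fh:
        json.dump({"entries": [vars(e) for e in manifest.entries]}, fh, indent=1)


def validate_manifest(manifest: Manifest) -> ManifestSummary:
    """Per-disease sample totals and unique accession counts.

    Totals are plain sums over entries; an accession counted once per
    disease even when split across several stage-specific entries.
    """
    totals: dict[str, dict[str, int]] = {}
    acc_by_disease: dict[str, set[str]] = {}
    for e in manifest.entries:
        t = totals.setdefault(e.disease, {"samples": 0, "control": 0, "disease": 0})
        t["samples"] += e.n_control + e.n_disease
        t["control"] += e.n_control
        t["disease"] += e.n_disease
        acc_by_disease.setdefault(e.disease, set()).add(e.accession)
    all_acc = set().union(*acc_by_disease.values()) if acc_by_disease else set()
    return ManifestSummary(
        per_disease_totals=totals,
        n_unique_accessions=len(all_acc),
        unique_accessions_per_disease={d: len(a) for d, a in acc_by_disease.items()},
    )
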
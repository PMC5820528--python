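import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crossdis.synthetic_data import (DISEASE_A, DISEASE_B, ConfigError,
                                     PlantedTruth, SimulationConfig,
                                     generate_collection,
                                     generate_pathway_library, generate_ppi,
                                     generate_regulator_libraries,
                                     generate_study, generate_truth,
                                     gene_names)

SMALL = SimulationConfig(n_genes=300, studies_per_disease=2, samples_per_group=6,
                         seed=11)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"samples_per_group": 0},
        {"frac_deg_per_disease": 1.2},
        {"frac_shared_deg": 0.2, "frac_deg_per_disease": 0.1},
        {"pathway_size_range": (3, 10)},
        {"ppi_attachment": 0},
        {"noise_sd": 0.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


class TestGenerateStudy:
    def test_shape_and_probe_multiplicity(self):
        ds = generate_study(SMALL, DISEASE_A, 0)
        assert ds.expression.shape[1] == 2 * SMALL.samples_per_group
        counts = ds.probe_map.dropna().value_counts()
        assert counts.min() >= 1 and counts.max() <= SMALL.n_probes_per_gene_max
        assert ds.probe_map.isna().sum() >= 1  # unannotated probes exist

    def test_same_seed_byte_identical(self):
        d1 = generate_study(SMALL, DISEASE_B, 1)
        d2 = generate_study(SMALL, DISEASE_B, 1)
        pd.testing.assert_frame_equal(d1.expression, d2.expression)

    def test_null_config_plants_nothing(self):
        cfg = dataclasses.replace(SMALL, frac_deg_per_disease=0.0,
                                  frac_shared_deg=0.0,
                                  frac_direction_conflict=0.0, noise_sd=1.0)
        truth = generate_truth(cfg)
        assert not truth.shared_deg_genes and not truth.conflict_genes
        assert not any(truth.deg_genes_by_disease.values())
        ds = generate_study(cfg, DISEASE_A, 0)
        ctrl = ds.expression[ds.control_samples].mean(axis=1)
        dis = ds.expression[ds.disease_samples].mean(axis=1)
        # no probe shifted systematically: differences are pure noise
        assert abs((dis - ctrl).mean()) < 0.1

    def test_planted_probe_power(self):
        # an effect of 2 log2 units at sd 0.5 and n=10/group is essentially
        # always detected by a plain t-test
        detected = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = SimulationConfig(n_genes=200, frac_deg_per_disease=0.1,
                                   frac_shared_deg=0.02, logfc_mean=2.0,
                                   noise_sd=0.5, samples_per_group=10, seed=seed)
            truth = generate_truth(cfg)
            ds = generate_study(cfg, DISEASE_A, 0)
            gene = sorted(truth.deg_genes_by_disease[DISEASE_A])[0]
            probe = ds.probe_map[ds.probe_map == gene].index[0]
            x = ds.expression.loc[probe, ds.control_samples]
            y = ds.expression.loc[probe, ds.disease_samples]
            detected += sps.ttest_ind(y, x).pvalue < 0.01
        assert detected >= 0.9 * n_seeds

    def test_bad_arguments(self):
        with pytest.raises(ConfigError):
            generate_study(SMALL, "nope", 0)
        with pytest.raises(ConfigError):
            generate_study(SMALL, DISEASE_A, SMALL.studies_per_disease)


class TestGenerateCollection:
    def test_counts_and_structure(self):
        studies, truth = generate_collection(SMALL)
        assert len(studies) == 2 * SMALL.studies_per_disease
        n_shared = round(SMALL.frac_shared_deg * SMALL.n_genes)
        assert len(truth.shared_deg_genes) == n_shared

    def test_truth_invariants(self):
        _, truth = generate_collection(SMALL)
        for d in (DISEASE_A, DISEASE_B):
            assert truth.shared_deg_genes <= truth.deg_genes_by_disease[d]
        assert not (truth.conflict_genes & truth.shared_deg_genes)
        for (a, b), block in truth.pair_shared_blocks.items():
            assert len(block) >= 1
            assert set(block) <= truth.shared_deg_genes

    def test_shared_genes_same_direction_both_diseases(self):
        _, truth = generate_collection(SMALL)
        for g in truth.shared_deg_genes:
            assert np.sign(truth.effects[DISEASE_A][g]) == \
                np.sign(truth.effects[DISEASE_B][g])

    def test_conflict_genes_flip_across_studies(self):
        cfg = dataclasses.replace(SMALL, frac_direction_conflict=0.02)
        _, truth = generate_collection(cfg)
        assert truth.conflict_genes
        g = sorted(truth.conflict_genes)[0]
        shifts = []
        for i in range(cfg.studies_per_disease):
            ds = generate_study(cfg, DISEASE_A, i)
            probe = ds.probe_map[ds.probe_map == g].index[0]
            diff = (ds.expression.loc[probe, ds.disease_samples].mean()
                    - ds.expression.loc[probe, ds.control_samples].mean())
            shifts.append(diff)
        assert np.sign(shifts[0]) != np.sign(shifts[1])

    @pytest.mark.parametrize("field,empty_attr", [
        ("frac_shared_deg", "shared_deg_genes"),
        ("frac_direction_conflict", "conflict_genes"),
    ])
    def test_zero_fractions_give_empty_truth_sets(self, field, empty_attr):
        cfg = dataclasses.replace(SMALL, **{field: 0.0})
        _, truth = generate_collection(cfg)
        assert getattr(truth, empty_attr) == set()


class TestPathwayLibrary:
    def test_sizes_within_range_and_count(self):
        _, truth = generate_collection(SMALL)
        lib = generate_pathway_library(SMALL, truth)
        lo, hi = SMALL.pathway_size_range
        assert len(lib) == SMALL.n_pathways
        for term in lib:
            assert len(lib.genes(term)) <= hi

    def test_planted_pathway_exceeds_expectation(self):
        _, truth = generate_collection(SMALL)
        lib = generate_pathway_library(SMALL, truth)
        degs = truth.deg_genes_by_disease[DISEASE_A]
        for pid in truth.enriched_pathways_by_disease[DISEASE_A]:
            genes = lib.genes(pid)
            expected = len(genes) * len(degs) / SMALL.n_genes
            assert len(genes & degs) > expected

    def test_strong_pairs_share_at_least_four(self):
        _, truth = generate_collection(SMALL)
        lib = generate_pathway_library(SMALL, truth)
        for pair in truth.crosstalk_pairs:
            common = lib.genes(pair[0]) & lib.genes(pair[1]) & truth.shared_deg_genes
            assert len(common) >= (4 if pair in truth.strong_pairs else 1)

    def test_null_pathway_pvalues_uniform(self, rng):
        # no planted signal: ORA p-values against a random query are uniform
        from crossdis.enrichment import ora
        cfg = SimulationConfig(n_genes=1000, frac_deg_per_disease=0.0,
                               frac_shared_deg=0.0, frac_direction_conflict=0.0,
                               n_pathways=200, seed=5)
        truth = generate_truth(cfg)
        lib = generate_pathway_library(cfg, truth)
        universe = set(gene_names(cfg))
        query = set(rng.choice(sorted(universe), size=100, replace=False))
        rows = ora(query, lib, universe)
        frac_sig = np.mean([r.p < 0.05 for r in rows])
        assert abs(frac_sig - 0.05) <= 0.03 + 0.02  # binomial noise on 200 terms


class TestPPI:
    def test_tree_backbone_when_attachment_one(self):
        import networkx as nx
        cfg = dataclasses.replace(SMALL, ppi_attachment=1)
        truth = generate_truth(cfg)
        g = generate_ppi(cfg, truth)
        assert nx.is_connected(g.subgraph(gene_names(cfg)))
        assert g.number_of_edges() >= cfg.n_genes - 1

    def test_heavy_tailed_degrees(self):
        for seed in range(10):
            cfg = SimulationConfig(n_genes=2000, seed=seed)
            truth = generate_truth(cfg)
            g = generate_ppi(cfg, truth)
            degrees = np.array([g.degree(n) for n in gene_names(cfg)])
            assert degrees.max() > 5 * np.median(degrees)

    def test_planted_hub_degree(self):
        for seed in range(5):
            cfg = dataclasses.replace(SMALL, seed=seed)
            truth = generate_truth(cfg)
            g = generate_ppi(cfg, truth)
            for h in truth.hub_genes:
                assert g.degree(h) >= 10

    def test_simple_graph_no_self_loops(self):
        import networkx as nx
        truth = generate_truth(SMALL)
        g = generate_ppi(SMALL, truth)
        assert not list(nx.selfloop_edges(g))

    def test_crosstalk_pairs_share_planted_edge(self):
        truth = generate_truth(SMALL)
        g = generate_ppi(SMALL, truth)
        for block in truth.pair_shared_blocks.values():
            assert g.has_edge(block[0], block[1])


class TestRegulatorLibraries:
    def test_determinism(self):
        truth = generate_truth(SMALL)
        t1, k1 = generate_regulator_libraries(SMALL, truth)
        t2, k2 = generate_regulator_libraries(SMALL, truth)
        assert {t: t1.genes(t) for t in t1} == {t: t2.genes(t) for t in t2}
        assert {t: k1.genes(t) for t in k1} == {t: k2.genes(t) for t in k2}

    def test_active_tfs_enriched_for_shared_degs(self):
        truth = generate_truth(SMALL)
        tf_lib, _ = generate_regulator_libraries(SMALL, truth)
        shared = truth.shared_deg_genes
        n = SMALL.n_genes
        for tf in tf_lib:
            frac = len(tf_lib.genes(tf) & shared) / len(tf_lib.genes(tf))
            if tf in truth.active_tfs:
                assert frac > 5 * len(shared) / n
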
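import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crossdis.deg import (DEGTable, ProbeStat, bh_adjust, collapse_probes,
                          filter_probes, merge_studies, moderated_t,
                          shared_degs, validate_against_known)
from crossdis.synthetic_data import SimulationConfig, generate_study
from conftest import make_dataset


def bh_oracle(p):
    """Hand step-up: p(i)*n/i from the largest rank down, cumulative min."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):
        running = min(running, p[order[i]] * n / (i + 1))
        adj[order[i]] = running
    return adj


class TestModeratedT:
    def test_flat_probe_is_null(self):
        ds = make_dataset(np.ones((3, 8)))
        for s in moderated_t(ds):
            assert s.logfc == 0 and s.t_stat == 0 and s.p == 1

    def test_reduces_to_pooled_t_at_zero_prior_df(self, rng):
        ds = make_dataset(rng.normal(size=(20, 12)))
        ours = moderated_t(ds, prior_df=0)
        ctrl = ds.expression[ds.control_samples].to_numpy()
        dis = ds.expression[ds.disease_samples].to_numpy()
        ref = sps.ttest_ind(dis, ctrl, axis=1, equal_var=True)
        assert np.allclose([s.t_stat for s in ours], ref.statistic, atol=1e-9)
        assert np.allclose([s.p for s in ours], ref.pvalue, atol=1e-12)

    def test_null_pvalues_uniform(self):
        # no planted shift: KS distance to U(0,1) stays small across seeds
        for seed in range(5):
            cfg = SimulationConfig(n_genes=500, frac_deg_per_disease=0,
                                   frac_shared_deg=0, frac_direction_conflict=0,
                                   noise_sd=1.0, seed=seed)
            stats = moderated_t(generate_study(cfg, "disease_a", 0))
            ks = sps.kstest([s.p for s in stats], "uniform").statistic
            assert ks < 0.08

    def test_moderation_shrinks_toward_common_variance(self, rng):
        # probes with wildly different sample variances: moderated |t| of the
        # noisiest probe exceeds its pooled |t| (variance shrunk down), and
        # degrees of freedom gained make the test better calibrated
        base = rng.normal(size=(50, 10))
        base[0] *= 20.0
        ds = make_dataset(base + np.pad(np.ones((1, 10)), ((0, 49), (0, 0))))
        mod = moderated_t(ds)
        plain = moderated_t(ds, prior_df=0)
        assert abs(mod[0].t_stat) > abs(plain[0].t_stat)

    def test_requires_two_per_group(self, rng):
        ds = make_dataset(rng.normal(size=(3, 3)), n_control=1)
        with pytest.raises(ValueError):
            moderated_t(ds)


class TestBHAdjust:
    def test_hand_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("pvals", [[0.5], [1.0, 1.0, 1.0]])
    def test_degenerate_inputs(self, pvals):
        assert np.allclose(bh_adjust(pvals), pvals)

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 60))
            assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_order_preserving_under_permutation(self, rng):
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestFilterAndCollapse:
    def _stat(self, probe, gene, logfc, adj_p):
        return ProbeStat(probe, gene, logfc, 0.0, adj_p, adj_p)

    @pytest.mark.parametrize("logfc,adj_p,kept", [
        (1.51, 0.04, True),     # boundary pass on both axes
        (-1.51, 6.18e-4, True),
        (1.49, 0.001, False),   # effect too small
        (3.0, 0.051, False),    # FDR too large
        (1.5, 0.05, True),      # thresholds are inclusive
    ])
    def test_thresholds(self, logfc, adj_p, kept):
        out = filter_probes([self._stat("p1", "G1", logfc, adj_p)])
        assert (len(out) == 1) is kept

    def test_agreeing_probes_average(self):
        res = collapse_probes([self._stat("p1", "G", 2.0, 0.01),
                               self._stat("p2", "G", 3.0, 0.02)])
        row = res.rows.iloc[0]
        assert row["logfc"] == 2.5 and row["adj_p"] == 0.01

    def test_conflicting_probes_discarded_and_logged(self):
        res = collapse_probes([self._stat("p1", "H", 2.0, 0.01),
                               self._stat("p2", "H", -1.0, 0.02)])
        assert len(res.rows) == 0 and res.discarded == ["H"]

    def test_single_probe_gene_passes_through(self):
        res = collapse_probes([self._stat("p1", "G", -2.2, 0.03)])
        assert res.rows.iloc[0]["logfc"] == -2.2

    def test_unannotated_probes_dropped(self):
        res = collapse_probes([self._stat("p1", None, 5.0, 0.001)])
        assert len(res.rows) == 0 and res.unmapped == 1


class TestMergeStudies:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "logfc", "adj_p"])

    def test_consistent_gene_averaged(self):
        t, discarded = merge_studies([self._table([("G", 2.0, 0.01)]),
                                      self._table([("G", 4.0, 0.02)])])
        assert t.rows.iloc[0]["logfc"] == 3.0 and not discarded

    def test_conflicting_gene_discarded(self):
        t, discarded = merge_studies([self._table([("G", 2.0, 0.01)]),
                                      self._table([("G", -2.0, 0.02)])])
        assert len(t) == 0 and discarded == ["G"]

    def test_disjoint_studies_union(self):
        t, _ = merge_studies([self._table([("A", 1.0, 0.01), ("B", -2.0, 0.01)]),
                              self._table([("C", 3.0, 0.01)])])
        assert t.genes == {"A", "B", "C"}
        assert t.n_up + t.n_down == len(t)

    def test_no_conflicting_signs_survive_random_tables(self, rng):
        # property: after the merge no gene retains contributions of mixed sign
        genes = [f"G{i}" for i in range(30)]
        tables = []
        for _ in range(4):
            pick = rng.choice(genes, size=15, replace=False)
            tables.append(self._table(
                [(g, float(rng.normal()), float(rng.uniform())) for g in pick]))
        merged, discarded = merge_studies(tables)
        all_rows = pd.concat(tables)
        for gene in merged.genes:
            signs = set(np.sign(all_rows.loc[all_rows["gene"] == gene, "logfc"]))
            assert len(signs) == 1
        for gene in discarded:
            signs = set(np.sign(all_rows.loc[all_rows["gene"] == gene, "logfc"]))
            assert len(signs) > 1


class TestSharedDegs:
    def _degtable(self, rows, disease=""):
        df = pd.DataFrame(rows, columns=["gene", "logfc", "adj_p"])
        df["direction"] = np.where(df["logfc"] > 0, "up", "down")
        return DEGTable(df, disease)

    def test_disjoint_tables_empty(self):
        a = self._degtable([("A", 1.0, 0.01)])
        b = self._degtable([("B", 1.0, 0.01)])
        assert len(shared_degs(a, b)) == 0

    def test_identical_tables_full_overlap(self):
        a = self._degtable([("A", 1.0, 0.01), ("B", -1.6, 0.02)])
        s = shared_degs(a, a)
        assert len(s) == 2 and not s["direction_conflict"].any()

    def test_cross_disease_direction_conflict_flagged(self):
        a = self._degtable([("A", 1.0, 0.01)])
        b = self._degtable([("A", -1.0, 0.01)])
        assert shared_degs(a, b)["direction_conflict"].all()


class TestValidateAgainstKnown:
    def test_exact_boundaries(self):
        t = DEGTable(pd.DataFrame({"gene": ["A", "B"], "logfc": [1.0, 2.0],
                                   "adj_p": [0.01, 0.01],
                                   "direction": ["up", "up"]}))
        assert validate_against_known(t, {"X"}) == 0
        assert validate_against_known(t, {"A", "B"}) == 2

    def test_random_overlap_matches_hypergeometric_expectation(self, rng):
        # 200-gene table vs random 50-gene known sets in a 1000-gene universe
        universe = [f"G{i}" for i in range(1000)]
        table = DEGTable(pd.DataFrame({
            "gene": universe[:200], "logfc": 2.0, "adj_p": 0.01,
            "direction": "up"}))
        overlaps = [validate_against_known(table, set(rng.choice(universe, 50,
                                                                 replace=False)))
                    for _ in range(50)]
        assert abs(np.mean(overlaps) - 10) <= 5
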
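"""Per-study differential expression and direction-aware cross-study merging.

The workflow mirrors the classic two-group microarray meta-analysis: an
empirical-Bayes moderated t-test per probe, Benjamini–Hochberg FDR control,
effect-size + FDR thresholding, probe→gene collapsing (average when probe
directions agree, discard when they conflict), a union merge across studies
of the same disease that discards direction-inconsistent genes, and finally
the gene-symbol intersection of the two diseases' merged tables.

All effect sizes are log2 fold changes; the default DEG thresholds are
adjusted p ≤ 0.05 and |logFC| ≥ 1.5 on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import StudyDataset

DEFAULT_FDR_MAX = 0.05
DEFAULT_EFFECT_MIN = 1.5


@dataclass
class ProbeStat:
    probe_id: str
    gene: str | None
    logfc: float
    t_stat: float
    p: float
    adj_p: float = np.nan


@dataclass
class DEGTable:
    """Gene-level differential expression calls for one disease.

    rows: columns gene, logfc, adj_p, direction (up ⟺ logfc > 0).
    """

    rows: pd.DataFrame
    disease: str = ""

    @property
    def genes(self) -> set[str]:
        return set(self.rows["gene"])

    @property
    def n_up(self) -> int:
        return int((self.rows["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.rows["direction"] == "down").sum())

    def __len__(self) -> int:
        return len(self.rows)


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on the monotone trigamma function.
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square variance prior (d0, s0²).

    Works on log sample variances: for s² ~ s0²·χ²_d/d scaled by the prior,
    E[log s²] and Var[log s²] involve digamma/trigamma terms, which are
    matched to the observed moments. Returns (inf, geometric mean) when the
    observed spread is no larger than the sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    evar = e.var(ddof=1) * s2.size / max(s2.size - 1, 1)
    excess = evar - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(dataset: StudyDataset, prior_df: float | None = None) -> list[ProbeStat]:
    """Empirical-Bayes moderated two-group t-test per probe.

    logfc = mean(disease) − mean(control). The pooled per-probe variance is
    shrunk toward a prior estimated from all probes:
    s²_post = (d0·s0² + d·s²)/(d0 + d), with two-sided p from t on d0 + d
    degrees of freedom. ``prior_df`` overrides the estimated d0 (0 recovers
    the ordinary pooled t-test exactly). Degenerate probes with zero
    variance and zero difference get t = 0, p = 1.
    """
    ctrl = dataset.expression[dataset.control_samples].to_numpy(float)
    dis = dataset.expression[dataset.disease_samples].to_numpy(float)
    n1, n2 = ctrl.shape[1], dis.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    df = n1 + n2 - 2
    logfc = dis.mean(axis=1) - ctrl.mean(axis=1)
    ss = ctrl.var(axis=1, ddof=1) * (n1 - 1) + dis.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df

    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(s2, df)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_variance_prior(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = 1e9
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), np.where(logfc == 0, 0.0, np.inf * np.sign(logfc)))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(se > 0, p, np.where(logfc == 0, 1.0, 0.0))
    t = np.where((se == 0) & (logfc == 0), 0.0, t)

    pm = dataset.probe_map
    return [
        ProbeStat(str(probe), pm.loc[probe] if pd.notna(pm.loc[probe]) else None,
                  float(logfc[i]), float(t[i]), float(min(p[i], 1.0)))
        for i, probe in enumerate(dataset.expression.index)
    ]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def adjust_stats(stats_list: list[ProbeStat]) -> list[ProbeStat]:
    """Fill in adj_p across a study's probes (BH over all tested probes)."""
    adj = bh_adjust([s.p for s in stats_list])
    for s, a in zip(stats_list, adj):
        s.adj_p = float(a)
    return stats_list


def filter_probes(stats_list: list[ProbeStat], fdr_max: float = DEFAULT_FDR_MAX,
                  effect_min: float = DEFAULT_EFFECT_MIN) -> list[ProbeStat]:
    """Keep probes with adj_p ≤ fdr_max and |logfc| ≥ effect_min."""
    return [s for s in stats_list
            if s.adj_p <= fdr_max and abs(s.logfc) >= effect_min]


@dataclass
class CollapseResult:
    rows: pd.DataFrame  # gene, logfc, adj_p
    discarded: list[str] = field(default_factory=list)  # direction conflicts
    unmapped: int = 0


def collapse_probes(stats_list: list[ProbeStat]) -> CollapseResult:
    """Collapse passing probes to one row per gene.

    Probes without a gene annotation are dropped. If all of a gene's probes
    share a sign the gene keeps the mean logfc and the minimum adj_p;
    otherwise the gene is discarded and logged.
    """
    by_gene: dict[str, list[ProbeStat]] = {}
    unmapped = 0
    for s in stats_list:
        if s.gene is None:
            unmapped += 1
            continue
        by_gene.setdefault(s.gene, []).append(s)

    recs, discarded = [], []
    for gene, probes in by_gene.items():
        signs = {np.sign(p.logfc) for p in probes}
        if len(signs) > 1:
            discarded.append(gene)
            continue
        recs.append((gene,
                     float(np.mean([p.logfc for p in probes])),
                     float(min(p.adj_p for p in probes))))
    rows = pd.DataFrame(recs, columns=["gene", "logfc", "adj_p"])
    return CollapseResult(rows, sorted(discarded), unmapped)


def merge_studies(tables: list[pd.DataFrame], disease: str = "") -> tuple[DEGTable, list[str]]:
    """Union-merge gene-level rows across a disease's studies.

    Genes present in several studies keep the mean logfc and minimum adj_p
    when all study signs agree; sign conflicts are discarded and returned.
    """
    if tables:
        combined = pd.concat(tables, ignore_index=True)
    else:
        combined = pd.DataFrame(columns=["gene", "logfc", "adj_p"])
    recs, discarded = [], []
    for gene, grp in combined.groupby("gene", sort=True):
        signs = set(np.sign(grp["logfc"]))
        if len(signs) > 1:
            discarded.append(str(gene))
            continue
        logfc = float(grp["logfc"].mean())
        recs.append((gene, logfc, float(grp["adj_p"].min()),
                     "up" if logfc > 0 else "down"))
    rows = pd.DataFrame(recs, columns=["gene", "logfc", "adj_p", "direction"])
    return DEGTable(rows, disease=disease), sorted(discarded)


def shared_degs(a: DEGTable, b: DEGTable) -> pd.DataFrame:
    """Intersect two diseases' DEG tables on gene symbol.

    Returns one row per shared gene with each disease's logfc/adj_p, the
    per-disease directions, and a flag for cross-disease direction
    conflicts (reported, not dropped).
    """
    merged = a.rows.merge(b.rows, on="gene", suffixes=("_a", "_b"))
    merged["direction_conflict"] = merged["direction_a"] != merged["direction_b"]
    return merged.sort_values("gene").reset_index(drop=True)


def run_study(dataset: StudyDataset, fdr_max: float = DEFAULT_FDR_MAX,
              effect_min: float = DEFAULT_EFFECT_MIN,
              prior_df: float | None = None) -> CollapseResult:
    """moderated_t → BH → threshold → collapse, for one study."""
    st = adjust_stats(moderated_t(dataset, prior_df=prior_df))
    return collapse_probes(filter_probes(st, fdr_max=fdr_max, effect_min=effect_min))


def validate_against_known(table: DEGTable, known_genes: set[str]) -> int:
    """Number of DEG genes also present in a user-supplied known-gene list."""
    return len(table.genes & {g.upper() for g in known_genes})
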
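# Methods

## Differential expression model

Each study is a probes × samples matrix of already-normalized log2
intensities with a two-group (control/disease) design; no normalization or
batch correction is applied, matching the assumption that inputs are
cross-comparable as published. Per probe, the effect is
logFC = mean(disease) − mean(control) and the test is the empirical-Bayes
moderated t: the pooled variance s² (d = n₁+n₂−2 df) is shrunk toward a
scaled inverse-χ² prior (d₀, s₀²) estimated from all probes by
moment-matching the log sample variances (digamma/trigamma relations; the
trigamma inverse is solved by Newton iteration). The posterior variance is
s²_post = (d₀s₀² + ds²)/(d₀+d) and p-values come from t on d₀+d df. When
the observed spread of log-variances does not exceed the sampling spread,
d₀ → ∞ and every probe uses the common variance. `prior_df=0` is an exact
escape hatch to the ordinary pooled t-test and is the contract the tests
pin down (max |Δt| < 1e-9); exact agreement with any particular
moderated-t implementation is *not* a contract — only the d₀→0 limit and
null calibration (KS < 0.08 against U(0,1)) are. Degenerate probes with
zero variance and zero difference are defined as t = 0, p = 1 so no NaN
escapes.

Thresholds: adj. p ≤ 0.05 (BH) and |log₂FC| ≥ 1.5, both inclusive and
configurable. The effect threshold is applied on the log2 scale — that is
the only reading under which a published borderline gene at magnitude 1.51
passes — and the scale is a config option, not a constant.

## Collapsing and merging rules

Probe→gene collapsing (after thresholding): probes without a gene are
dropped; a gene whose passing probes agree in sign keeps the mean logFC
and the minimum adj. p; sign-conflicting genes are discarded *and logged*,
never silently. The same rule merges studies of one disease (union across
studies, mean logFC, min adj. p, discard on sign conflict). Thresholding
happens per study before merging; whether the original procedure ordered
these steps the same way is unstated, so the order here is a documented
choice. Min-p for the collapsed/merged adj. p is consistent with
union-based inclusion and conservative for ranking; it is not an
inferential combined p-value. Shared DEGs are the gene-symbol intersection
of the two diseases' merged tables; cross-disease direction conflicts are
flagged in a column rather than removed, since the published shared lists
contain only direction-consistent genes but no explicit rule was stated.

## Over-representation

One-sided hypergeometric upper tail (equivalently the one-sided Fisher
exact test), BH-adjusted within each library. The universe defaults to the
union of genes measured across the disease's studies rather than the whole
genome — the defensible background for a meta-analysis — and is
configurable. GO-style filtering keeps terms with ≥5 hits and adjusted
p ≤ 0.05; a raw-p mode exists because pathway-library practice alternates
between raw and adjusted thresholds. GO is treated as a flat library; no
DAG propagation.

## Network stage

The zero-order network is the PPI subgraph induced on DEG seeds only.
Betweenness is unnormalized, undirected, endpoints excluded, each
unordered pair counted once (Brandes accumulation) — the convention on
which published hub tables report raw values in the 10⁴–10⁵ range. Hubs
are degree ≥ 10, boundary inclusive. Modules come from walktrap random-walk
community detection (walk length 4) with clusters split into connected
components, so modules are always disjoint and connected; the exact
community algorithm behind the original web tool is unpublished, so only
the contract (disjoint connected modules, determinism, recovery of an
unambiguous planted partition) is binding. Module significance is a
one-sided Wilcoxon rank-sum comparing, per member, intra-module vs
inter-module neighbor counts (exact for small tie-free samples, tie-
corrected normal approximation otherwise; singletons get p = 1). What
population the original tool's rank-sum compared is not recoverable; this
construction is explicit configuration, not a reproduction. Module
enrichment only tests modules with ≥10 DEG members.

## Crosstalk

JC and OC are computed on each pathway's DEG **hit** set by default — the
eligibility rules count DEGs and published crosstalk tables list hit
counts — with a full-membership mode behind a flag. Edge overlap is always
computed on the zero-order network (edges with both endpoints in the hit
set). Eligibility: ≥5 hits per term at adj. p ≤ 0.05, ≥1 shared gene, ≥1
shared edge, JC ≥ 0.01; strong ⟺ >3 shared genes. The OC bins use
half-open intervals with lower-inclusive cut points 0.2 and 0.5 (the prose
the bins come from is typographically ambiguous; this reading is fixed
here). Same-term pairs are legal candidates and use each disease's own hit
set. Ranking is total and deterministic: descending score, then shared-gene
count, then lexicographic term ids.

## Upstream regulators

Per regulator: Fisher one-sided p of the query in its target set; z is a
rank-deviation score — the regulator's p-rank for the real query
standardized against the mean/SD of its ranks over `n_background`
(default 100) seeded random queries of the same size, so regulators doing
better than background get negative z. The combined score is C = −ln(p)·|z|;
this closed form reproduces the published worked examples
(−ln(1.69e-2)·2.26 = 9.22, etc.) to printed precision, which is how the
unpublished formula was fixed. The exact background construction of the
original web service is not recoverable; the one here is Enrichr-style and
config-exposed. Up- and down-regulated shared genes are analyzed as
separate queries (plus a combined run used for recovery scoring). The
Genes2Networks-style expansion adds intermediates adjacent to ≥1 regulator
and ≥1 target (path length ≤ 2; capped highest-degree-first), and kinase
enrichment reuses the identical statistics on the expanded node set.

## Synthetic data: what it emulates and what it does not

The generator emulates: several studies per disease on "platforms" with
many-to-one probe→gene maps (Uniform{1..3} probes per gene plus a ~1%
block of unannotated noise probes); Gaussian log2 noise around per-gene
baselines (N(8, 1.5)); planted per-disease DEGs (default 10% of 2,000
genes) with shared DEGs (2%) planted in the same direction in both
diseases; conflict genes (0.5%) whose sign flips between studies and which
the merge must discard; pathway libraries seeded so planted pathways are
unambiguously enriched (disease DEGs ≈ 40% of the set) and planted
crosstalk pairs share a block of shared DEGs (4 for strong pairs, 2
otherwise) plus one planted PPI edge; a Barabási–Albert PPI backbone
(m = 2) with planted hubs wired to DEGs; and TF/kinase libraries whose
active regulators draw half their targets from the shared DEGs. Effect
sizes are N(2, 0.3) in log2 units at noise sd 0.5 and 10 samples/group —
a strong-signal regime chosen so that recovery failures indicate pipeline
defects rather than statistical noise. Hubs are planted on the most
strongly shifted shared genes so that "planted hub" is consistent with
"member of the zero-order network" by construction. Every output is a
pure function of (config, seed); per-stage streams are derived via CRC32
tags so stages are reproducible in isolation.

Deliberately not emulated: platform-specific intensity distributions and
probe naming, inter-study effect-size heterogeneity beyond the logfc_sd
draw, correlated genes, batch effects, and annotation errors. Passing
recovery tests therefore demonstrates the pipeline's correctness under its
own assumptions (independent Gaussian noise, honest probe maps), not
robustness to real microarray pathology.

## Problem sizes and numerical choices

The validation suites run the full pipeline at the default design
(2 × 3 studies × 2,000 genes × 20 samples) over 20 seeds for recovery and
10 seeds for null calibration, and regulator recovery over 50 seeds at 800
genes — sizes chosen so each suite completes in well under a minute while
binomial Monte-Carlo error stays far from the pass thresholds.
Ties in BH and in ranking are resolved by stable sorts; regulator rank
ties are averaged so results are independent of library iteration order;
p-values are floored at the smallest positive float before taking logs.

## Known limitations

Only the two-group contrast is supported (no paired designs or covariates);
gene identifiers are never converted between systems; crosstalk
significance is descriptive (no permutation p-values, as none were defined
for the original score); and the GEO loader is intentionally absent —
inputs are plain TSV/GMT/SIF/JSON files.
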
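# Methods

`gliaseq` implements the statistical pipeline of a longitudinal microglia
transcriptome study: bulk RNA-seq of microglia acutely isolated from a tau
transgenic (TG) mouse model and wild-type (WT) littermates at four ages
(2, 4, 6, 8 months), four replicates per genotype × age cell, followed by
comparison of the resulting differentially expressed genes (DEGs) with a
human brain co-expression network. This note records the models, the
defaults and why they were chosen, and what the synthetic-data tests do and
do not demonstrate.

## Synthetic data (`gliaseq.simulate`)

The exon-count generator emulates the 2 × 4 factorial design. Gene *g* in
sample *s* has expectation

μ_gs = 2^(b_g + δ_g(genotype, month)) · ℓ_s,

split across the gene's exons by fixed Dirichlet(2) proportions, with
negative-binomial sampling, variance μ + φ_g μ² (Poisson when φ = 0).
Defaults: baseline b_g ~ U(3, 9) log2 units (spanning low-expressed genes
that the exon filter removes, as in real data), library factor
ℓ_s ~ LogNormal(0, 0.2), dispersion φ_g ~ LogNormal(ln 0.05, 0.5) —
conventional bulk RNA-seq magnitudes. The design (2 genotypes × 4 months ×
4 replicates = 32 samples) mirrors the study it emulates.

Planted DEGs follow one of four temporal patterns (log2 shift per month):

| pattern | TG curve | WT curve | shape |
|---|---|---|---|
| 1 | 0, −1, −1.5, −2 | 0, 0, 0, 0 | TG down with age, WT flat |
| 2 | 0.5, 1, 1.5, 2 | 0, 0, 0, 0 | TG up with age, WT flat |
| 3 | 0.5, 1.5, 1.5, 0.5 | 0, −0.5, −1, −1.5 | TG mid-course peak, WT down |
| 4 | −0.5, −1, −1.5, −2 | 0, 0.3, 0.6, 1 | TG down, WT moderately up |

Curves are piecewise-linear in month index with ±0.5–2 log2 magnitudes;
the source figures show only qualitative medians, so magnitudes were chosen
for testability (clearly separated but not trivial at σ ≈ 0.3 residual
noise) and fixed before any recovery test was run.

The co-expression generator is a latent-factor model: each planted module
has an independent N(0, 1) factor per sample and member genes are
`loading · factor + noise_sd · N(0, 1)`, so within-module correlation is
loading²/(loading² + noise_sd²) and between-module correlation is 0.
It emulates modular structure, not the full marginal distribution, outlier
samples, or overlapping modules of real cortex data — network tests
therefore show that the ensemble recovers clean planted modules, not that
it reproduces any particular human network.

Gene sets, signed regulons, cell-type marker sets and one-to-one ortholog
maps are emitted consistently with the planted truth so that enrichment,
regulator and cross-mapping stages can be tested end to end.

## Rollup (`gliaseq.preprocess`)

Sample QC is threshold-based: a sample is excluded iff any metric
(mapping rate, mapped reads, 3′ bias, rRNA/mitochondrial fraction, adapter
content) leaves its configured pass range; defaults are permissive since
the study names the metrics but not the cutoffs.

Exon filtering drops an exon when **more than 80%** of samples have
**fewer than 10** counts; both boundaries strict (exactly 80% is retained,
a count of 10 is not low). Genes losing all exons are dropped and reported.

The gene signal is the sample effect of the robust two-way additive fit
log2(count + 1) ≈ sample effect + exon effect. The default fitter is
Tukey's median polish (≤ 20 iterations, tolerance 1e-6), with Huber
M-estimation (statsmodels RLM) as an option; "robust linear model" admits
either, and median polish is deterministic, fast and resistant to isolated
corrupted cells (a +20 outlier in one cell moves the recovered sample
effects by < 0.1, versus 20/n_exons for a plain mean). Exon effects are
re-centred to mean zero so that exactly additive data reproduces per-sample
means. The pseudocount is 1 (unstated in the source; the conventional
choice). Normalization shifts each sample additively so per-sample medians
equal the grand median on the log2 scale; the per-sample interpretation of
"median normalized" is implemented (the per-gene alternative is a
one-line change and deliberately not a flag on the default path).

## Differential expression (`gliaseq.diffexpr`)

`FactorialDE(signals, meta).fit()` fits, per gene, the full-interaction
cell-means form of the 2 × 4 factorial linear model by OLS; residual
variance is pooled over all 8 cells (24 df at n = 4), with no
empirical-Bayes moderation — the source describes a plain factorial model.
The TG − WT contrast within each month is a t-statistic on the pooled
variance. Degenerate zero-residual genes get p = 1 when the contrast is 0
and p = 0 otherwise, and are flagged.

Benjamini–Hochberg is applied across genes **within each month's
contrast** ("FDR per contrast"); no across-month correction. A DEG has
FDR < 0.05 and |signed fold change| > 1.5, where signed fold change is
sign(log2fc) · 2^|log2fc|; both inequalities strict, so |FC| = 1.5 exactly
is never a DEG. Summaries reproduce the per-month up/down and |FC| > 2
partitions, the Venn cells over month subsets, and the persistence
fraction (earliest-month DEGs still called at every later month).

## Temporal clustering and PCA (`gliaseq.patterns`)

Profiles are per-(genotype, month) medians across replicates (8-vectors),
standardized per gene; constant profiles are excluded and reported.
Distance is 1 − Pearson r with **average** linkage — Ward is reserved for
the sample-level clustering because it presumes Euclidean geometry, which
1 − r does not provide. The tree is cut at k = 4 and clusters are
renumbered by optimally matching cluster median curves to the four
canonical pattern templates (Hungarian assignment on negative
correlation), so cluster ids carry the pattern semantics. A gap-statistic
helper exists for choosing k but the pipeline default stays k = 4.

Sample clustering uses Ward on per-gene standardized data; PCA is an SVD
of the same standardized matrix with component signs fixed by the
largest-loading convention.

## Gene sets and upstream regulators (`gliaseq.genesets`)

ORA is the hypergeometric upper tail P(X ≥ k) with BH across the tested
sets and the conventional p < 0.05 / Q < 0.1 significance rule. The
default universe is the genes surviving rollup.

The activation z-score over a regulon's DEG targets is
z = Σ(±1 sign matches)/√N, so |z| ≤ √N with equality iff all matches
agree; the accompanying enrichment p is direction-blind (hypergeometric
on target membership in the DEG list). Regulator selection gates on
p < 0.05, ranks by |z| descending with lexicographic tie-break, and takes
the top 10 — one concrete reading of "gated by p-values and z-scores".
Regulons are a user-supplied TSV; no proprietary knowledge base is used
or emulated, and edge weights/confidence levels are out of scope.

## Network ensemble (`gliaseq.netinfer`)

Six base methods score all gene pairs: soft-threshold correlation
(|r|^β, β = 6 default), binned-MI ARACNe-style with DPI pruning
(ε = 0.15), lasso and ridge neighborhood regressions (symmetrized by max
|coefficient|; lasso regularization chosen per node by BIC), an
MRMR-flavoured relevance-minus-redundancy MI score, and a max-MI-per-node
filter. MI uses equal-frequency binning with ⌈n^(1/3)⌉ bins (min 3):
with ~√n bins the plug-in MI bias is ≈ (B−1)²/2n ≈ 0.5 nats regardless of
n, which compresses MI ratios enough that the multiplicative DPI tolerance
rarely fires; cube-root binning keeps the bias near 0.05 nats and makes
DPI behave as intended.

Edges are ranked per method by descending weight (average tie ranks) and
aggregated by the per-edge mean rank. Final selection is greedy local BIC:
for each gene, candidate neighbors in ascending mean-rank order join an
OLS regression of that gene while BIC strictly decreases, stopping at the
first non-improvement or `max_neighbors` (default 10); an edge survives if
either endpoint selects it (union), matching the "edges supported by the
data" reading. The per-node selection counts are kept on the network for
sparsity diagnostics.

Modules: Louvain, Walktrap, fast-greedy and label propagation run on the
selected graph; a co-assignment frequency matrix is averaged; pairs with
frequency ≥ 0.5 form the consensus graph; a seeded Louvain pass on it
gives the partition, numbered by decreasing size. Cell-type annotation
tests each module against disjointified marker sets with one-sided Fisher
tests, BH across all (module, cell type) pairs, labelling a module only
when its best marker set has q < 0.05.

## Cross-species mapping (`gliaseq.crossmap`)

Ortholog mapping in one-to-one mode drops sources with zero or multiple
targets (and targets hit by several sources), reporting them. Overlap of
each per-age DEG set with each module is a two-sided Fisher exact test
over the intersection of the mapped universe and the network nodes (the
source leaves the universe unstated; the intersection is the conservative
choice and is configurable). The odds ratio is the sample cross-product
with Haldane–Anscombe 0.5 correction on zero cells. Connectivity uses
node degree with two-sided Wilcoxon rank-sum tests: exact enumeration
when both groups have ≤ 12 untied observations, otherwise the
tie-corrected normal approximation with continuity correction.

## Problem sizes and numerical conventions

The test-suite and acceptance-script simulations use desk-scale sizes
chosen as the smallest at which each property is stable: DE calibration at
2000 genes × 20 seeds, power at 50 planted genes × 20 seeds, temporal
clustering at 200 genes/pattern × 20 seeds, the network ensemble at 120
genes, 4 modules, n = 300 × 20 seeds, BIC sparsity at 50 genes, n = 200.
Deterministic tie-breaks everywhere: stable sorts, lexicographic pair
ordering, size-ordered module ids, fixed seeds for the community
detectors. Exact-test discreteness: the null-calibration test for the
overlap statistic smears the discrete Fisher atoms uniformly (a standard
device for discrete tests), since the unsmeared two-sided p is
conservative by construction.

## Known limitations

- Gaussian OLS on log2 signals, not a count GLM; no variance moderation,
  no surrogate-variable or sex covariates (the emulated study used females
  only).
- The generator's planted effects are piecewise-linear and
  module-exclusive; real temporal programs overlap and drift.
- The base-method ensemble substitutes neighborhood regressions for
  tree-ensemble and stability-selection learners; the aggregation contract
  is unchanged but absolute edge weights differ from those methods.
- Published real-data headline counts (total DEG numbers, specific module
  overlaps and their odds ratios) depend on the original cohorts and are
  not reproduced here; the pipeline reproduces the arithmetic relations
  among the published summary counts and its own calibration on planted
  truth.
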
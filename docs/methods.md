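# Methods

`devatlas` implements the statistical core of a developmental gene
expression atlas (dGEA) analysis: given a genes × samples TPM matrix
spanning many tissues and ordered developmental stages, it derives
tissue- and stage-specific gene sets, clusters developmental
trajectories, compares externally detected co-expression modules, and
asks whether GWAS association signal concentrates in the cis windows of
those gene sets. This note records the models, the defaults and why they
were chosen, and what the synthetic benchmarks do and do not demonstrate.

## Expression QC and normalization

A gene counts as *expressed* in a sample when TPM ≥ 0.1. QC is applied in
a fixed order, each step idempotent:

1. drop genes expressed in no sample;
2. drop samples expressing strictly less than 40% of the retained genes;
3. drop all samples of tissues left with fewer than 3 samples.

Boundary semantics are strict-removal: a sample at exactly 40% breadth
and a tissue with exactly 3 samples survive. All downstream statistics
operate on log2(TPM + 0.25); the pseudocount maps TPM = 0 to −2 and keeps
fold changes finite. Sample-similarity structure uses 1 − r (Pearson)
distances, optionally restricted to the 6000 genes with the highest TPM
standard deviation (ties broken lexicographically by gene id so the list
is deterministic). Cohort-level outlier removal by clustering has no
closed-form rule; it is exposed only as an explicit exclude-list.
Missing values are not permitted: upstream quantifiers emit zeros, not NA.

## Tissue and stage specificity

**Tau.** For a non-negative per-group profile x over N groups,
τ = Σᵢ(1 − xᵢ/max x)/(N − 1); τ = 0 for uniform expression and 1 for
single-group expression, and it is invariant to positive rescaling. The
pipeline evaluates it on per-tissue median TPM transformed as
log2(x + 1), which compresses dynamic range so τ reflects breadth of
expression rather than magnitude of the top tissue.

**Differential expression.** One-vs-rest comparisons use a two-sided
Welch t-test on log2(TPM + 0.25) with Benjamini–Hochberg FDR across
genes. Count-model tests (e.g. negative-binomial GLMs) are the standard
for raw read counts, but this pipeline's inputs are TPM; since
tissue-specific calling is rank-based (below), the ranking — not the test
family — carries the result. Zero-variance degenerate genes get p = 1.

**Tissue-specific sets** are the top ⌈0.05 · n_tested⌉ upregulated genes
(log2FC > 0) ranked by ascending FDR, with the tie-break chain
FDR → p → descending log2FC → gene id fixing a deterministic order. The
ceiling makes the 101-gene case yield 6 genes. The quota denominator is
all genes tested in the comparison. If fewer upregulated genes exist than
the quota, all are returned with a warning.

**Stage-specific sets** are called within one tissue, one stage against
the rest, requiring log2FC strictly greater than 2 *and* FDR strictly
below 0.05, with at least 3 samples on each side. Both inequalities are
strict, so a gene at exactly log2FC = 2 is excluded.

## Time-course clustering

Per-gene trajectories are per-stage means of log2(TPM + 0.25),
row-standardized to mean 0 / SD 1 (population SD; constant rows dropped),
so Euclidean distance compares shape only. Fuzzy c-means alternates

- memberships  u_ik = 1 / Σⱼ (d_ik/d_ij)^{2/(m−1)}
- centroids    c_k = Σᵢ u_ik^m xᵢ / Σᵢ u_ik^m

until the objective J = Σ u^m d² changes by < 1e-6 (max 1000 sweeps),
with K distinct data rows as seeded random initial centroids. A point
coinciding with a centroid takes membership 1 there (standard degenerate
rule), and a centroid losing all membership mass stays in place rather
than dividing by zero. The objective is asserted non-increasing on every
sweep. The fuzzification exponent defaults to m = 2, the canonical
choice; it is an exposed knob since soft-clustering packages sometimes
estimate it from data. Cluster labels are arbitrary across seeds — all
comparisons use partition metrics (adjusted Rand index), never label
identity.

**Choosing K.** For each K in a range, the minimum pairwise Euclidean
distance between centroids is recorded. When K exceeds the number of
genuinely distinct trajectory shapes, two centroids must split one shape
and the curve collapses; `suggest_k` reports the K just before the
largest drop. It is a reported diagnostic, not an enforced decision.

## Co-expression module comparison

Module detection itself is out of scope — assignments arrive as
(gene, module) tables and may overlap, as factorization methods produce.
Two assignments are compared by the Jaccard module-sharing index
J(a,b) = |a∩b|/|a∪b| over all module pairs (0 for two empty modules,
with a warning). A module is summarized by its *eigengene*: the first
right-singular vector of the gene-standardized log2(TPM + 0.25)
submatrix, sign-fixed to correlate non-negatively with the module's mean
profile. Module–stage association is the Pearson correlation of the
eigengene with each stage's one-hot indicator (point-biserial), a
two-sided p from the t transform of r, and BH FDR across all
(module, stage) pairs of the run. The eigengene convention and the
one-hot correlation are the simplest constructions that yield a
per-stage correlation heatmap; mean-expression summaries are an
alternative the API accommodates by passing any per-sample score.

## GWAS gene-set enrichment

SNPs are assigned to genes when their position falls inside the gene
body extended by a symmetric ±20 kb cis window (1-based inclusive on
both ends, clamped at position 1, strand-agnostic; a SNP may serve
several genes). A gene set's SNPs are the union over its genes — a SNP
near two member genes counts once, so overlapping windows do not
double-weight effects.

The set statistic is T_sum = Σ b², the sum of squared marginal SNP
effects over the set's m_g SNPs. Its null is permutational: n_perm
(default 10,000) random SNP subsets of size m_g drawn uniformly without
replacement from all GWAS SNPs, and

    p = (1 + #{T_perm ≥ T_obs}) / (1 + n_perm).

Ties count toward the null tail and the +1/+1 pseudocount keeps p > 0;
both choices are conservative relative to a plain "greater than"
proportion, and the estimator's floor is 1/(n_perm + 1). Because T_sum
is quadratically homogeneous and the null is drawn from the same effect
vector, p is invariant to rescaling all effects — raw and standardized
effects give identical inference. Subsets are materialized by
arg-partitioning i.i.d. uniform keys, which selects every m-subset with
equal probability and vectorizes across permutations; chunking bounds
memory at a few tens of MB regardless of n_perm.

An alternative *gene-matched* null (`null_mode="gene"`) draws random gene
sets of matched gene count and uses their window unions; it differs from
the SNP-matched null when genes vary in SNP density and is the
appropriate reference when set membership, not SNP count, is the
hypothesis. BH FDR runs across all testable sets of an invocation; sets
mapping to zero SNPs are reported untestable and excluded from the
correction. The permutation null treats SNPs as exchangeable and does
not model linkage disequilibrium; with strong LD the effective number of
independent signals is smaller than m_g and empirical p values can be
anti-conservative. LD-aware nulls are out of scope.

## Synthetic data generator

The generator emulates a tissue × stage × timepoint × replicate bulk
RNA-seq design on the log2 scale:

    log2 expr = baseline_g + tissue effect + stage effect
                + archetype curve + N(0, noise_sd²)

with per-gene baselines N(baseline_log2_mean, baseline_log2_sd²),
then exponentiation and per-sample rescaling to TPM (columns sum to
1e6). Defaults: 6 tissues × 4 stages × 2 timepoints × 5 replicates,
1000 genes, 50 tissue-specific genes per tissue and 20 stage-specific
genes per stage at 4 log2-unit effects (16-fold — a strongly restricted
gene), noise SD 0.3 log2 units, consistent with replicate-level spread
of bulk RNA-seq TPM. Trajectory genes follow one of eight fixed
unit-amplitude archetype curves (monotone up/down, single peak/dip,
early/late peak, sigmoid up/down) evaluated at equally spaced stage
fractions and cycled in fixed order. The noise model is log-normal, not
a count model, because every downstream statistic operates on TPM; an
additive model on the analysis scale keeps planted effects exact. The
generator therefore does *not* emulate count overdispersion,
library-size artifacts, batch effects, correlated gene programs beyond
the planted ones, or LD among SNPs — passing benchmarks demonstrate
statistical correctness of the methods under their own assumptions, not
robustness to those real-data features.

The genome generator tiles genes deterministically: contiguous blocks
per chromosome, gene k at [k·(L+G)+1, k·(L+G)+L] for gene length L and
gap G (defaults 20 kb and 60 kb, so ±20 kb windows of adjacent genes do
not overlap and window contents are analytically predictable). SNP
positions are uniform over the covered length; effects are
N(0, background_sd²) except inside the enriched set's windows, which use
enriched_sd. Equal SDs give an exchangeable null GWAS. The
variance-inflation planting is a calibration device, not a claim about
any species' genetic architecture.

## Benchmarks and problem sizes

The validation suite (`devatlas.benchmarks`, also driven by
`scripts/acceptance.py`) uses sizes chosen to resolve each property in
seconds to a couple of minutes on one core:

- **Calibration**: 20,000 null SNPs, 500 random 10-gene sets, 1000
  permutations; the rejection rate at α = 0.05 must fall in the exact
  95% binomial interval around 0.05.
- **Power**: 3× effect-SD planting in one 50-gene set vs 20 size-matched
  decoys, 20 replicates; the planted set must attain the smallest p
  (ties broken by the standardized statistic) in ≥ 95% of replicates.
- **Exactness**: 12 SNPs / set size 3, where all 220 subsets are
  enumerable; 200,000 permutations must agree with the enumerated tail
  proportion within 0.005.
- **Specificity recovery**: ≥ 90% of planted tissue-specific genes in
  the top-5% sets; null-atlas DE call rate ≤ 5% over 20 replicates.
- **Clustering**: adjusted Rand ≥ 0.9 against 4 planted archetypes over
  10 seeds, with the K-selection curve dropping maximally after the true
  K.
- **Oracles**: τ against direct formula evaluation (≤ 1e-12), window
  mapping against a brute-force interval scan (exact), and bit-identical
  reruns of every stochastic stage under fixed seeds.

## Known limitations

- The Welch-on-log-TPM test substitutes for count-model DE; absolute p
  values differ from count-based pipelines even where rankings agree.
- The permutation null ignores LD (see above) and treats all SNPs as
  eligible for resampling regardless of allele frequency.
- The minimum-centroid-distance heuristic assumes well-separated
  archetypes; on continuous trajectory manifolds the curve decays
  smoothly and K selection is judgment.
- Eigengene summaries assume a dominant first principal component; for
  loose modules the eigengene explains little variance and the stage
  associations inherit that noise.
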
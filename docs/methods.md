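# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Data model and conventions

Relative abundances are fractions of 1 everywhere inside the package; the
0.01% detection floor is `min_abund = 1e-4`.  Abundance profiles follow the
MetaPhlAn dialect (tab-separated, features in rows, pipe-delimited taxonomy
strings with `p__`/`g__`/`s__` rank prefixes); unprefixed identifiers are
accepted as rank-unknown, and a transpose flag handles the samples-in-rows
dialect.  Readers renormalize each sample to sum 1; normalization is
idempotent and validated to 1e-6.  Sequence-level processing (FASTQ,
alignment, taxonomic/functional profiling) and raw LC-MS spectra are out of
scope: the pipeline consumes the profilers' table outputs.

## Synthetic data

The generator plants known signal so downstream stages have exact recovery
tests.  Defaults mirror the study design it emulates: 56 MK and 60 NS
samples and 149 species-level taxa.

**Microbiome.**  Per-taxon baseline log-abundances are Gaussian with SD 1.5
(log-normal abundances spanning roughly 2.5–3 decades, the realistic range
for a species table truncated at a 0.01% detection floor; a much wider
spread would push planted taxa below the absolute-abundance floor of the
LDA effect size, making them undetectable by construction).  Sample-level
log noise has SD 1.  Planted differential taxa are shifted by
`effect_log2fc·ln 2` in their enriched group (assigned at random), and taxa
of a planted module share a latent Gaussian factor with loading
√module_rho, giving within-module pairwise correlation ≈ module_rho.
Samples are then closed to sum 1: signals live on absolute abundances and
the closure's compositional distortion is deliberately retained, because
that is what a relative-abundance profiler delivers.  A consequence worth
knowing: planting strong shifts on some taxa induces genuine (smaller)
relative shifts on all others, so a small rate of "false" calls on
non-planted taxa is a property of compositional data, not a screening bug.

**Metabolome.**  Log-normal intensities (baseline log-mean ≈ 11.5, SD 1.5
across metabolites; within-metabolite noise SD 0.5).  `n_diff` metabolites
are shifted between groups by `effect_log2fc·ln 2` (default 1.0; this
keyword augments the generator because a planted shift needs a magnitude);
`n_cross` metabolites are linearly coupled to the log-scale latent signal
of randomly chosen taxa with correlation `coupling_rho`.

**Cells.**  Negative-binomial counts (dispersion 2) with log-normal
per-gene means and log-normal per-cell size factors (SD 1), so per-cell UMI
totals straddle both QC boundaries.  Genes of an "active" set are scaled by
`activity_fc` in the mapped clusters.

One master seed derives named substreams (CRC32-keyed `SeedSequence` spawn
keys), so adding a generator call never perturbs earlier draws.

What the generator does **not** emulate: real taxon names or phylogeny,
zero inflation and sequencing-depth variation, batch effects, non-linear
taxon–metabolite relationships, doublets or ambient RNA.  Passing recovery
tests therefore demonstrates correctness of the algorithms under the stated
generative model, not field performance on real cohorts.

## Ecology

Shannon uses the natural log; Simpson is reported as Gini–Simpson 1 − Σp²
(the common toolkit default; the variant is otherwise ambiguous).  Chao1
always uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), defined
even when no doubletons exist, and requires integer counts.  Alpha-
diversity group differences use the same rank-sum test as the differential
module (the choice of test is otherwise unspecified; this keeps one
two-group test throughout).

PCoA double-centers −d²/2 (Gower), orders axes by eigenvalue and scales
coordinates by √λ.  Negative eigenvalues are excluded from the
proportion-explained denominator; no correction is applied by default (a
Cailliez correction is available by flag).  ANOSIM uses tie-midranked
distances, R = (r̄_between − r̄_within)/(N(N−1)/4), and the add-one
permutation estimator p = (1 + #{R* ≥ R})/(1 + n_perm), so p is never 0 and
the floor with the default 999 permutations is 0.001.  UPGMA breaks tied
merge candidates by the lexicographic order of the clusters' smallest leaf
labels, making the newick output deterministic.

The prevalence filter keeps features at `abundance ≥ min_abund` in
`≥ ceil(min_prev·n)` samples, both comparisons inclusive, and does **not**
renormalize the surviving fractions.  Whether pathway tables should be
renormalized before the LDA screen is exposed as a config flag
(`renorm_pathways`, default off).

## Differential screening

The rank-sum test uses exact enumeration when the pooled sample size is
≤ 12 and tie-free, and the tie-corrected normal approximation otherwise —
without continuity correction, so exchangeable inputs give p = 1 exactly.
Student's t is the pooled-variance form (Welch by flag); the zero-variance
degenerate case is flagged explicitly.  BH adjustment is the standard
step-up with monotonicity enforcement, order-preserving.

The LDA (LEfSe-style) screen is two-class only — the emulated design has
no subclass structure, so the subclass (pairwise-Wilcoxon) stage is
omitted.  Stage 1 keeps features with rank-sum p < alpha.  Stage 2 scales
samples to sum 10⁶, draws `n_boot = 30` bootstraps of `boot_frac = 2/3` of
each class, fits a one-dimensional Fisher discriminant with the pooled
within-class covariance ridge-shrunk by ε = 1e-3 of its mean variance, and
scores feature j as log10(1 + mean over bootstraps of
(|Δmean_j| + |w_j|·|Δprojection|/‖w‖)/2).  Defaults follow the original
effect-size screen's description and are config-exposed.  Calls require
p < alpha AND score ≥ cut (2.5 taxa, 3.0 pathways).

OPLS-DA removes `n_ortho` (default 1) y-orthogonal components by the
orthogonal-filtering NIPALS scheme, then fits one predictive component.
VIP defaults to the predictive component only (√J·|w_j|/‖w‖, giving
mean(VIP²) = 1 exactly); the multi-component formula including orthogonal
components is available (`vip_mode="all"`).  Zero-variance features are
excluded with a warning.  The enrichment background is the full universe of
detected features of that omics layer.

## Networks

Edges require p < 0.05 AND |ρ| > 0.3 (strict), then the 200 strongest |ρ|
are kept — filters first, then the cap, with ties at the cut broken by
lexicographic node-pair order.  Networks are built per group (MK samples
only; NS samples only).  Modules come from seeded Louvain modularity
maximization on the unweighted, sign-ignored graph (the module algorithm is
otherwise unspecified; seed 0 by default).  Zi uses the population SD of
within-module degrees (0 when the SD is 0); Pi = 1 − Σ(k_im/k_i)² (0 for
isolated nodes); degrees are unweighted and sign-ignored by default with an
|ρ|-weighted option.  All four role thresholds are strict, so a node
exactly on a boundary is peripheral; core species are the connectors.

## Integration

Cross-omics blocks restrict to the intersection of sample ids (≥ 5
required), compute midrank Spearman ρ with two-sided p from the
t-approximation (df = n − 2), and apply BH per block, not globally —
blocks are reported separately.  The display mask is p < 0.05; both p and
q are always emitted so either display rule can be applied.  "Highly
associated" rows are operationalized as the top-k (default 50, mirroring
the emulated analysis) by the maximum |ρ| over displayed cells, with an
optional |ρ| floor — the original criterion is not stated, so it is made
explicit and tunable.

## Classifier

A single stratified split (70/30, nearest rounding, ≥ 1 test sample per
group) mirrors the emulated design; no cross-validation or hyperparameter
search.  The forest uses 500 trees with untouched class priors and no
feature scaling.  Importance is the mean decrease in accuracy estimated
per tree on its out-of-bag samples (the classic randomForest estimator):
for each tree, OOB accuracy is compared with OOB accuracy after permuting
one feature's column, and decreases are averaged over trees and
`n_repeats` permutations.  Whole-forest permutation on the held-out test
set is available (`estimator="test"`), but it is a much coarser
instrument: test accuracy moves in steps of 1/n_test and a redundant
ensemble rarely changes a prediction when a single feature is permuted, so
correlated informative features collapse to zero importance and the top-k
panel degenerates to tie-breaking.  The per-tree OOB estimator was
therefore made the default.  ROC scores are out-of-sample forest votes on
the test set (`roc_on="all"` evaluates all samples); AUC uses the
Mann–Whitney identity with ties at ½, and the 95% CI is a stratified
percentile bootstrap (2000 resamples) widened, if necessary, to contain
the point estimate.

## Single cell

QC keeps cells with 200 ≤ total UMI ≤ 6000 (boundaries inclusive — the
rule removes strictly-below/above).  Pathway activity uses a transparent
rank-AUC scorer: genes ranked per cell by descending count (average ranks
for ties), score = area under the recovery curve of the set's detected
genes within the top ⌈top_frac·G⌉ ranks, normalized by the maximal
attainable area, in [0, 1].  The normalizer uses the full set size so the
score is monotone when set-gene counts rise; undetected set genes never
count as recovered, and a cell detecting no set gene scores 0.  The
upstream scorer this replaces is treated as a black box by the emulated
analysis, so a fully specified, testable statistic is used instead
(top_frac default 0.05).  Doublet removal, variable-gene selection,
embedding and clustering are consumed as precomputed labels, not
recomputed.

## Problem sizes used in verification

The acceptance checks run on desk-scale simulations chosen to finish in a
few minutes on one CPU while keeping estimator variance well inside the
asserted margins: 20 seeds for LDA recovery at the cohort size (56/60,
150 taxa), 3 seeds × 780 metabolites for the VIP screen, 10 seeds each for
signal and null classifier runs, 1000–10000 replicates for type-I-error
calibration, and 100 random graphs for the Zi/Pi oracle.

## Known limitations

No compositional correlation correction (SparCC/SPIEC-EASI) — Spearman on
closed fractions, as in the emulated analysis; no rarefaction or UniFrac;
no effect-size confidence intervals for the screens; the cohort-scale
headline numbers of the emulated study (e.g. specific species counts and
AUCs) depend on its real data and are not reproduction targets — the
package verifies the machinery, not the cohort.
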
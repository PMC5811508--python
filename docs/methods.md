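# Methods

This note documents the statistical procedures implemented in `pmikit`,
the generative model behind the synthetic cohorts, the numerical choices
made where the design was genuinely open, and what the recovery tests do
and do not demonstrate about real post-mortem data.

## Data model and preprocessing

Expression is held as a genes × samples object with three layers: raw
counts, RPKM = 10⁹·count/(gene length · library size), and
log2(RPKM + pseudo-count) with pseudo-count 1 (so an all-zero gene has
log value exactly 0). Gene filtering keeps genes with at least 5 total
exonic reads; analyses of continuous PMI association additionally require
tissue-mean RPKM strictly above 0.5, evaluated on pre-normalization RPKM.

Quantile normalization is applied per tissue on the log layer: each
sample's values are replaced by the mean of order statistics across the
tissue's samples, rank-matched, with tied ranks receiving the average of
the target values they span. This is the canonical behavior of the
widely used `normalize.quantiles` routine. After normalization all
samples of a tissue share the same multiset of values (exactly so for
tie-free data; ties are averaged, which perturbs the multiset by the tie
structure of each column).

Samples are assigned to five PMI intervals — [0, 60), [60, 240),
[240, 360), [360, 900), [900, ∞) minutes — closed on the left and open on
the right. Pre-mortem samples (negative PMI, flagged) are excluded from
interval-based analyses; a negative PMI without the flag is a validation
error. An optional cleaning rule drops post-mortem samples whose sample
PMI is below the donor PMI, an impossible collection order.

## Temporal differential expression

For each gene and each pair of consecutive intervals with at least five
samples per side, a two-sided Wilcoxon rank-sum test is computed on the
(normalized log) expression, and the fold change as the log2 ratio of the
two group medians on the positive scale (RPKM + 1). A (gene, transition)
event is significant when p < 0.05 and the median ratio exceeds the
fold-change threshold, default 2× (i.e. |log2 FC| > 1), with no
multiple-testing correction at this stage. Two numerical choices deserve
comment:

- **Fold change on the positive scale.** Standardized z-scores are
  convenient for visualization but the log ratio of two z-score medians
  is undefined whenever a median is negative, so the gate is evaluated on
  positive-scale medians. The z-score medians of both intervals are still
  reported for heatmaps. Because the rank-sum test is invariant under
  monotone transforms, the p-value is identical either way.
- **Threshold on the ratio scale.** The default gate is "greater than
  2-fold" (strictly), exposed as `fc_threshold`; a planted 4-fold shift
  passes it with high probability at 20 samples per interval, whereas a
  gate at 4-fold would sit exactly on the boundary of a 4-fold effect and
  turn recovery into a coin flip.

Rank-sum p-values use the exact null distribution whenever both groups
have ≤ 25 observations and the pooled data are tie-free, and the normal
approximation with continuity and tie correction otherwise; for group
sizes ≤ 8 the exact p-value is verified against full enumeration of rank
assignments in the test suite. Transitions with fewer than five samples
on either side are skipped, not errored.

## Covariate-corrected PMI association

Candidate covariates are screened by level count (2–15 distinct values),
numeric encoding of categoricals by level order (deliberately not
one-hot), and |Pearson r| > 0.1 with PMI, with whole variable groups that
directly describe the collection procedure excluded by name prefix.

The association itself is a two-step scheme: expression is residualized
on the covariate matrix by OLS (collinear columns dropped with a
warning), **PMI is residualized on the same covariates**, and the Pearson
correlation of the two residual vectors is computed with t-distributed
p-values (df = n − 2) and Benjamini–Hochberg adjustment within tissue.
Residualizing both sides makes the statistic exactly the partial
correlation r(expression, PMI | covariates) (Frisch–Waugh), which the
test suite verifies against an independent partial-correlation
implementation to 1e-10. Correlating residuals against *raw* PMI — a
variant sometimes written in analysis scripts — multiplies every r by
√(1 − R²(PMI ~ covariates)) without changing the gene ranking; we use
the unattenuated form. PMI never enters the covariate regression, so the
scheme remains a residualize-then-correlate procedure rather than a
joint model.

Tissue similarity is the Spearman correlation of two tissues' per-gene r
profiles over shared genes (pairs with < 10 shared genes are flagged
unreliable), ordered by average-linkage clustering on 1 − similarity.
Structural-feature association is the Pearson correlation between a
per-gene feature vector (exon count, gene length, GC content, …) and the
genes' r values.

## Splicing

PSI is computed from **pre-aggregated** inclusion/exclusion junction
counts as inc/(inc + exc); junction bookkeeping from raw alignments is
upstream of this package. A cell is missing when fewer than 5 total reads
support it; an exon enters analysis when its missing fraction is below
10%, its PSI standard deviation is positive, and its PSI range exceeds
0.1. PSI–PMI association is a plain Pearson correlation on
pairwise-complete samples with BH adjustment and the joint |r| > 0.5,
FDR ≤ 1% significance rule (covariates can optionally be supplied, in
which case the same residualization as above applies). Pre- vs
post-mortem differential inclusion in blood uses the rank-sum test, BH,
ΔPSI = median(post) − median(pre), and the FDR < 1% with |ΔPSI| > 0.1
rule; the direction summary reports the fraction of significant exons
more included pre-mortem.

Splicing entropy uses isoform abundance ratios P(Iᵢ) = Iᵢ/ΣIᵢ computed
from isoform RPKM (not counts) and the Shannon entropy with natural log
and 0·log 0 = 0; the log base only rescales entropy and cannot affect
correlation-based thresholds. Genes require ≥ 2 isoforms and non-zero
total expression in ≥ 90% of samples; samples with zero total expression
get missing entropy. The major-isoform share (max ratio) is reported per
sample for dominance analyses.

## Networks, modularity, MDS

To ask whether tissue signatures persist across PMI, samples are first
balanced: tissues with fewer than `min_per_bin` (default 10) samples in
any populated PMI bin are dropped, and each surviving tissue contributes
exactly k samples per bin, with k the minimum available count over all
(bin, tissue) pairs, drawn with a seeded generator. Within each bin a
graph is built whose nodes are samples and whose edges join pairs with
Pearson correlation (on log2(RPKM+1), all filtered genes) strictly above
a threshold; the graph is unweighted after thresholding. Newman–Girvan
modularity Q = Σ_c [e_c/m − (d_c/2m)²] of the tissue-label partition is
computed on this graph (zero-edge graphs get Q = 0 with a warning). The
informative threshold range is data-dependent — it must leave densities
comparable and below saturation — so thresholds are user parameters
swept over a list. The embedding is non-metric MDS on the
dist(a, b) = 1 − r(a, b) distance, with the stress value and an
average-linkage dendrogram on the same distance returned; constant
samples have undefined correlation and are dropped with a warning.

## Sample QC

MT% divides reads in annotated mitochondrial genes by reads in all
annotated genes; nMT% divides each sample's MT% by its tissue's median
MT%, making tissues comparable (the in-tissue median of nMT% is 1 by
construction). The PMI dependence is an OLS slope of nMT% on PMI with a
confidence interval, an optional age covariate, and a rank-sum comparison
of nMT% between early and late samples split at 680 minutes (exposed as
a flag). The 5′/3′ coverage-bias ratio is defined here as the mean
per-base coverage over the first 50 bases of a transcript divided by the
mean over its last 50, averaged over transcripts with ≥ 100 covered bases
and non-zero 3′ coverage — one defensible reading of a "50 bp-based"
5′/3′ ratio, stated explicitly because aggregation order is otherwise
ambiguous.

## PMI prediction

The two-step framework:

1. **Tissue models.** Individuals (donors) are split 75/25 into train and
   test, stratified by quantiles of their tissue counts so both sides
   keep a similar distribution of tissues per individual; no donor
   appears on both sides. Per tissue, protein-coding genes with
   |Pearson r| ≥ 0.4 against the tissue samples' PMI *on training samples
   only* are selected (absolute correlation: a gene falling with PMI is
   as informative as one rising; an optional cap keeps the top genes by
   |r|). For each of 13 ensemble seeds, hyperparameters are chosen by
   3-repeat-5-fold cross-validation over a grid (depth {4, 5, 6},
   learning rate {0.001, 0.01, 0.05, 0.1}, gamma {0, 0.05, 0.1, 0.15})
   minimizing RMSE, with the number of boosting rounds chosen by early
   stopping on the held-out fold within a 1000-round cap; ties go to the
   least complex model (smallest depth, then fewest rounds). The winner
   is refit on all training samples. The tissue target is the sample's
   own PMI, not the donor's.
2. **Individual aggregation.** Seed-wise predictions are averaged per
   sample, each tissue's elapsed processing time is subtracted
   (normalizing predictions to the start of the collection procedure),
   and the corrected values are averaged over the top-k tissues by
   training R² (default 20) into the individual PMI. The coefficient of
   variation of the corrected values measures per-individual stability.

R² throughout is the squared Pearson correlation of real vs predicted
(the regression R², which is what a fit of one on the other reports).
Leakage is a contract, not a hope: prefiltering, CV and grid search read
only training individuals, and the test suite asserts that scrambling
test-set PMI leaves the serialized boosters byte-identical. The
pre-mortem negative control repeats the full train/test procedure on
pre-mortem blood with time-to-death as the target; since pre-mortem
expression carries no post-mortem signal, any predictive skill there
would indicate overfitting. Subset search enumerates all tissue
combinations of sizes 2–6 per test individual and tabulates how often
each tissue joins the optimal (minimum |error|) subset. The entire
pipeline also accepts any gene × sample feature matrix (e.g.
transcript-integrity scores) in place of expression; only the input
matrix changes.

Seeds flow top-down: a master seed deterministically derives per-stage,
per-tissue and per-repetition seeds (`numpy.random.SeedSequence`), and no
stage draws from global randomness, which is what makes two pipeline runs
with one master seed byte-identical.

## Synthetic cohort generator

The generator emulates the cohort structure the analyses need, not raw
reads. Donors receive a PMI drawn uniformly on (17, 1739) minutes by
default (the observed range of such cohorts); an `interval_balanced`
option instead picks one of the five intervals uniformly first, for
experiments that need comparable per-interval group sizes. Each tissue is
retained per donor with a configurable probability and adds an elapsed
delay uniform on (10, 300) minutes, so sample PMI = donor PMI + elapsed
exactly. A configurable fraction of blood samples is pre-mortem with PMI
uniform on (−1300, −20) minutes and zero elapsed time.

Counts follow a negative binomial (gamma-Poisson, dispersion
`noise_dispersion`, default 0.05) with log2 mean

    baseline(gene) + signature(gene, tissue) + trajectory shift
    + covariate loadings + beta(gene)·latent(sample) + N(0, 0.5)

Baselines are N(6, 1.5²) log2 units; tissue signatures N(0, 2²) give the
strong tissue identity the modularity analyses rely on. Trajectory
classes are piecewise interval shifts of ±`effect_size_log2`: *early*
steps at I1→I2 and stays; *sustained* adds an equal step at every
transition; *peaked* steps up into I4 and back down into I5; class
fractions, magnitude and the affected tissue set are configurable.
Covariates are ρ·z(PMI) + √(1−ρ²)·noise with a single confounding knob ρ,
and every gene carries random covariate loadings, so an uncorrected
analysis shows inflated PMI associations that residualization must
remove. *Monotonic-linear* genes load on a shared per-sample latent
L = √(r²)·e + √(1−r²)·η, where e is z(PMI) orthogonalized against the
realized covariates (so the planted association survives residualization
exactly) and `pmi_latent_r2` caps the PMI variance recoverable from
expression; the latent is zeroed for pre-mortem samples, which is what
makes the negative control signal-free by construction. When `target_r`
is set, per-gene effect sizes are solved so the planted partial
correlation equals the target, using a delta-method estimate of the
count-noise variance; the recorded `gene_true_r` refers to that partial
correlation. The latent noise η is drawn per sample, not per donor, so
averaging several tissues of one donor genuinely improves the individual
estimate, as multi-tissue aggregation should.

Mitochondrial genes are generated so the expected mitochondrial count
share follows a tissue-specific linear trend in PMI (an odds factor
against the nuclear total, clipped to [0.01, 0.85]). Isoform ratios mix a
gene's base proportions toward the uniform distribution with weight
clip(drift·PMI, 0, 1) plus multiplicative noise, so entropy rises with
PMI for drift genes; exon inclusion draws binomial reads around
clip(psi₀ + slope·PMI), with totals Poisson around a configurable mean.

**What the generator does not emulate:** read-level artifacts, alignment
and mapping bias, batch structure beyond the confounded covariates,
library-preparation effects, cellular-composition shifts, and any
correlation structure among genes beyond the shared latent and tissue
signatures. Passing recovery tests therefore demonstrates that the
estimators recover what they claim to measure under a faithful
overdispersed count model — not that real post-mortem tissue satisfies
these models.

## Problem sizes and defaults in the shipped tests

The test and acceptance runs use desk-scale cohorts chosen as the
package's defaults for self-contained validation: 100–200 donors, 1–8
tissues, 400–2000 genes, 100–200 pooled null replicates for calibration;
the predictor runs use a reduced configuration (`PredictorConfig.desk_scale()`:
3-model ensembles, an 8-point grid, 1-repeat-3-fold CV, 300-round cap, 50
prefiltered genes) and the negative control a lighter one still
(single-model, 4-point grid, 20 repartitions). The full-scale defaults
(13 models, 48-point grid, 3×5 CV) remain the constructor defaults for
real use.

## Known limitations

- The temporal fold-change gate on positive-scale medians is sensitive to
  the pseudo-count for genes expressed near zero.
- PSI ratios ignore junction-level read assignment uncertainty; the
  binomial read model in the generator is correspondingly idealized.
- The per-gene p-values of the partial correlation use df = n − 2 rather
  than n − 2 − k; for the sample sizes and covariate counts involved the
  difference is negligible relative to the BH step.
- Boosted-tree determinism is guaranteed for single-threaded training
  (`n_jobs=1`), which the package fixes; multi-threaded histogram
  building can break bit-reproducibility.
- Network thresholds near saturation (density → 1) make modularity
  uninformative; the sweep reports density precisely so such settings are
  visible.
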
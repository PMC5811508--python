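# pmikit

Tools for studying how death and post-mortem cold ischemia reshape bulk
tissue transcriptomes, and for predicting an individual's post-mortem
interval (PMI) from multi-tissue gene expression.

Post-mortem tissue is the main source of "normal" human expression data,
but RNA levels keep changing after death: some genes respond within the
first hour, others shift for many hours, and the response is strongly
tissue-specific. For anyone analyzing post-mortem RNA-seq — biobank
studies, eQTL projects, forensic pathology — two questions matter: *how
much does ischemia time distort expression (and can covariates absorb
it)?* and *can the distortion itself be read backwards to estimate the
time since death?* `pmikit` implements a complete analysis pipeline for
both, together with a synthetic-cohort generator that plants known effects
so that every stage can be validated by parameter recovery without any
protected human data.

## What it computes

Throughout, PMI is measured in minutes; a tissue sample's PMI is the time
from death (or cessation of blood flow) to tissue stabilization, the
donor's PMI is the time to the start of the collection procedure, and the
difference is the elapsed processing delay of that tissue. Pre-mortem
blood samples carry negative PMI.

- **Temporal differential expression** (`pmikit.temporal`) — samples are
  grouped into five PMI intervals (I1 < 1 h, I2 1–4 h, I3 4–6 h,
  I4 6–15 h, I5 ≥ 15 h); every pair of consecutive intervals with ≥ 5
  samples per side is compared per gene by a two-sided Wilcoxon rank-sum
  test, and a gene is called at a transition when p < 0.05 and the
  median fold change exceeds 2×. Cross-tissue recurrence is summarized per
  gene.
- **Covariate-corrected PMI association** (`pmikit.association`) — each
  gene's quantile-normalized log2(RPKM+1) expression and the PMI vector
  are both residualized on selected covariates by OLS; the Pearson
  correlation of the residuals (equal to the partial correlation
  r(expression, PMI | covariates) by Frisch–Waugh) is tested and
  BH-adjusted per tissue. Covariate screening (2–15 levels, |r| > 0.1
  with PMI, excluded variable groups), tissue-similarity clustering of
  correlation profiles, and gene-structural-feature correlations are
  included.
- **Splicing** (`pmikit.splicing`) — percent-spliced-in from
  inclusion/exclusion junction reads (PSI = inc/(inc+exc), missing below
  5 total reads; exons filtered by < 10% missingness, sd > 0, range
  > 0.1), PSI–PMI correlation, pre- vs post-mortem differential inclusion
  in blood (FDR < 1%, |ΔPSI| > 0.1), and per-gene isoform Shannon entropy
  E(G) = −Σ p(Iᵢ) log p(Iᵢ) with its PMI association.
- **Network modularity & MDS** (`pmikit.network`) — tissue-balanced
  subsamples per PMI bin, sample-correlation networks thresholded on
  Pearson r, Newman–Girvan modularity Q of the tissue partition, and
  non-metric MDS on the 1 − r distance.
- **Sample QC** (`pmikit.qc`) — mitochondrial read fraction MT%, its
  tissue-normalized form nMT%, the nMT% ~ PMI slope per tissue, and the
  5′/3′ coverage-bias ratio.
- **PMI prediction** (`pmikit.predictor`) — a two-step framework: per
  tissue, an ensemble of gradient-boosted tree regressors (13 seeds by
  default; grid over depth 4–6, learning rate 0.001–0.1, gamma 0–0.15,
  ≤ 1000 rounds; repeated k-fold CV minimizing RMSE) predicts the tissue
  sample's PMI from PMI-correlated protein-coding genes; predictions are
  corrected to donor level by subtracting each tissue's elapsed time and
  averaged (over the top-k tissues by training R²) into one individual
  estimate with a coefficient-of-variation stability score. Includes
  individual-level train/test splitting, leakage guards, a pre-mortem
  negative control, optimal tissue-subset search, death-class
  stratification, and an alternate-feature mode (any gene × sample matrix,
  e.g. transcript-integrity scores, in place of expression).
- **Synthetic cohorts** (`pmikit.synthetic`) — negative-binomial counts on
  a log2 link with tissue signatures, planted trajectory classes (early /
  sustained / peaked / linear), covariates confounded with PMI, pre-mortem
  blood, mitochondrial PMI slopes, entropy-drifting isoform ratios and
  PSI slopes — all recorded in a `SyntheticTruth` oracle.

## Worked example

Covariate correction (examples/03_pmi_association.py). Three covariates
are confounded with PMI at ρ = 0.5 and 5% of 1000 genes are planted at a
partial correlation of 0.5 with PMI:

```
significant at FDR<1% with covariates:      55 of 993 (5.5%)
significant at FDR<1% without covariates:  573 of 993 (57.7%)
planted genes recovered: 55/56
```

Without residualization, more than half the genes look PMI-associated
purely through the confounded covariates; the corrected analysis returns
almost exactly the planted 5%.

PMI prediction (examples/06_predict_pmi.py), five tissues, 120 donors,
planted latent explaining ~60% of PMI variance:

```
individual-PMI R^2 (real vs predicted): 0.74
individual_id  individual_pmi_pred  real_pmi  cv
        D0000                942.8     943.7 0.4
        D0001                608.2     608.1 0.4
```

Each held-out individual's PMI (minutes) is the average of its
elapsed-time-corrected tissue predictions; `cv` is their coefficient of
variation (lower = more consistent tissues).

The other examples cover cohort simulation, the temporal scan, the
modularity sweep and the splicing statistics; each prints what it computes
and a line on what the numbers mean.

## Command line

A thin CLI wraps the library for file-based use:

```bash
pmikit simulate --seed 1 --out cohort/
pmikit temporal-de --counts-dir cohort/ --metadata cohort/samples.tsv --out tde.tsv
pmikit run pipeline.yaml     # YAML-configured multi-stage run with manifest
```

Subcommands: `simulate`, `preprocess`, `temporal-de`, `pmi-assoc`,
`modularity`, `splicing`, `qc`, `run`. All tabular outputs are TSV; the
pipeline manifest records stage seeds and SHA-256 hashes of every output,
and two runs with the same master seed produce identical tables.

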
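"""Covariate-corrected gene-PMI correlation.

Plants genes at a partial correlation of 0.5 with PMI while three
covariates are confounded with PMI at rho = 0.5, then compares the
covariate-residualized analysis with the naive covariate-free one.
"""

from pmikit import SyntheticConfig, generate_cohort, pmi_correlation
from pmikit.preprocess import normalize_per_tissue

cfg = SyntheticConfig(
    n_donors=158, tissues={"t": 0.95}, n_genes=1000,
    effect_class_fractions={"none": 0.95, "monotonic_linear": 0.05},
    target_r=0.5, n_covariates=3, covariate_pmi_confounding=0.5,
    covariate_effect_log2=0.4, seed=3,
)
mat, samples, truth = generate_cohort(cfg)
mat = normalize_per_tissue(mat, samples)

covs = ["cov1", "cov2", "cov3"]
with_cov = pmi_correlation(mat, samples, "t", covariates=covs, fdr_threshold=0.01)
no_cov = pmi_correlation(mat, samples, "t", covariates=[], fdr_threshold=0.01)

print(f"significant at FDR<1% with covariates:    {with_cov['significant'].sum():4d}"
      f" of {len(with_cov)} ({100 * with_cov['significant'].mean():.1f}%)")
print(f"significant at FDR<1% without covariates: {no_cov['significant'].sum():4d}"
      f" of {len(no_cov)} ({100 * no_cov['significant'].mean():.1f}%)")
planted = truth.gene_effect_class[truth.gene_effect_class == "monotonic_linear"].index
found = with_cov.set_index("gene").reindex(planted)["significant"]
print(f"planted genes recovered: {int(found.sum())}/{len(planted)}")
# without residualization, covariates confounded with PMI inflate the hit
# count far beyond the planted 5%; the corrected analysis recovers almost
# exactly the planted set.
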
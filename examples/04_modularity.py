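"""Tissue-signature persistence across PMI bins via network modularity.

Balances samples per tissue within each PMI bin, thresholds the
sample-sample correlation network, and shows that modularity by tissue
label stays stable across bins when no PMI effect is planted.
"""

from pmikit import SyntheticConfig, generate_cohort, balanced_subsample, modularity_sweep

cfg = SyntheticConfig(
    n_donors=120, tissues={"muscle": 1.0, "lung": 1.0, "liver": 1.0},
    n_genes=300, effect_class_fractions={"none": 1.0},
    pmi_distribution="interval_balanced",
    pmi_range_minutes=(1.0, 1800.0), elapsed_delay_range_minutes=(1.0, 10.0),
    seed=4,
)
mat, samples, _ = generate_cohort(cfg)
bins = balanced_subsample(samples, min_per_bin=8, seed=0)
sweep = modularity_sweep(mat, bins, thresholds=[0.5, 0.55, 0.6], samples=samples)
print(sweep.pivot(index="bin", columns="threshold", values="modularity").round(3))
# rows are PMI bins, columns correlation thresholds: modularity ~0.65 for
# three well-separated tissues, and approximately constant down each
# column -- tissue identity survives the post-mortem interval.
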
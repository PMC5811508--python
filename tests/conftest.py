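import numpy as np
import pandas as pd
import pytest

from pmikit import SyntheticConfig, generate_cohort
from pmikit.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def mixed_cohort():
    """A small multi-tissue cohort with every planted effect class."""
    cfg = SyntheticConfig(
        n_donors=80,
        tissues={"muscle": 0.9, "lung": 0.9, "blood": 0.9},
        n_genes=400,
        effect_class_fractions={
            "none": 0.7,
            "early": 0.1,
            "sustained": 0.05,
            "peaked": 0.05,
            "monotonic_linear": 0.1,
        },
        effect_size_log2=2.0,
        n_covariates=2,
        covariate_pmi_confounding=0.4,
        premortem_blood_fraction=0.4,
        mt_slope_per_tissue={"muscle": -5e-5, "lung": -5e-5, "blood": 1e-4},
        n_isoform_genes=40,
        entropy_drift=5e-4,
        seed=11,
    )
    mat, samples, truth = generate_cohort(cfg)
    return cfg, mat, samples, truth


def make_matrix(values, sample_ids=None, gene_ids=None, lengths=None, biotype=None):
    """ExpressionMatrix from a 2-D array of counts (genes x samples)."""
    values = np.asarray(values)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cols = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    counts = pd.DataFrame(values, index=genes, columns=cols)
    lengths = pd.Series(lengths if lengths is not None else 1000, index=genes)
    bio = pd.Series(biotype if biotype is not None else "protein_coding", index=genes)
    return ExpressionMatrix.from_counts(counts, lengths, bio)


def make_samples(n, tissue="muscle", pmi=None, donor_ids=None, **extra):
    """Minimal valid sample table."""
    pmi = np.asarray(pmi if pmi is not None else np.linspace(30, 1500, n), float)
    donors = donor_ids or [f"d{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(n)],
            "donor_id": donors,
            "tissue": tissue,
            "sample_pmi_minutes": pmi,
            "donor_pmi_minutes": np.where(pmi >= 0, np.maximum(pmi - 30, 0), 100.0),
            "elapsed_minutes": np.where(pmi >= 0, np.minimum(pmi, 30.0), 0.0),
            "rin": 7.0,
            "premortem": pmi < 0,
            "hardy_class": 2,
            "death_class": "other",
        }
    )
    for key, val in extra.items():
        df[key] = val
    return df
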
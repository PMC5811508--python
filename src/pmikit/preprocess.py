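"""Loading, filtering, normalization and PMI interval assignment.

Expression values are RPKM, log2-transformed with a pseudo-count of 1, and
quantile-normalized per tissue (each sample's values are replaced by the
mean of order statistics across that tissue's samples, rank-matched, which
is the behavior of the canonical quantile-normalization routine).

Samples are assigned to five PMI intervals:

    I1: [0, 1 h)   I2: [1 h, 4 h)   I3: [4 h, 6 h)   I4: [6 h, 15 h)   I5: [15 h, inf)

Bounds are closed on the left and open on the right.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, read_sample_table

__all__ = [
    "PMI_INTERVALS",
    "INTERVAL_LABELS",
    "assign_pmi_intervals",
    "quantile_normalize",
    "normalize_per_tissue",
    "filter_genes",
    "load_and_normalize",
    "drop_inconsistent_postmortem",
]

#: label -> (lower_minutes inclusive, upper_minutes exclusive)
PMI_INTERVALS: dict[str, tuple[float, float]] = {
    "I1": (0.0, 60.0),
    "I2": (60.0, 240.0),
    "I3": (240.0, 360.0),
    "I4": (360.0, 900.0),
    "I5": (900.0, np.inf),
}
INTERVAL_LABELS = tuple(PMI_INTERVALS)
_EDGES = np.array([0.0, 60.0, 240.0, 360.0, 900.0, np.inf])


def assign_pmi_intervals(samples: pd.DataFrame) -> pd.Series:
    """Map each post-mortem sample to its PMI interval label.

    Pre-mortem samples (flagged, negative PMI) are excluded from the result;
    a negative PMI without the pre-mortem flag is a validation error.
    """
    pmi = samples["sample_pmi_minutes"].to_numpy(float)
    pre = samples["premortem"].to_numpy(bool)
    bad = (pmi < 0) & ~pre
    if bad.any():
        raise ValueError(
            f"{bad.sum()} samples have negative PMI without the premortem flag"
        )
    post = samples.loc[~pre]
    idx = np.searchsorted(_EDGES, post["sample_pmi_minutes"].to_numpy(float), side="right") - 1
    labels = pd.Series(
        pd.Categorical.from_codes(idx, categories=list(INTERVAL_LABELS)),
        index=post["sample_id"].to_numpy(),
        name="pmi_interval",
    )
    return labels


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean of their order statistics.

    After normalization every column holds the same multiset of values.
    Tied values within a column receive the average of the target values
    their ranks span.
    """
    X = values.to_numpy(float)
    if X.shape[1] <= 1:
        return values.copy()
    target = np.sort(X, axis=0).mean(axis=1)
    n = X.shape[0]
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), target)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_per_tissue(mat: ExpressionMatrix, samples: pd.DataFrame) -> ExpressionMatrix:
    """Quantile-normalize the log layer within each tissue."""
    tissue = samples.set_index("sample_id")["tissue"]
    log = mat.log_rpkm.copy()
    for t, ids in tissue.groupby(tissue).groups.items():
        cols = [s for s in ids if s in log.columns]
        if len(cols) > 1:
            log[cols] = quantile_normalize(log[cols])
    return mat.with_log_layer(log)


def filter_genes(
    mat: ExpressionMatrix,
    min_reads: int = 5,
    min_mean_rpkm: float = 0.0,
    biotypes: set[str] | None = None,
) -> ExpressionMatrix:
    """Keep genes with >= min_reads total reads, mean RPKM strictly above
    ``min_mean_rpkm`` and (optionally) biotype in ``biotypes``.

    Gene order is preserved; the filter is idempotent.
    """
    if min_reads < 0 or min_mean_rpkm < 0:
        raise ValueError("thresholds must be non-negative")
    keep = mat.counts.sum(axis=1) >= min_reads
    if min_mean_rpkm > 0:
        keep &= mat.rpkm.mean(axis=1) > min_mean_rpkm
    if biotypes is not None:
        keep &= mat.biotype.isin(biotypes)
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return mat.subset_genes(mat.gene_ids[keep])


def drop_inconsistent_postmortem(samples: pd.DataFrame) -> pd.DataFrame:
    """Blood cleaning rule: drop post-mortem samples whose sample PMI is
    smaller than the donor PMI (an impossible collection order)."""
    bad = (~samples["premortem"]) & (
        samples["sample_pmi_minutes"] < samples["donor_pmi_minutes"]
    )
    if bad.any():
        warnings.warn(f"dropping {bad.sum()} post-mortem samples with PMI below donor PMI")
    return samples.loc[~bad].copy()


def load_and_normalize(
    counts_dir: str | Path,
    metadata_path: str | Path,
    pseudo_count: float = 1.0,
    prefix: str = "expression",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Load a TSV cohort, compute RPKM and log layers, quantile-normalize
    per tissue. Returns (matrix, sample table)."""
    mat = ExpressionMatrix.read_tsv(counts_dir, prefix=prefix, pseudo_count=pseudo_count)
    samples = read_sample_table(metadata_path)
    mat = mat.subset_samples([s for s in mat.sample_ids if s in set(samples["sample_id"])])
    return normalize_per_tissue(mat, samples), samples
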
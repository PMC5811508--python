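"""Non-linear temporal differential expression between consecutive PMI intervals.

For each gene and each pair of consecutive PMI intervals with at least five
samples on each side, a two-sided Wilcoxon rank-sum test compares the
expression values, and a fold change is computed as the log2 ratio of the
group medians on the positive scale (RPKM + pseudo-count). A (gene,
transition) event is called significant when p < 0.05 and the median fold
change exceeds 2-fold. The fold change is deliberately computed on the
positive scale rather than on z-scores (a ratio of z-score medians is
undefined when a median is negative); z-scores are used for reporting and
heatmaps only, and leave the rank-sum p-value unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .preprocess import INTERVAL_LABELS, assign_pmi_intervals

__all__ = [
    "interval_shift_test",
    "ranksum_pvalues",
    "temporal_de_scan",
    "recurrence_summary",
]

_EXACT_MAX_N = 25


def ranksum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, vectorized over rows.

    ``x`` and ``y`` are (k, n1) and (k, n2) arrays. The exact null
    distribution is used when both groups have at most 25 observations and
    the data carry no ties; otherwise the normal approximation with
    continuity and tie correction is used.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    n1, n2 = x.shape[1], y.shape[1]
    pooled = np.concatenate([x, y], axis=1)
    has_ties = any(len(np.unique(row)) < n1 + n2 for row in pooled)
    method = "exact" if (max(n1, n2) <= _EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, axis=1, method=method, alternative="two-sided")
    return np.minimum(np.atleast_1d(res.pvalue), 1.0)


def interval_shift_test(
    expr_i: np.ndarray, expr_j: np.ndarray
) -> tuple[float, float]:
    """Rank-sum p-value and positive-scale log2 fold change of medians.

    ``expr_i``/``expr_j`` must be on a positive scale (RPKM + pseudo-count)
    for the fold-change term. A zero median in the denominator yields a
    signed infinity.
    """
    expr_i = np.asarray(expr_i, float)
    expr_j = np.asarray(expr_j, float)
    p = float(ranksum_pvalues(expr_i, expr_j)[0])
    mi, mj = np.median(expr_i), np.median(expr_j)
    if mj == 0 or mi == 0:
        if mi == mj:
            fc = 0.0
        else:
            fc = np.inf if mi > mj else -np.inf
            warnings.warn("zero median in fold change; reporting signed infinity")
    else:
        fc = float(np.log2(mi / mj))
    return p, fc


def temporal_de_scan(
    mat: ExpressionMatrix,
    samples: pd.DataFrame,
    tissue: str,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Test every gene at every consecutive PMI interval transition.

    ``fc_threshold`` is on the ratio scale: a transition passes the
    fold-change gate when the positive-scale median ratio exceeds it
    (equivalently |log2 FC| > log2(fc_threshold)).

    Returns one row per tested (gene, transition) with the p-value, log2
    fold change, z-score medians of both intervals, group sizes and the
    joint significance call.
    """
    in_tissue = samples["tissue"] == tissue
    if not in_tissue.any():
        raise ValueError(f"tissue {tissue!r} not present")
    tsamples = samples.loc[in_tissue & ~samples["premortem"]]
    intervals = assign_pmi_intervals(tsamples)
    counts = intervals.value_counts()
    if (counts >= min_samples).sum() < 2:
        warnings.warn(f"tissue {tissue!r} has fewer than two populated intervals")
        return _empty_result()

    ids = intervals.index
    pos = mat.rpkm[ids].to_numpy() + mat.pseudo_count
    log = mat.log_rpkm[ids].to_numpy()
    mean = log.mean(axis=1, keepdims=True)
    sd = log.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (log - mean) / sd, 0.0)

    log2_gate = np.log2(fc_threshold)
    rows = []
    labels = np.asarray(intervals)
    for a, b in zip(INTERVAL_LABELS[:-1], INTERVAL_LABELS[1:]):
        ia = np.flatnonzero(labels == a)
        ib = np.flatnonzero(labels == b)
        if len(ia) < min_samples or len(ib) < min_samples:
            continue
        pvals = ranksum_pvalues(log[:, ia], log[:, ib])
        med_a = np.median(pos[:, ia], axis=1)
        med_b = np.median(pos[:, ib], axis=1)
        with np.errstate(divide="ignore"):
            fc = np.log2(med_a / med_b)
        z_med_a = np.median(z[:, ia], axis=1)
        z_med_b = np.median(z[:, ib], axis=1)
        sig = (pvals < p_threshold) & (np.abs(fc) > log2_gate)
        rows.append(
            pd.DataFrame(
                {
                    "gene": mat.gene_ids,
                    "tissue": tissue,
                    "transition": f"{a}->{b}",
                    "pvalue": pvals,
                    "fold_change_log2": fc,
                    "zscore_median_i": z_med_a,
                    "zscore_median_j": z_med_b,
                    "n_i": len(ia),
                    "n_j": len(ib),
                    "significant": sig,
                }
            )
        )
    if not rows:
        warnings.warn(f"no testable transitions in tissue {tissue!r}")
        return _empty_result()
    return pd.concat(rows, ignore_index=True)


def _empty_result() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "gene",
            "tissue",
            "transition",
            "pvalue",
            "fold_change_log2",
            "zscore_median_i",
            "zscore_median_j",
            "n_i",
            "n_j",
            "significant",
        ]
    )


def recurrence_summary(
    results: dict[str, pd.DataFrame], min_tissues: int = 1
) -> dict[str, set[str]]:
    """Map genes to the tissues where they are significant in >= 1 transition,
    keeping genes seen in at least ``min_tissues`` tissues."""
    hits: dict[str, set[str]] = {}
    for tissue, df in results.items():
        if df.empty:
            continue
        for gene in df.loc[df["significant"], "gene"].unique():
            hits.setdefault(gene, set()).add(tissue)
    return {g: t for g, t in hits.items() if len(t) >= min_tissues}
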
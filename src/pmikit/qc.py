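"""Sample-level QC: mitochondrial read fraction and 5'/3' coverage bias.

MT% is the fraction of reads in annotated mitochondrial genes over all
annotated reads; nMT% divides each sample's MT% by the median MT% of its
tissue, removing the large between-tissue differences in mitochondrial
activity. The 5'/3' coverage ratio is the mean per-base coverage over the
first 50 bases of a transcript divided by the mean over its last 50,
averaged over transcripts per sample (a ratio below 1 indicates the 3'
bias typical of degraded RNA).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import ExpressionMatrix
from .temporal import ranksum_pvalues

__all__ = ["mt_metrics", "nmt_pmi_slope", "coverage_bias_ratio"]


def mt_metrics(
    mat: ExpressionMatrix, mt_genes: list[str], samples: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample MT% and tissue-normalized nMT%."""
    mt_present = [g for g in mt_genes if g in mat.gene_ids]
    if not mt_present:
        raise ValueError("no mitochondrial genes present in the matrix")
    total = mat.counts.sum(axis=0).astype(float)
    mt = mat.counts.loc[mt_present].sum(axis=0).astype(float)
    frac = mt / total
    meta = samples.set_index("sample_id")
    out = pd.DataFrame(
        {
            "sample_id": frac.index,
            "tissue": meta.loc[frac.index, "tissue"].to_numpy(),
            "mt_fraction": frac.to_numpy(),
            "pmi_minutes": meta.loc[frac.index, "sample_pmi_minutes"].to_numpy(),
        }
    )
    med = out.groupby("tissue")["mt_fraction"].transform("median")
    if (med == 0).any():
        bad = sorted(out.loc[med == 0, "tissue"].unique())
        raise ValueError(f"tissue median MT% is zero for: {bad}")
    out["nmt"] = out["mt_fraction"] / med
    if "age" in meta.columns:
        out["age"] = meta.loc[out["sample_id"], "age"].to_numpy()
    return out


def nmt_pmi_slope(
    qc: pd.DataFrame,
    tissue: str,
    adjust_age: bool = False,
    split_minutes: float = 680.0,
    min_samples: int = 10,
) -> dict:
    """OLS slope of nMT% on PMI within one tissue, with CI and an
    early (<= split) vs late (> split) rank-sum comparison."""
    sub = qc.loc[(qc["tissue"] == tissue) & (qc["pmi_minutes"] >= 0)].copy()
    if len(sub) < min_samples:
        raise ValueError(f"fewer than {min_samples} samples in tissue {tissue!r}")
    X = sub[["pmi_minutes"]].to_numpy(float)
    if adjust_age:
        if "age" not in sub.columns:
            raise ValueError("age adjustment requested but no 'age' column")
        X = np.column_stack([X, sub["age"].to_numpy(float)])
    X = sm.add_constant(X)
    y = sub["nmt"].to_numpy(float)
    degenerate = np.std(y) == 0
    if degenerate:
        warnings.warn(f"constant nMT in tissue {tissue!r}; degenerate fit")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()[1]
    early = y[sub["pmi_minutes"].to_numpy() <= split_minutes]
    late = y[sub["pmi_minutes"].to_numpy() > split_minutes]
    split_p = (
        float(ranksum_pvalues(early, late)[0]) if len(early) and len(late) else np.nan
    )
    return {
        "tissue": tissue,
        "slope": float(fit.params[1]),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "pvalue": float(fit.pvalues[1]),
        "n": len(sub),
        "degenerate": bool(degenerate),
        "early_late_ranksum_p": split_p,
        "n_early": int(len(early)),
        "n_late": int(len(late)),
    }


def coverage_bias_ratio(
    coverage: dict[str, list[np.ndarray]],
    edge_bases: int = 50,
    min_transcript_bases: int = 100,
) -> pd.Series:
    """Per-sample mean of (mean coverage over first 50 bases) /
    (mean over last 50 bases) across usable transcripts.

    Transcripts shorter than ``min_transcript_bases`` or with zero 3'
    coverage are excluded; a sample with no usable transcripts gets NaN.
    """
    out = {}
    for sample, transcripts in coverage.items():
        ratios = []
        for cov in transcripts:
            cov = np.asarray(cov, float)
            if len(cov) < min_transcript_bases:
                continue
            head = cov[:edge_bases].mean()
            tail = cov[-edge_bases:].mean()
            if tail == 0:
                continue
            ratios.append(head / tail)
        if not ratios:
            warnings.warn(f"no usable transcripts for sample {sample!r}")
            out[sample] = np.nan
        else:
            out[sample] = float(np.mean(ratios))
    return pd.Series(out, name="cov_ratio_5p_3p")
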
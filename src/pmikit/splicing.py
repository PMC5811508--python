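"""Exon inclusion (PSI), isoform-usage entropy, and their PMI association.

PSI is computed from pre-aggregated inclusion/exclusion junction read
counts as inc / (inc + exc); a cell is missing when fewer than five total
reads support it. Exons are retained for analysis when they are missing in
less than 10% of samples, have a non-zero standard deviation, and span a
PSI range greater than 0.1.

Splicing entropy of a gene is the Shannon entropy (natural log) of its
isoform abundance ratios P(I_i) = I_i / sum(I), with 0*log(0) = 0; it is 0
when a single isoform dominates and log(k) when all k isoforms are equally
used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .temporal import ranksum_pvalues

__all__ = [
    "PsiTable",
    "build_psi_table",
    "psi_pmi_correlation",
    "blood_differential_inclusion",
    "shannon_entropy",
    "splicing_entropy_profile",
]

MIN_TOTAL_READS = 5


@dataclass
class PsiTable:
    """Exon inclusion levels (exons x samples) with their junction counts."""

    psi: pd.DataFrame
    inclusion: pd.DataFrame
    exclusion: pd.DataFrame
    gene_of_exon: pd.Series

    @property
    def exon_ids(self) -> pd.Index:
        return self.psi.index


def build_psi_table(
    junction_counts: pd.DataFrame,
    max_missing_fraction: float = 0.10,
    min_psi_range: float = 0.1,
) -> PsiTable:
    """Compute PSI from a long junction-count table and apply the exon filters.

    ``junction_counts`` columns: exon_id, gene_id, sample_id,
    inclusion_reads, exclusion_reads. An exon survives iff its missing
    fraction is below ``max_missing_fraction``, its PSI standard deviation
    is strictly positive, and max(PSI) - min(PSI) exceeds ``min_psi_range``.
    """
    inc = junction_counts.pivot_table(
        index="exon_id", columns="sample_id", values="inclusion_reads", aggfunc="sum"
    ).fillna(0.0)
    exc = junction_counts.pivot_table(
        index="exon_id", columns="sample_id", values="exclusion_reads", aggfunc="sum"
    ).reindex(index=inc.index, columns=inc.columns).fillna(0.0)
    total = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = inc / total
    psi = psi.where(total >= MIN_TOTAL_READS)

    present = psi.notna()
    dropped_absent = present.sum(axis=1) == 0
    if dropped_absent.any():
        psi = psi.loc[~dropped_absent]
    missing_frac = psi.isna().mean(axis=1)
    sd = psi.std(axis=1, ddof=1)
    rng_ = psi.max(axis=1) - psi.min(axis=1)
    keep = (missing_frac < max_missing_fraction) & (sd > 0) & (rng_ > min_psi_range)
    kept = psi.index[keep]
    gene_of_exon = (
        junction_counts.drop_duplicates("exon_id").set_index("exon_id")["gene_id"]
    )
    return PsiTable(
        psi=psi.loc[kept],
        inclusion=inc.loc[kept],
        exclusion=exc.loc[kept],
        gene_of_exon=gene_of_exon.reindex(kept),
    )


def psi_pmi_correlation(
    psi: PsiTable,
    samples: pd.DataFrame,
    r_threshold: float = 0.5,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Pearson correlation of each exon's PSI with sample PMI.

    Pairwise-complete samples per exon; BH adjustment across exons;
    significance by the joint |r| > r_threshold and FDR <= fdr_threshold
    rule. Exons with fewer than 3 defined samples are skipped.
    """
    pmi = samples.set_index("sample_id")["sample_pmi_minutes"]
    common = [s for s in psi.psi.columns if s in pmi.index]
    P = psi.psi[common]
    x = pmi[common].to_numpy(float)
    rows = []
    for exon, row in P.iterrows():
        mask = row.notna().to_numpy()
        if mask.sum() < 3:
            continue
        y = row.to_numpy(float)[mask]
        if np.std(y) == 0:
            r, p = np.nan, 1.0
        else:
            res = stats.pearsonr(y, x[mask])
            r, p = res.statistic, res.pvalue
        rows.append({"exon_id": exon, "gene_id": psi.gene_of_exon.get(exon),
                     "r": r, "pvalue": p, "n": int(mask.sum())})
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        out["significant"] = []
        return out
    out["fdr"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = (out["r"].abs() > r_threshold) & (out["fdr"] <= fdr_threshold)
    return out


def exon_recurrence(assoc: dict[str, pd.DataFrame], min_tissues: int = 3) -> dict[str, set[str]]:
    """Exons significantly PMI-correlated in at least ``min_tissues`` tissues."""
    hits: dict[str, set[str]] = {}
    for tissue, df in assoc.items():
        if df.empty:
            continue
        for exon in df.loc[df["significant"], "exon_id"]:
            hits.setdefault(exon, set()).add(tissue)
    return {e: t for e, t in hits.items() if len(t) >= min_tissues}


def blood_differential_inclusion(
    psi: PsiTable,
    samples: pd.DataFrame,
    fdr_threshold: float = 0.01,
    min_delta_psi: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Pre- vs post-mortem differential exon inclusion.

    Per retained exon: two-sided rank-sum test of PSI between the
    pre-mortem and post-mortem groups, BH adjustment, and
    delta PSI = median(post) - median(pre). An exon is significant when
    FDR < fdr_threshold and |delta PSI| > min_delta_psi. The summary
    reports the fraction of significant exons more included pre-mortem.
    """
    flags = samples.set_index("sample_id")["premortem"]
    common = [s for s in psi.psi.columns if s in flags.index]
    pre_ids = [s for s in common if flags[s]]
    post_ids = [s for s in common if not flags[s]]
    if not pre_ids or not post_ids:
        raise ValueError("both pre- and post-mortem samples are required")
    rows = []
    for exon, row in psi.psi[common].iterrows():
        pre = row[pre_ids].dropna().to_numpy(float)
        post = row[post_ids].dropna().to_numpy(float)
        if len(pre) == 0 or len(post) == 0:
            continue
        p = float(ranksum_pvalues(pre, post)[0])
        rows.append(
            {
                "exon_id": exon,
                "pvalue": p,
                "delta_psi": float(np.median(post) - np.median(pre)),
                "n_pre": len(pre),
                "n_post": len(post),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out, {"n_significant": 0, "fraction_more_included_premortem": np.nan}
    out["fdr"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = (out["fdr"] < fdr_threshold) & (
        out["delta_psi"].abs() > min_delta_psi
    )
    sig = out.loc[out["significant"]]
    frac_pre = float((sig["delta_psi"] < 0).mean()) if len(sig) else np.nan
    return out, {
        "n_significant": int(out["significant"].sum()),
        "fraction_more_included_premortem": frac_pre,
    }


def shannon_entropy(ratios: np.ndarray) -> float:
    """Shannon entropy (natural log) of a ratio vector; 0*log(0) = 0."""
    p = np.asarray(ratios, float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def splicing_entropy_profile(
    isoform_rpkm: pd.DataFrame,
    samples: pd.DataFrame,
    min_isoforms: int = 2,
    min_expressed_fraction: float = 0.9,
    r_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-sample splicing entropy and per-gene entropy-PMI correlation.

    ``isoform_rpkm`` is indexed by (gene_id, isoform_id). Genes enter the
    analysis when they have at least ``min_isoforms`` isoforms and non-zero
    total expression in at least ``min_expressed_fraction`` of the samples.
    Returns (entropy genes x samples, per-gene association table,
    major-isoform share genes x samples).
    """
    pmi = samples.set_index("sample_id")["sample_pmi_minutes"]
    common = [s for s in isoform_rpkm.columns if s in pmi.index]
    X = isoform_rpkm[common]
    ent_rows, major_rows, genes = [], [], []
    for gene, block in X.groupby(level="gene_id", sort=True):
        vals = block.to_numpy(float)
        if vals.shape[0] < min_isoforms:
            continue
        totals = vals.sum(axis=0)
        expressed = totals > 0
        if expressed.mean() < min_expressed_fraction:
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = vals / totals
        ent = np.full(len(common), np.nan)
        major = np.full(len(common), np.nan)
        for j in np.flatnonzero(expressed):
            ent[j] = shannon_entropy(ratios[:, j])
            major[j] = ratios[:, j].max()
        genes.append(gene)
        ent_rows.append(ent)
        major_rows.append(major)
    entropy = pd.DataFrame(ent_rows, index=genes, columns=common)
    major_share = pd.DataFrame(major_rows, index=genes, columns=common)

    x = pmi[common].to_numpy(float)
    rows = []
    for gene, row in entropy.iterrows():
        mask = row.notna().to_numpy()
        if mask.sum() < 3:
            continue
        y = row.to_numpy(float)[mask]
        if np.std(y) == 0:
            r, p = np.nan, 1.0
        else:
            res = stats.pearsonr(y, x[mask])
            r, p = res.statistic, res.pvalue
        rows.append({"gene_id": gene, "r": r, "pvalue": p, "n": int(mask.sum())})
    assoc = pd.DataFrame(rows)
    if not assoc.empty:
        assoc["fdr"] = multipletests(assoc["pvalue"].to_numpy(), method="fdr_bh")[1]
        assoc["significant"] = (assoc["r"].abs() > r_threshold) & (
            assoc["fdr"] < fdr_threshold
        )
    return entropy, assoc, major_share
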
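"""Core data containers for the PMI analysis pipeline.

The two central objects are :class:`ExpressionMatrix` (genes x samples, with
raw-count, RPKM and log2-RPKM layers) and the sample metadata table, a plain
:class:`pandas.DataFrame` with a fixed column contract validated by
:func:`validate_sample_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SAMPLE_TABLE_COLUMNS",
    "validate_sample_table",
    "read_sample_table",
    "write_sample_table",
]

#: Required columns of a sample metadata table. Additional columns are
#: treated as covariates (any name) and carried along untouched.
SAMPLE_TABLE_COLUMNS = (
    "sample_id",
    "donor_id",
    "tissue",
    "sample_pmi_minutes",
    "donor_pmi_minutes",
    "elapsed_minutes",
    "rin",
    "premortem",
    "hardy_class",
    "death_class",
)


def rpkm_from_counts(counts: pd.DataFrame, gene_lengths_bp: pd.Series) -> pd.DataFrame:
    """RPKM = 1e9 * count / (gene_length_bp * library_size).

    Library size is the per-sample total of the supplied counts.
    """
    lib = counts.sum(axis=0).astype(float)
    lengths = gene_lengths_bp.reindex(counts.index).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = counts.div(lib, axis=1).mul(1e9).div(lengths, axis=0)
    return out


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with raw-count, RPKM and log2 layers.

    ``log_rpkm`` is always ``log2(rpkm + pseudo_count)``; when a normalized
    log layer replaces it (quantile normalization), the RPKM identity no
    longer holds and ``normalized`` is set.
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    log_rpkm: pd.DataFrame
    gene_lengths_bp: pd.Series
    biotype: pd.Series
    pseudo_count: float = 1.0
    normalized: bool = False

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            raise ValueError("duplicated gene ids")
        if cols.has_duplicates:
            raise ValueError("duplicated sample ids")
        for name in ("rpkm", "log_rpkm"):
            layer = getattr(self, name)
            if not (layer.index.equals(idx) and layer.columns.equals(cols)):
                raise ValueError(f"layer {name!r} does not align with counts")
        self.gene_lengths_bp = self.gene_lengths_bp.reindex(idx)
        self.biotype = self.biotype.reindex(idx)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        gene_lengths_bp: pd.Series,
        biotype: pd.Series | None = None,
        pseudo_count: float = 1.0,
    ) -> "ExpressionMatrix":
        """Build all layers from raw counts and gene lengths."""
        counts = counts.astype(np.int64, copy=False)
        missing = gene_lengths_bp.reindex(counts.index).isna()
        if missing.any():
            dropped = counts.index[missing]
            warnings.warn(
                f"dropping {len(dropped)} genes without a gene length", stacklevel=2
            )
            counts = counts.loc[~missing.values]
        if biotype is None:
            biotype = pd.Series("protein_coding", index=counts.index)
        rpkm = rpkm_from_counts(counts, gene_lengths_bp)
        log_rpkm = np.log2(rpkm + pseudo_count)
        return cls(
            counts=counts,
            rpkm=rpkm,
            log_rpkm=log_rpkm,
            gene_lengths_bp=gene_lengths_bp.reindex(counts.index),
            biotype=biotype.reindex(counts.index),
            pseudo_count=pseudo_count,
        )

    # -- views ------------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        return replace(
            self,
            counts=self.counts.loc[genes],
            rpkm=self.rpkm.loc[genes],
            log_rpkm=self.log_rpkm.loc[genes],
            gene_lengths_bp=self.gene_lengths_bp.loc[genes],
            biotype=self.biotype.loc[genes],
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        return replace(
            self,
            counts=self.counts[samples],
            rpkm=self.rpkm[samples],
            log_rpkm=self.log_rpkm[samples],
        )

    def with_log_layer(self, log_rpkm: pd.DataFrame, normalized: bool = True) -> "ExpressionMatrix":
        return replace(self, log_rpkm=log_rpkm, normalized=normalized)

    # -- IO ---------------------------------------------------------------

    def write_tsv(self, directory: str | Path, prefix: str = "expression") -> None:
        """Write counts/rpkm layers and gene annotation as TSV files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(directory / f"{prefix}.counts.tsv", sep="\t", index_label="gene_id")
        self.rpkm.to_csv(directory / f"{prefix}.rpkm.tsv", sep="\t", index_label="gene_id")
        anno = pd.DataFrame(
            {"gene_length_bp": self.gene_lengths_bp, "biotype": self.biotype}
        )
        anno.to_csv(directory / f"{prefix}.genes.tsv", sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(
        cls, directory: str | Path, prefix: str = "expression", pseudo_count: float = 1.0
    ) -> "ExpressionMatrix":
        directory = Path(directory)
        counts = pd.read_csv(directory / f"{prefix}.counts.tsv", sep="\t", index_col="gene_id")
        anno = pd.read_csv(directory / f"{prefix}.genes.tsv", sep="\t", index_col="gene_id")
        return cls.from_counts(
            counts,
            anno["gene_length_bp"],
            anno["biotype"],
            pseudo_count=pseudo_count,
        )


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate the sample metadata contract and return the table.

    Checks the fixed columns, uniqueness of sample ids, the pre-mortem flag
    (premortem <=> sample PMI < 0) and, for post-mortem samples, that sample
    PMI is not below donor PMI (the collection procedure starts at the donor
    PMI, so tissue stabilization can only happen later).
    """
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicated sample ids in sample table")
    pmi = samples["sample_pmi_minutes"].to_numpy(float)
    if not np.isfinite(pmi).all():
        raise ValueError("non-finite sample PMI values")
    pre = samples["premortem"].to_numpy(bool)
    if not np.array_equal(pre, pmi < 0):
        raise ValueError("premortem flag inconsistent with negative sample PMI")
    post = samples.loc[~pre]
    bad = post["sample_pmi_minutes"] < post["donor_pmi_minutes"] - 1e-9
    if bad.any():
        raise ValueError(
            "post-mortem samples with sample PMI below donor PMI: "
            f"{post.loc[bad, 'sample_id'].tolist()[:5]}"
        )
    return samples


def covariate_columns(samples: pd.DataFrame) -> list[str]:
    """Columns beyond the fixed contract, treated as candidate covariates."""
    return [c for c in samples.columns if c not in SAMPLE_TABLE_COLUMNS]


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t")
    samples["premortem"] = samples["premortem"].astype(bool)
    return validate_sample_table(samples)
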
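"""Synthetic multi-tissue cohorts with known post-mortem interval structure.

The generator emulates the structure of a donor cohort in which every tissue
sample carries a cold-ischemia time (sample PMI, minutes): donors die with a
donor-level PMI, each collected tissue adds an elapsed processing delay, and
whole blood may additionally contain pre-mortem samples with negative PMI.
Planted features -- temporal trajectory classes, linear PMI-correlated
genes, covariates confounded with PMI, mitochondrial fractions with
tissue-specific PMI slopes, isoform ratios whose Shannon entropy drifts
with PMI, and exon inclusion levels linear in PMI -- are all recorded in a
:class:`SyntheticTruth` object so that every downstream stage has a
ground-truth recovery oracle.

Counts are drawn from a negative-binomial (gamma-Poisson) model on a
log2 link::

    log2 mu[g, s] = baseline[g] + signature[g, tissue(s)] + trajectory shift
                    + covariate loadings + beta[g] * latent(s) + noise

Trajectory classes are realized as piecewise shifts over the five PMI
intervals (early: step at the I1->I2 transition; sustained: an equal step at
every transition; peaked: a step up into I4 and back down into I5).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_sample_table

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_isoform_data",
    "write_cohort",
]

EFFECT_CLASSES = ("none", "early", "sustained", "peaked", "monotonic_linear")

#: Per-interval multiples of ``effect_size_log2`` for each trajectory class
#: over the five PMI intervals I1..I5.
_TRAJECTORY_OFFSETS = {
    "none": (0.0, 0.0, 0.0, 0.0, 0.0),
    "early": (0.0, 1.0, 1.0, 1.0, 1.0),
    "sustained": (0.0, 1.0, 2.0, 3.0, 4.0),
    "peaked": (0.0, 0.0, 0.0, 1.0, 0.0),
    "monotonic_linear": (0.0, 0.0, 0.0, 0.0, 0.0),  # handled continuously
}

_LN2_SQ = np.log(2.0) ** 2


class ConfigurationError(ValueError):
    """Raised when a SyntheticConfig violates its invariants."""


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic cohort. Same config + seed => identical cohort."""

    n_donors: int = 100
    #: tissue name -> probability that a donor contributes a sample.
    tissues: Mapping[str, float] = field(
        default_factory=lambda: {"muscle": 0.9, "lung": 0.85, "liver": 0.8, "blood": 0.9}
    )
    pmi_range_minutes: tuple[float, float] = (17.0, 1739.0)
    #: "uniform" draws donor PMI uniformly on pmi_range_minutes;
    #: "interval_balanced" first picks one of the five PMI intervals
    #: uniformly, then a time uniformly inside it (open-ended I5 capped at
    #: the range maximum) -- used for experiments that need comparable
    #: per-interval group sizes.
    pmi_distribution: str = "uniform"
    n_genes: int = 1000
    effect_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"none": 1.0}
    )
    effect_size_log2: float = 2.0
    #: restrict planted trajectory effects to these tissues (None = all).
    effect_tissues: list[str] | None = None
    n_covariates: int = 3
    covariate_pmi_confounding: float = 0.3
    #: per-gene loading scale of covariates on expression (log2 units).
    covariate_effect_log2: float = 0.3
    noise_dispersion: float = 0.05
    biological_noise_log2: float = 0.5
    #: squared correlation between the shared PMI latent and sample PMI;
    #: 1.0 means linear genes track PMI directly, lower values cap the
    #: variance of PMI explainable from expression.
    pmi_latent_r2: float = 1.0
    #: when set, monotonic_linear genes are planted at exactly this
    #: |correlation| with PMI (random sign); otherwise the planted shift is
    #: ``effect_size_log2`` per latent standard deviation.
    target_r: float | None = None
    n_isoform_genes: int = 0
    entropy_drift: float = 0.0
    entropy_drift_fraction: float = 0.5
    psi_assoc_fraction: float = 0.5
    psi_slope_per_minute: float = 3e-4
    psi_mean_total_reads: float = 40.0
    mt_slope_per_tissue: Mapping[str, float] = field(default_factory=dict)
    n_mt_genes: int = 5
    mt_base_fraction: float = 0.15
    premortem_blood_fraction: float = 0.0
    premortem_pmi_range: tuple[float, float] = (-1300.0, -20.0)
    elapsed_delay_range_minutes: tuple[float, float] = (10.0, 300.0)
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    tissue_signature_sd: float = 2.0
    protein_coding_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not self.tissues:
            raise ConfigurationError("tissue list is empty")
        fr = dict(self.effect_class_fractions)
        unknown = set(fr) - set(EFFECT_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown effect classes: {sorted(unknown)}")
        total = sum(fr.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ConfigurationError(f"effect_class_fractions sum to {total}, not 1")
        if any(v < 0 for v in fr.values()):
            raise ConfigurationError("negative effect class fraction")
        for name, rng_ in (
            ("pmi_range_minutes", self.pmi_range_minutes),
            ("elapsed_delay_range_minutes", self.elapsed_delay_range_minutes),
            ("premortem_pmi_range", self.premortem_pmi_range),
        ):
            lo, hi = rng_
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(f"{name} must be a finite (min, max) pair")
        if not 0.0 <= self.premortem_blood_fraction <= 1.0:
            raise ConfigurationError("premortem_blood_fraction outside [0, 1]")
        if not 0.0 <= self.covariate_pmi_confounding <= 1.0:
            raise ConfigurationError("covariate_pmi_confounding outside [0, 1]")
        if self.noise_dispersion < 0:
            raise ConfigurationError("noise_dispersion must be non-negative")
        if not 0.0 < self.pmi_latent_r2 <= 1.0:
            raise ConfigurationError("pmi_latent_r2 outside (0, 1]")
        if self.pmi_distribution not in ("uniform", "interval_balanced"):
            raise ConfigurationError("unknown pmi_distribution")
        if self.target_r is not None and self.target_r**2 >= self.pmi_latent_r2:
            raise ConfigurationError(
                "target_r^2 must be below pmi_latent_r2; the latent caps the "
                "achievable gene-PMI correlation"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic cohort."""

    gene_effect_class: pd.Series
    #: planted expression-PMI correlation after covariate confounding;
    #: 0 for 'none', NaN for trajectory classes (their association with PMI
    #: is deliberately non-linear).
    gene_true_r: pd.Series
    donor_pmi_minutes: pd.Series
    sample_elapsed_minutes: pd.Series
    effect_tissues: list[str]
    mt_genes: list[str] = field(default_factory=list)
    mt_slope_per_tissue: dict = field(default_factory=dict)
    exon_true_assoc: pd.Series | None = None
    exon_true_slope: pd.Series | None = None
    entropy_drift_genes: set = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_effect_class": self.gene_effect_class.to_dict(),
            "gene_true_r": {
                k: (None if pd.isna(v) else float(v))
                for k, v in self.gene_true_r.items()
            },
            "donor_pmi_minutes": self.donor_pmi_minutes.to_dict(),
            "sample_elapsed_minutes": self.sample_elapsed_minutes.to_dict(),
            "effect_tissues": list(self.effect_tissues),
            "mt_genes": list(self.mt_genes),
            "mt_slope_per_tissue": dict(self.mt_slope_per_tissue),
            "exon_true_assoc": None
            if self.exon_true_assoc is None
            else {k: bool(v) for k, v in self.exon_true_assoc.items()},
            "exon_true_slope": None
            if self.exon_true_slope is None
            else {k: float(v) for k, v in self.exon_true_slope.items()},
            "entropy_drift_genes": sorted(self.entropy_drift_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _draw_samples(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Donors, tissue retention, elapsed delays, covariates, metadata."""
    donors = [f"D{i:04d}" for i in range(config.n_donors)]
    lo, hi = config.pmi_range_minutes
    if config.pmi_distribution == "interval_balanced":
        edges = np.array([0.0, 60.0, 240.0, 360.0, 900.0, hi])
        edges[0] = max(lo, 0.0)
        which = rng.integers(0, 5, size=config.n_donors)
        donor_pmi = rng.uniform(edges[which], edges[which + 1])
    else:
        donor_pmi = rng.uniform(lo, hi, size=config.n_donors)
    hardy = rng.integers(1, 5, size=config.n_donors)
    death = rng.choice(
        ["cerebrovascular", "heart", "other"], size=config.n_donors, p=[0.3, 0.3, 0.4]
    )

    rows = []
    dlo, dhi = config.elapsed_delay_range_minutes
    for t_idx, (tissue, keep_p) in enumerate(config.tissues.items()):
        keep = rng.random(config.n_donors) < keep_p
        elapsed = rng.uniform(dlo, dhi, size=config.n_donors)
        for d_idx in np.flatnonzero(keep):
            rows.append(
                {
                    "sample_id": f"{donors[d_idx]}-{tissue}",
                    "donor_id": donors[d_idx],
                    "tissue": tissue,
                    "donor_pmi_minutes": donor_pmi[d_idx],
                    "elapsed_minutes": elapsed[d_idx],
                    "sample_pmi_minutes": donor_pmi[d_idx] + elapsed[d_idx],
                    "premortem": False,
                    "hardy_class": int(hardy[d_idx]),
                    "death_class": death[d_idx],
                }
            )
    samples = pd.DataFrame(rows)

    # pre-mortem whole-blood samples: negative PMI, no processing delay
    if config.premortem_blood_fraction > 0 and "blood" in config.tissues:
        blood = samples.index[samples["tissue"] == "blood"]
        n_pre = int(round(config.premortem_blood_fraction * len(blood)))
        pre_idx = rng.choice(blood, size=n_pre, replace=False)
        plo, phi = config.premortem_pmi_range
        samples.loc[pre_idx, "sample_pmi_minutes"] = rng.uniform(plo, phi, size=n_pre)
        samples.loc[pre_idx, "elapsed_minutes"] = 0.0
        samples.loc[pre_idx, "premortem"] = True

    samples["rin"] = np.clip(
        9.0 - 1.5e-3 * np.maximum(samples["sample_pmi_minutes"], 0.0)
        + rng.normal(0, 0.5, size=len(samples)),
        3.0,
        10.0,
    )

    # covariates partially confounded with PMI: rho * z(PMI) + sqrt(1-rho^2) * u
    z_pmi = _standardize(samples["sample_pmi_minutes"].to_numpy())
    rho = config.covariate_pmi_confounding
    for j in range(config.n_covariates):
        u = rng.normal(size=len(samples))
        samples[f"cov{j + 1}"] = rho * z_pmi + np.sqrt(1 - rho**2) * u
    return samples


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _interval_index(pmi: np.ndarray) -> np.ndarray:
    """0-based index of the five PMI intervals; pre-mortem times map to -1."""
    edges = np.array([0.0, 60.0, 240.0, 360.0, 900.0, np.inf])
    idx = np.searchsorted(edges, pmi, side="right") - 1
    idx[pmi < 0] = -1
    return idx


def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate an expression matrix, sample table and planted truth.

    The output is fully determined by ``config`` (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = _draw_samples(config, rng)
    n_samples = len(samples)
    pmi = samples["sample_pmi_minutes"].to_numpy()
    tissue_codes = pd.Categorical(
        samples["tissue"], categories=list(config.tissues)
    ).codes
    interval_idx = _interval_index(pmi)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_genes = config.n_genes

    classes = list(config.effect_class_fractions)
    probs = np.array([config.effect_class_fractions[c] for c in classes])
    gene_class = rng.choice(classes, size=n_genes, p=probs / probs.sum())

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    signature = rng.normal(0, config.tissue_signature_sd, (n_genes, len(config.tissues)))
    gene_lengths = rng.integers(500, 10000, size=n_genes)
    biotype = np.where(
        rng.random(n_genes) < config.protein_coding_fraction,
        "protein_coding",
        "lincRNA",
    )

    # covariate loadings (all genes; nulls pick up PMI-confounded covariate
    # signal, which the residualization stage must remove)
    cov_cols = [f"cov{j + 1}" for j in range(config.n_covariates)]
    C = samples[cov_cols].to_numpy() if cov_cols else np.empty((n_samples, 0))
    loadings = rng.normal(0, config.covariate_effect_log2, (n_genes, len(cov_cols)))

    # shared PMI latent: orthogonalize z(PMI) against the realized covariates
    # so the planted correlation survives residualization exactly, then mix
    # with a shared per-sample noise term capping the explainable variance.
    z = _standardize(pmi)
    if C.shape[1]:
        Caug = np.column_stack([np.ones(n_samples), C])
        beta_hat, *_ = np.linalg.lstsq(Caug, z, rcond=None)
        e = _standardize(z - Caug @ beta_hat)
    else:
        e = z
    eta = rng.normal(size=n_samples)
    r2 = config.pmi_latent_r2
    latent = np.sqrt(r2) * e + np.sqrt(1 - r2) * eta
    # the latent models a post-mortem process: pre-mortem samples carry no
    # time-to-death signal in their expression
    latent = np.where(pmi >= 0, latent, 0.0)

    # planted effect magnitudes
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    mu_bar = 2.0**baseline
    sigma_count2 = (config.noise_dispersion + 1.0 / np.maximum(mu_bar, 1.0)) / _LN2_SQ
    sigma_tot = np.sqrt(config.biological_noise_log2**2 + sigma_count2)
    is_linear = gene_class == "monotonic_linear"
    beta = np.zeros(n_genes)
    if config.target_r is not None:
        t = config.target_r
        beta[is_linear] = t * sigma_tot[is_linear] / np.sqrt(r2 - t**2)
    else:
        beta[is_linear] = config.effect_size_log2
    beta *= sign

    gene_true_r = np.zeros(n_genes)
    with np.errstate(invalid="ignore"):
        gene_true_r[is_linear] = (
            beta[is_linear]
            * np.sqrt(r2)
            / np.sqrt(beta[is_linear] ** 2 + sigma_tot[is_linear] ** 2)
        )
    gene_true_r[np.isin(gene_class, ["early", "sustained", "peaked"])] = np.nan

    # trajectory shifts per (gene, sample)
    effect_tissues = (
        list(config.tissues) if config.effect_tissues is None else list(config.effect_tissues)
    )
    in_effect_tissue = samples["tissue"].isin(effect_tissues).to_numpy()
    offsets = np.zeros((n_genes, n_samples))
    shift_lookup = np.zeros((len(EFFECT_CLASSES), 6))  # column 0 = pre-mortem
    for ci, cname in enumerate(EFFECT_CLASSES):
        shift_lookup[ci, 1:] = np.array(_TRAJECTORY_OFFSETS[cname]) * config.effect_size_log2
    class_idx = np.array([EFFECT_CLASSES.index(c) for c in gene_class])
    offsets = shift_lookup[class_idx][:, interval_idx + 1] * sign[:, None]
    offsets[:, ~in_effect_tissue] = 0.0

    log2_mu = (
        baseline[:, None]
        + signature[:, tissue_codes]
        + offsets
        + loadings @ C.T
        + beta[:, None] * latent[None, :]
        + rng.normal(0, config.biological_noise_log2, (n_genes, n_samples))
    )

    # mitochondrial genes: expected count share follows a tissue-specific
    # linear trend in PMI, via an odds factor against the nuclear total
    mt_genes: list[str] = []
    if config.mt_slope_per_tissue and config.n_mt_genes > 0:
        mt_genes = [f"MT{i:02d}" for i in range(config.n_mt_genes)]
        slopes = np.array(
            [config.mt_slope_per_tissue.get(t, 0.0) for t in config.tissues]
        )
        frac = np.clip(
            config.mt_base_fraction + slopes[tissue_codes] * np.maximum(pmi, 0.0),
            0.01,
            0.85,
        )
        nuclear_total = (2.0**log2_mu).sum(axis=0)
        mt_total = nuclear_total * frac / (1.0 - frac)
        split = rng.dirichlet(np.full(config.n_mt_genes, 20.0))
        mt_mu = split[:, None] * mt_total[None, :]
        log2_mu = np.vstack([log2_mu, np.log2(mt_mu)])
        genes = genes + mt_genes
        gene_lengths = np.concatenate([gene_lengths, rng.integers(500, 2000, len(mt_genes))])
        biotype = np.concatenate([biotype, ["Mt_rRNA"] * len(mt_genes)])
        gene_class = np.concatenate([gene_class, ["none"] * len(mt_genes)])
        gene_true_r = np.concatenate([gene_true_r, np.zeros(len(mt_genes))])

    counts = _negative_binomial(rng, 2.0**log2_mu, config.noise_dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples["sample_id"].to_numpy())

    mat = ExpressionMatrix.from_counts(
        counts_df,
        pd.Series(gene_lengths, index=genes),
        pd.Series(biotype, index=genes),
    )

    validate_sample_table(samples)
    truth = SyntheticTruth(
        gene_effect_class=pd.Series(gene_class, index=genes),
        gene_true_r=pd.Series(gene_true_r, index=genes),
        donor_pmi_minutes=pd.Series(
            samples.drop_duplicates("donor_id").set_index("donor_id")["donor_pmi_minutes"]
        ),
        sample_elapsed_minutes=pd.Series(
            samples.set_index("sample_id")["elapsed_minutes"]
        ),
        effect_tissues=effect_tissues,
        mt_genes=mt_genes,
        mt_slope_per_tissue=dict(config.mt_slope_per_tissue),
    )
    return mat, samples, truth


def generate_isoform_data(
    config: SyntheticConfig, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Isoform RPKMs and exon junction counts with planted PMI structure.

    Returns ``(isoform_rpkm, junction_counts, truth)`` where ``isoform_rpkm``
    is indexed by (gene_id, isoform_id) with samples in columns, and
    ``junction_counts`` is a long table with columns
    (exon_id, gene_id, sample_id, inclusion_reads, exclusion_reads).

    Genes in ``entropy_drift_genes`` have isoform ratios that mix toward
    the uniform distribution as PMI grows (concentration decreases, Shannon
    entropy rises); exons flagged in ``exon_true_assoc`` have inclusion
    levels linear in PMI with slope ``psi_slope_per_minute``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = config.n_isoform_genes
    sample_ids = samples["sample_id"].to_numpy()
    pmi = samples["sample_pmi_minutes"].to_numpy()
    n_samples = len(samples)

    truth = SyntheticTruth(
        gene_effect_class=pd.Series(dtype=object),
        gene_true_r=pd.Series(dtype=float),
        donor_pmi_minutes=pd.Series(
            samples.drop_duplicates("donor_id").set_index("donor_id")["donor_pmi_minutes"]
        ),
        sample_elapsed_minutes=pd.Series(samples.set_index("sample_id")["elapsed_minutes"]),
        effect_tissues=list(config.tissues),
    )

    if n == 0:
        iso = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["gene_id", "isoform_id"]),
            columns=sample_ids,
            dtype=float,
        )
        junc = pd.DataFrame(
            columns=["exon_id", "gene_id", "sample_id", "inclusion_reads", "exclusion_reads"]
        )
        truth.exon_true_assoc = pd.Series(dtype=bool)
        truth.exon_true_slope = pd.Series(dtype=float)
        return iso, junc, truth

    # --- isoform ratios ---------------------------------------------------
    drift_genes = set()
    pmi_pos = np.maximum(pmi, 0.0)
    lam_full = np.clip(config.entropy_drift * pmi_pos, 0.0, 1.0)
    rows, index = [], []
    for g in range(n):
        gene = f"ISO{g:04d}"
        k = int(rng.integers(2, 6))
        base = np.sort(rng.dirichlet(np.full(k, 3.0)))[::-1]
        drifts = config.entropy_drift != 0 and rng.random() < config.entropy_drift_fraction
        lam = lam_full if drifts else np.zeros(n_samples)
        if drifts:
            drift_genes.add(gene)
        # mix toward uniform with PMI, then multiplicative noise
        p = (1 - lam)[None, :] * base[:, None] + lam[None, :] / k
        p = p * np.exp(rng.normal(0, 0.15, (k, n_samples)))
        p /= p.sum(axis=0, keepdims=True)
        total = rng.lognormal(np.log(30.0), 0.4, n_samples)
        for i in range(k):
            rows.append(p[i] * total)
            index.append((gene, f"{gene}.{i + 1}"))
    iso = pd.DataFrame(
        np.array(rows),
        index=pd.MultiIndex.from_tuples(index, names=["gene_id", "isoform_id"]),
        columns=sample_ids,
    )
    truth.entropy_drift_genes = drift_genes

    # --- exon inclusion ---------------------------------------------------
    exon_ids, assoc_flags, slopes_out = [], [], []
    recs = []
    for g in range(n):
        exon = f"EX{g:04d}"
        gene = f"ISO{g:04d}"
        assoc = rng.random() < config.psi_assoc_fraction
        slope = config.psi_slope_per_minute * (1 if rng.random() < 0.5 else -1) if assoc else 0.0
        psi0 = rng.uniform(0.25, 0.7) if assoc else rng.uniform(0.1, 0.9)
        psi_true = np.clip(psi0 + slope * pmi_pos, 0.01, 0.99)
        total = rng.poisson(config.psi_mean_total_reads, n_samples)
        inc = rng.binomial(total, psi_true)
        exon_ids.append(exon)
        assoc_flags.append(assoc)
        slopes_out.append(slope)
        recs.append(
            pd.DataFrame(
                {
                    "exon_id": exon,
                    "gene_id": gene,
                    "sample_id": sample_ids,
                    "inclusion_reads": inc,
                    "exclusion_reads": total - inc,
                }
            )
        )
    junc = pd.concat(recs, ignore_index=True)
    truth.exon_true_assoc = pd.Series(assoc_flags, index=exon_ids)
    truth.exon_true_slope = pd.Series(slopes_out, index=exon_ids)
    return iso, junc, truth


def write_cohort(
    directory: str | Path,
    mat: ExpressionMatrix,
    samples: pd.DataFrame,
    truth: SyntheticTruth,
) -> None:
    """Write the cohort as TSV files plus a truth sidecar JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat.write_tsv(directory)
    samples.to_csv(directory / "samples.tsv", sep="\t", index=False)
    truth.to_json(directory / "truth.json")
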
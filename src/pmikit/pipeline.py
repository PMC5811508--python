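"""End-to-end pipeline wiring with deterministic seed derivation.

A run configuration (YAML or dict) names the stages to execute and their
parameters; stages run in dependency order, every stage draws its seed
deterministically from the master seed, and the run manifest records the
per-stage outputs and the SHA-256 of every table written, so two runs with
the same master seed produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from . import association, network, preprocess, qc, splicing, synthetic, temporal
from .containers import ExpressionMatrix, read_sample_table
from .predictor import PredictorConfig, run_prediction

__all__ = ["run_pipeline", "load_config"]

STAGE_ORDER = [
    "simulate",
    "preprocess",
    "temporal_de",
    "pmi_assoc",
    "modularity",
    "splicing",
    "qc",
    "predict",
]

_KNOWN_KEYS = {
    "stages",
    "output_dir",
    "master_seed",
    "simulate",
    "preprocess",
    "temporal_de",
    "pmi_assoc",
    "modularity",
    "splicing",
    "qc",
    "predict",
}


class PipelineError(RuntimeError):
    pass


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    _validate(config)
    return config


def _validate(config: dict) -> None:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise PipelineError(f"unknown configuration keys: {sorted(unknown)}")
    stages = config.get("stages", [])
    bad = [s for s in stages if s not in STAGE_ORDER]
    if bad:
        raise PipelineError(f"unknown stages: {bad}")
    if "output_dir" not in config:
        raise PipelineError("output_dir is required")
    for stage in stages:
        params = config.get(stage, {}) or {}
        if not isinstance(params, dict):
            raise PipelineError(f"stage {stage!r} parameters must be a mapping")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages; return the run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        _validate(config)
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("master_seed", 0))
    stages = sorted(config.get("stages", []), key=STAGE_ORDER.index)

    manifest: dict = {"master_seed": master_seed, "stages": []}
    state: dict = {}

    for stage in stages:
        params = dict(config.get(stage, {}) or {})
        seed = _stage_seed(master_seed, stage)
        try:
            outputs = _STAGE_FUNCS[stage](params, seed, outdir, state)
        except Exception as err:
            manifest["failed_stage"] = stage
            manifest["error"] = str(err)
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
            raise PipelineError(f"stage {stage!r} failed: {err}") from err
        manifest["stages"].append(
            {
                "name": stage,
                "seed": seed,
                "outputs": {name: _sha256(Path(p)) for name, p in outputs.items()},
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# --- stage implementations -------------------------------------------------


def _stage_simulate(params, seed, outdir, state):
    params.setdefault("seed", seed)
    cfg = synthetic.SyntheticConfig(**params)
    mat, samples, truth = synthetic.generate_cohort(cfg)
    synthetic.write_cohort(outdir / "cohort", mat, samples, truth)
    state["raw_mat"], state["samples"], state["truth"], state["config"] = mat, samples, truth, cfg
    base = outdir / "cohort"
    return {
        "counts": base / "expression.counts.tsv",
        "samples": base / "samples.tsv",
        "truth": base / "truth.json",
    }


def _require(state, key, stage):
    if key not in state:
        raise PipelineError(f"stage {stage!r} requires an earlier stage providing {key!r}")
    return state[key]


def _stage_preprocess(params, seed, outdir, state):
    if "counts_dir" in params:
        mat, samples = preprocess.load_and_normalize(
            params["counts_dir"], params["metadata_path"],
            pseudo_count=params.get("pseudo_count", 1.0),
        )
    else:
        mat = _require(state, "raw_mat", "preprocess")
        samples = _require(state, "samples", "preprocess")
        mat = preprocess.normalize_per_tissue(mat, samples)
    mat = preprocess.filter_genes(
        mat,
        min_reads=params.get("min_reads", 5),
        min_mean_rpkm=params.get("min_mean_rpkm", 0.0),
    )
    state["mat"], state["samples"] = mat, samples
    intervals = preprocess.assign_pmi_intervals(samples)
    path = outdir / "pmi_intervals.tsv"
    intervals.to_frame().to_csv(path, sep="\t", index_label="sample_id")
    return {"pmi_intervals": path}


def _stage_temporal_de(params, seed, outdir, state):
    mat = _require(state, "mat", "temporal_de")
    samples = state["samples"]
    tissues = params.get("tissues") or sorted(samples["tissue"].unique())
    results = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in tissues:
            results[t] = temporal.temporal_de_scan(
                mat, samples, t,
                p_threshold=params.get("p_threshold", 0.05),
                fc_threshold=params.get("fc_threshold", 2.0),
            )
    table = pd.concat(results.values(), ignore_index=True)
    path = outdir / "temporal_de.tsv"
    table.to_csv(path, sep="\t", index=False)
    state["temporal_de"] = results
    return {"temporal_de": path}


def _stage_pmi_assoc(params, seed, outdir, state):
    mat = _require(state, "mat", "pmi_assoc")
    samples = state["samples"]
    covariates = params.get("covariates", [c for c in samples.columns if c.startswith("cov")])
    tissues = params.get("tissues") or sorted(
        samples.loc[~samples["premortem"], "tissue"].unique()
    )
    assoc = {}
    for t in tissues:
        assoc[t] = association.pmi_correlation(
            mat, samples.loc[~samples["premortem"]], t,
            covariates=covariates,
            fdr_threshold=params.get("fdr_threshold", 0.01),
            min_mean_rpkm=params.get("min_mean_rpkm", 0.5),
        )
    table = pd.concat(assoc.values(), ignore_index=True)
    table["used_covariates"] = table["used_covariates"].map(lambda c: ",".join(c))
    path = outdir / "pmi_association.tsv"
    table.to_csv(path, sep="\t", index=False)
    outputs = {"pmi_association": path}
    if len(assoc) >= 2:
        sim, order, _ = association.tissue_similarity(assoc)
        sim_path = outdir / "tissue_similarity.tsv"
        sim.loc[order, order].to_csv(sim_path, sep="\t")
        outputs["tissue_similarity"] = sim_path
    state["assoc"] = assoc
    return outputs


def _stage_modularity(params, seed, outdir, state):
    mat = _require(state, "mat", "modularity")
    samples = state["samples"]
    bins = network.balanced_subsample(
        samples, min_per_bin=params.get("min_per_bin", 10), seed=seed
    )
    sweep = network.modularity_sweep(
        mat, bins, params.get("thresholds", [0.86, 0.88, 0.9, 0.92]), samples
    )
    path = outdir / "modularity_sweep.tsv"
    sweep.to_csv(path, sep="\t", index=False)
    return {"modularity_sweep": path}


def _stage_splicing(params, seed, outdir, state):
    samples = _require(state, "samples", "splicing")
    cfg = state.get("config")
    if cfg is None or cfg.n_isoform_genes == 0:
        raise PipelineError("splicing stage needs a simulate stage with n_isoform_genes > 0")
    iso, junc, truth = synthetic.generate_isoform_data(cfg, samples)
    psi = splicing.build_psi_table(junc)
    assoc = splicing.psi_pmi_correlation(psi, samples)
    entropy, ent_assoc, _ = splicing.splicing_entropy_profile(iso, samples)
    p1 = outdir / "psi_pmi_association.tsv"
    p2 = outdir / "entropy_pmi_association.tsv"
    assoc.to_csv(p1, sep="\t", index=False)
    ent_assoc.to_csv(p2, sep="\t", index=False)
    return {"psi_pmi_association": p1, "entropy_pmi_association": p2}


def _stage_qc(params, seed, outdir, state):
    mat = _require(state, "mat", "qc")
    samples = state["samples"]
    mt_genes = params.get("mt_genes")
    if mt_genes is None:
        truth = state.get("truth")
        mt_genes = truth.mt_genes if truth is not None else []
    if not mt_genes:
        raise PipelineError("qc stage needs mitochondrial gene ids")
    metrics = qc.mt_metrics(mat, mt_genes, samples)
    path = outdir / "qc_metrics.tsv"
    metrics.to_csv(path, sep="\t", index=False)
    return {"qc_metrics": path}


def _stage_predict(params, seed, outdir, state):
    mat = _require(state, "mat", "predict")
    samples = state["samples"]
    config = PredictorConfig.desk_scale() if params.get("desk_scale", True) else PredictorConfig()
    for key in ("ensemble_size", "r_min", "top_k_tissues", "max_genes"):
        if key in params:
            setattr(config, key, params[key])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = run_prediction(mat, samples, config, seed=seed)
    path = outdir / "pmi_predictions.tsv"
    res = out["results"].copy()
    res["tissue_set_used"] = res["tissue_set_used"].map(lambda c: ",".join(c))
    res.to_csv(path, sep="\t", index=False)
    state["prediction"] = out
    return {"pmi_predictions": path}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "temporal_de": _stage_temporal_de,
    "pmi_assoc": _stage_pmi_assoc,
    "modularity": _stage_modularity,
    "splicing": _stage_splicing,
    "qc": _stage_qc,
    "predict": _stage_predict,
}
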
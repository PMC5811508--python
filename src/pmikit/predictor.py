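"""Two-step PMI prediction from multi-tissue expression.

Step one fits, per tissue, an ensemble of gradient-boosted tree regressors
(one per seed; 13 by default) predicting the tissue sample's own PMI from
the expression of PMI-correlated protein-coding genes, with hyperparameters
chosen by repeated k-fold cross-validation over a grid (tree depth 4-6,
learning rate 0.001-0.1, gamma 0-0.15, up to 1000 rounds, RMSE criterion).
Step two corrects each tissue prediction to the donor level by subtracting
the elapsed time of the collection procedure for that tissue, and averages
the corrected predictions (over the top-k tissues by training R^2) into a
single individual PMI estimate, along with its coefficient of variation as
a stability measure.

All training decisions (gene prefiltering, cross-validation, grid search)
see only the training individuals; the split is at the individual level, so
no donor contributes samples to both sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import RepeatedKFold
from xgboost import XGBRegressor

from .containers import ExpressionMatrix

__all__ = [
    "PredictorConfig",
    "TissueModelBundle",
    "split_individuals",
    "prefilter_genes",
    "train_tissue_ensemble",
    "predict_and_correct",
    "aggregate_individual",
    "run_prediction",
    "subset_search",
    "negative_control",
    "stratified_eval",
    "regression_r2",
]


@dataclass
class PredictorConfig:
    """Training configuration; defaults follow the full-scale protocol."""

    ensemble_size: int = 13
    cv_repeats: int = 3
    cv_folds: int = 5
    depths: tuple[int, ...] = (4, 5, 6)
    etas: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1)
    gammas: tuple[float, ...] = (0.0, 0.05, 0.1, 0.15)
    max_rounds: int = 1000
    early_stopping_rounds: int = 20
    r_min: float = 0.4
    top_k_tissues: int = 20
    max_genes: int | None = None
    train_frac: float = 0.75
    importance_threshold: float = 0.1

    def grid(self) -> list[tuple[int, float, float]]:
        return list(product(self.depths, self.etas, self.gammas))

    @classmethod
    def desk_scale(cls) -> "PredictorConfig":
        """Reduced settings for desk-scale cohorts: 3-model ensembles, an
        8-point grid, single-repeat 3-fold CV, 300-round cap."""
        return cls(
            ensemble_size=3,
            cv_repeats=1,
            cv_folds=3,
            depths=(4, 6),
            etas=(0.05, 0.1),
            gammas=(0.0, 0.1),
            max_rounds=300,
            early_stopping_rounds=15,
            max_genes=50,
        )


@dataclass
class TissueModelBundle:
    """Fitted per-tissue ensemble with its selected genes and diagnostics."""

    tissue: str
    genes: list[str]
    models: list[XGBRegressor]
    seeds: list[int]
    best_params: list[dict]
    training_r2: float
    informative_genes: list[str] = field(default_factory=list)

    def raw_bytes(self) -> list[bytes]:
        """Serialized boosters, usable for bit-level identity checks."""
        return [bytes(m.get_booster().save_raw()) for m in self.models]


def regression_r2(real: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation of real vs predicted (regression R^2)."""
    real = np.asarray(real, float)
    predicted = np.asarray(predicted, float)
    if len(real) < 3 or np.std(real) == 0 or np.std(predicted) == 0:
        return 0.0
    return float(np.corrcoef(real, predicted)[0, 1] ** 2)


def split_individuals(
    samples: pd.DataFrame, train_frac: float = 0.75, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Individual-level train/test split stratified by tissue count.

    Donors are binned by quantiles of their number of available tissues and
    split within each bin, keeping the tissue-count distribution similar on
    both sides. No donor appears in both sets.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    counts = samples.groupby("donor_id")["tissue"].nunique().sort_index()
    if len(counts) < 8:
        raise ValueError("need at least 8 individuals to split")
    try:
        strata = pd.qcut(counts, q=min(4, counts.nunique()), duplicates="drop")
    except ValueError:
        strata = pd.Series(0, index=counts.index)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for _, group in counts.groupby(strata, observed=True):
        ids = group.index.to_numpy()
        rng.shuffle(ids)
        n_train = int(round(train_frac * len(ids)))
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return sorted(train), sorted(test)


def _tissue_samples(
    samples: pd.DataFrame, tissue: str, donors: list[str], premortem: bool = False
) -> pd.DataFrame:
    mask = (
        (samples["tissue"] == tissue)
        & samples["donor_id"].isin(donors)
        & (samples["premortem"] == premortem)
    )
    return samples.loc[mask].set_index("sample_id")


def prefilter_genes(
    mat: ExpressionMatrix,
    samples: pd.DataFrame,
    tissue: str,
    train_donors: list[str],
    r_min: float = 0.4,
    coding_only: bool = True,
    max_genes: int | None = None,
    target: pd.Series | None = None,
) -> list[str]:
    """Protein-coding genes with |Pearson r| >= r_min vs the tissue sample
    PMI, computed on training samples only.

    ``target`` overrides the per-sample regression target (used for the
    pre-mortem negative control, where the target is time to death).
    Absolute correlation is used: genes moving down with PMI are as
    informative as genes moving up.
    """
    sub = samples.loc[
        (samples["tissue"] == tissue) & samples["donor_id"].isin(train_donors)
    ].set_index("sample_id")
    if target is None:
        sub = sub.loc[~sub["premortem"]]
        y = sub["sample_pmi_minutes"]
    else:
        sub = sub.loc[sub.index.intersection(target.index)]
        y = target.loc[sub.index]
    ids = [s for s in sub.index if s in set(mat.sample_ids)]
    if len(ids) < 3:
        warnings.warn(f"tissue {tissue!r}: too few training samples to prefilter")
        return []
    genes = mat.gene_ids
    if coding_only:
        genes = genes[mat.biotype.loc[genes] == "protein_coding"]
    Y = mat.log_rpkm.loc[genes, ids].to_numpy(float)
    x = y.loc[ids].to_numpy(float)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / np.sqrt((Yc**2).sum(axis=1) * (xc**2).sum())
    r = np.nan_to_num(r)
    keep = np.abs(r) >= r_min
    selected = list(genes[keep])
    if not selected:
        warnings.warn(f"tissue {tissue!r}: no genes pass the |r| >= {r_min} prefilter")
        return []
    if max_genes is not None and len(selected) > max_genes:
        order = np.argsort(-np.abs(r[keep]))
        selected = [selected[i] for i in order[:max_genes]]
    return selected


def _make_model(depth: int, eta: float, gamma: float, rounds: int, seed: int,
                early_stopping: int | None = None) -> XGBRegressor:
    return XGBRegressor(
        max_depth=depth,
        learning_rate=eta,
        gamma=gamma,
        n_estimators=rounds,
        objective="reg:squarederror",
        eval_metric="rmse",
        early_stopping_rounds=early_stopping,
        n_jobs=1,
        random_state=seed,
        tree_method="hist",
        verbosity=0,
    )


def train_tissue_ensemble(
    mat: ExpressionMatrix,
    samples: pd.DataFrame,
    tissue: str,
    genes: list[str],
    train_donors: list[str],
    config: PredictorConfig,
    seed: int = 0,
    target: pd.Series | None = None,
    min_train_samples: int = 25,
) -> TissueModelBundle:
    """Grid-search and fit one boosted-tree ensemble for a tissue.

    For each ensemble seed, hyperparameters are chosen by repeated k-fold
    cross-validation minimizing RMSE (rounds via early stopping on the
    held-out fold); ties go to the least complex model (smallest depth,
    then fewest rounds). The winning configuration is refit on all
    training samples.
    """
    if not genes:
        raise ValueError(f"empty gene list for tissue {tissue!r}")
    sub = samples.loc[
        (samples["tissue"] == tissue) & samples["donor_id"].isin(train_donors)
    ].set_index("sample_id")
    if target is None:
        sub = sub.loc[~sub["premortem"]]
        y_all = sub["sample_pmi_minutes"]
    else:
        sub = sub.loc[sub.index.intersection(target.index)]
        y_all = target.loc[sub.index]
    ids = [s for s in sub.index if s in set(mat.sample_ids)]
    if len(ids) < min_train_samples:
        raise ValueError(
            f"tissue {tissue!r}: {len(ids)} training samples < {min_train_samples}"
        )
    X = mat.log_rpkm.loc[genes, ids].to_numpy(float).T
    y = y_all.loc[ids].to_numpy(float)
    if np.std(y) == 0:
        raise ValueError(f"tissue {tissue!r}: constant PMI target")

    ens_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 np.random.SeedSequence(seed).spawn(config.ensemble_size)]
    models, chosen = [], []
    for es in ens_seeds:
        cv = RepeatedKFold(
            n_splits=config.cv_folds, n_repeats=config.cv_repeats, random_state=es
        )
        best = None  # (rmse, depth, rounds, eta, gamma)
        for depth, eta, gamma in config.grid():
            rmses, iters = [], []
            for tr, va in cv.split(X):
                m = _make_model(
                    depth, eta, gamma, config.max_rounds, es,
                    early_stopping=config.early_stopping_rounds,
                )
                m.fit(X[tr], y[tr], eval_set=[(X[va], y[va])], verbose=False)
                rmses.append(m.best_score)
                iters.append(m.best_iteration + 1)
            key = (float(np.mean(rmses)), depth, int(round(np.mean(iters))))
            if best is None or key < (best[0], best[1], best[2]):
                best = (*key, eta, gamma)
        rmse, depth, rounds, eta, gamma = best
        final = _make_model(depth, eta, gamma, rounds, es)
        final.fit(X, y, verbose=False)
        models.append(final)
        chosen.append(
            {"depth": depth, "eta": eta, "gamma": gamma, "rounds": rounds,
             "cv_rmse": rmse, "seed": es}
        )

    train_pred = np.mean([m.predict(X) for m in models], axis=0)
    informative: set[str] = set()
    for m in models:
        imp = m.feature_importances_
        informative.update(g for g, v in zip(genes, imp) if v >= config.importance_threshold)
    return TissueModelBundle(
        tissue=tissue,
        genes=list(genes),
        models=models,
        seeds=ens_seeds,
        best_params=chosen,
        training_r2=regression_r2(y, train_pred),
        informative_genes=sorted(informative),
    )


def predict_and_correct(
    bundle: TissueModelBundle,
    mat: ExpressionMatrix,
    samples: pd.DataFrame,
    donors: list[str],
) -> pd.DataFrame:
    """Seed-averaged tissue PMI predictions, corrected by elapsed time.

    corrected = mean over seeds of the sample prediction, minus the
    sample's elapsed processing time; individuals without an elapsed time
    for this tissue are excluded with a warning.
    """
    sub = _tissue_samples(samples, bundle.tissue, donors)
    ids = [s for s in sub.index if s in set(mat.sample_ids)]
    if not ids:
        return pd.DataFrame(
            columns=["donor_id", "tissue", "sample_id", "prediction", "elapsed", "corrected"]
        )
    missing = sub.loc[ids, "elapsed_minutes"].isna()
    if missing.any():
        warnings.warn(
            f"tissue {bundle.tissue!r}: {missing.sum()} samples without elapsed time excluded"
        )
        ids = [s for s in ids if not missing[s]]
    X = mat.log_rpkm.loc[bundle.genes, ids].to_numpy(float).T
    preds = np.mean([m.predict(X) for m in bundle.models], axis=0)
    elapsed = sub.loc[ids, "elapsed_minutes"].to_numpy(float)
    return pd.DataFrame(
        {
            "donor_id": sub.loc[ids, "donor_id"].to_numpy(),
            "tissue": bundle.tissue,
            "sample_id": ids,
            "prediction": preds,
            "elapsed": elapsed,
            "corrected": preds - elapsed,
        }
    )


def aggregate_individual(
    corrected: pd.DataFrame,
    true_donor_pmi: pd.Series | None = None,
    tissue_set: list[str] | None = None,
) -> pd.DataFrame:
    """Average corrected tissue predictions into an individual PMI.

    ``tissue_set`` restricts aggregation (e.g. the top-k tissues by
    training R^2). Returns one row per individual with the mean prediction,
    the coefficient of variation of the corrected values, and the signed
    error (real - predicted) when the truth is supplied.
    """
    df = corrected
    if tissue_set is not None:
        df = df.loc[df["tissue"].isin(tissue_set)]
    rows = []
    for donor, grp in df.groupby("donor_id"):
        vals = grp["corrected"].to_numpy(float)
        mean = float(vals.mean())
        cv = float(vals.std(ddof=1) / mean) if len(vals) > 1 and mean != 0 else np.nan
        row = {
            "individual_id": donor,
            "individual_pmi_pred": mean,
            "cv": cv,
            "n_tissues": len(vals),
            "tissue_set_used": tuple(sorted(grp["tissue"])),
        }
        if true_donor_pmi is not None and donor in true_donor_pmi.index:
            real = float(true_donor_pmi[donor])
            row["real_pmi"] = real
            row["signed_error"] = real - mean
        rows.append(row)
    return pd.DataFrame(rows)


def run_prediction(
    mat: ExpressionMatrix,
    samples: pd.DataFrame,
    config: PredictorConfig | None = None,
    seed: int = 0,
    tissues: list[str] | None = None,
) -> dict:
    """End-to-end two-step prediction on one cohort.

    Splits individuals, trains a per-tissue ensemble on the training side,
    predicts and corrects on the test side, aggregates over the top-k
    tissues, and reports the test-set R^2 of real vs predicted donor PMI.
    """
    config = config or PredictorConfig()
    post = samples.loc[~samples["premortem"]]
    train_donors, test_donors = split_individuals(post, config.train_frac, seed)
    tissues = tissues or sorted(post["tissue"].unique())
    seed_seq = np.random.SeedSequence(seed).spawn(len(tissues))
    bundles: dict[str, TissueModelBundle] = {}
    corrected = []
    for tissue, ss in zip(tissues, seed_seq):
        tseed = int(ss.generate_state(1)[0] % (2**31))
        genes = prefilter_genes(
            mat, post, tissue, train_donors,
            r_min=config.r_min, max_genes=config.max_genes,
        )
        if not genes:
            warnings.warn(f"tissue {tissue!r} skipped: no prefiltered genes")
            continue
        try:
            bundle = train_tissue_ensemble(
                mat, post, tissue, genes, train_donors, config, seed=tseed
            )
        except ValueError as err:
            warnings.warn(f"tissue {tissue!r} skipped: {err}")
            continue
        bundles[tissue] = bundle
        corrected.append(predict_and_correct(bundle, mat, post, test_donors))
    if not bundles:
        raise ValueError("no tissue could be trained")
    corrected_df = pd.concat(corrected, ignore_index=True)
    ranked = sorted(bundles, key=lambda t: -bundles[t].training_r2)
    top = ranked[: config.top_k_tissues]
    truth = post.drop_duplicates("donor_id").set_index("donor_id")["donor_pmi_minutes"]
    results = aggregate_individual(corrected_df, truth, tissue_set=top)
    r2 = regression_r2(results["real_pmi"], results["individual_pmi_pred"]) if len(results) else 0.0
    return {
        "bundles": bundles,
        "corrected": corrected_df,
        "results": results,
        "train_donors": train_donors,
        "test_donors": test_donors,
        "top_tissues": top,
        "test_r2": r2,
    }


def subset_search(
    corrected: pd.DataFrame,
    true_donor_pmi: pd.Series,
    sizes: tuple[int, ...] = (2, 3, 4, 5, 6),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exhaustive search for the per-individual optimal tissue subsets.

    For every individual and subset size, enumerate all tissue combinations
    of that size among the individual's available tissues and keep the one
    minimizing |real - mean(corrected)|. Returns (per-size tissue frequency
    table, per-individual best-subset table). Sizes exceeding an
    individual's tissue count are skipped for that individual.
    """
    freq_rows, best_rows = [], []
    per_donor = {
        d: grp.set_index("tissue")["corrected"]
        for d, grp in corrected.groupby("donor_id")
        if d in true_donor_pmi.index
    }
    for size in sizes:
        tissue_hits: dict[str, int] = {}
        n_feasible = 0
        for donor, vals in per_donor.items():
            if len(vals) < size:
                continue
            n_feasible += 1
            real = float(true_donor_pmi[donor])
            best = min(
                combinations(vals.index, size),
                key=lambda c: abs(real - vals[list(c)].mean()),
            )
            best_rows.append(
                {
                    "individual_id": donor,
                    "size": size,
                    "tissues": tuple(sorted(best)),
                    "abs_error": abs(real - vals[list(best)].mean()),
                }
            )
            for t in best:
                tissue_hits[t] = tissue_hits.get(t, 0) + 1
        for t, c in tissue_hits.items():
            freq_rows.append(
                {"size": size, "tissue": t, "frequency": c / n_feasible, "n_individuals": n_feasible}
            )
    return pd.DataFrame(freq_rows), pd.DataFrame(best_rows)


def evaluate_tissue_subset(
    corrected: pd.DataFrame, true_donor_pmi: pd.Series, tissues: list[str]
) -> float:
    """R^2 of individual predictions aggregated over a fixed tissue subset."""
    res = aggregate_individual(corrected, true_donor_pmi, tissue_set=tissues)
    res = res.dropna(subset=["real_pmi"])
    return regression_r2(res["real_pmi"], res["individual_pmi_pred"])


def _single_tissue_r2(
    mat: ExpressionMatrix,
    samples: pd.DataFrame,
    target: pd.Series,
    config: PredictorConfig,
    seed: int,
    tissue: str,
) -> float:
    """Train/test R^2 for one tissue with an explicit per-sample target."""
    train_donors, test_donors = split_individuals(samples, config.train_frac, seed)
    genes = prefilter_genes(
        mat, samples, tissue, train_donors,
        r_min=config.r_min, max_genes=config.max_genes, target=target,
    )
    if not genes:
        return 0.0
    bundle = train_tissue_ensemble(
        mat, samples, tissue, genes, train_donors, config,
        seed=seed, target=target, min_train_samples=15,
    )
    test_ids = [
        s for s in samples.loc[
            (samples["tissue"] == tissue) & samples["donor_id"].isin(test_donors),
            "sample_id",
        ]
        if s in target.index and s in set(mat.sample_ids)
    ]
    X = mat.log_rpkm.loc[bundle.genes, test_ids].to_numpy(float).T
    preds = np.mean([m.predict(X) for m in bundle.models], axis=0)
    return regression_r2(target.loc[test_ids], preds)


def negative_control(
    mat: ExpressionMatrix,
    samples: pd.DataFrame,
    n_repeats: int = 20,
    config: PredictorConfig | None = None,
    seed: int = 0,
    tissue: str = "blood",
    min_premortem: int = 20,
) -> dict:
    """Pre-mortem overfitting control with a post-mortem companion run.

    Pre-mortem blood samples carry no post-mortem signal; if the pipeline
    could predict their time to death (|negative PMI|) this would indicate
    overfitting. The full train/test procedure is repeated ``n_repeats``
    times with fresh partitions on (a) pre-mortem samples, target = time to
    death, and (b) post-mortem samples, target = sample PMI.
    """
    config = config or PredictorConfig.desk_scale()
    pre = samples.loc[samples["premortem"] & (samples["tissue"] == tissue)]
    post = samples.loc[~samples["premortem"] & (samples["tissue"] == tissue)]
    if len(pre) < min_premortem:
        raise ValueError(f"only {len(pre)} pre-mortem samples; need {min_premortem}")
    pre_target = -pre.set_index("sample_id")["sample_pmi_minutes"]
    post_target = post.set_index("sample_id")["sample_pmi_minutes"]
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(seed).spawn(n_repeats)]
    pre_r2, post_r2 = [], []
    for s in seeds:
        pre_r2.append(_single_tissue_r2(mat, pre, pre_target, config, s, tissue))
        post_r2.append(_single_tissue_r2(mat, post, post_target, config, s, tissue))
    return {
        "premortem_r2": pre_r2,
        "postmortem_r2": post_r2,
        "premortem_median": float(np.median(pre_r2)),
        "postmortem_median": float(np.median(post_r2)),
    }


def stratified_eval(
    results: pd.DataFrame, death_class: pd.Series, min_per_class: int = 5
) -> pd.DataFrame:
    """Per-death-class R^2 of real vs predicted individual PMI."""
    df = results.dropna(subset=["real_pmi"]).copy()
    df["death_class"] = death_class.reindex(df["individual_id"]).to_numpy()
    rows = []
    for cls, grp in df.groupby("death_class"):
        rows.append(
            {
                "death_class": cls,
                "n": len(grp),
                "r2": regression_r2(grp["real_pmi"], grp["individual_pmi_pred"]),
                "low_n": len(grp) < min_per_class,
            }
        )
    return pd.DataFrame(rows)
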
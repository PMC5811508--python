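"""Two-step PMI predictor: splitting, prefiltering, training, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmikit import (
    PredictorConfig,
    SyntheticConfig,
    aggregate_individual,
    generate_cohort,
    predict_and_correct,
    prefilter_genes,
    split_individuals,
    stratified_eval,
    subset_search,
    train_tissue_ensemble,
)
from pmikit.predictor import TissueModelBundle, evaluate_tissue_subset, regression_r2, _single_tissue_r2
from pmikit.preprocess import normalize_per_tissue

from conftest import make_matrix, make_samples

FAST = PredictorConfig(
    ensemble_size=2, cv_repeats=1, cv_folds=3, depths=(4,), etas=(0.1,),
    gammas=(0.0,), max_rounds=120, early_stopping_rounds=10, max_genes=25,
)


@pytest.fixture(scope="module")
def predict_cohort():
    cfg = SyntheticConfig(
        n_donors=90, tissues={"t0": 0.9, "t1": 0.9},
        n_genes=300, effect_class_fractions={"none": 0.8, "monotonic_linear": 0.2},
        effect_size_log2=1.0, pmi_latent_r2=0.7, n_covariates=0,
        protein_coding_fraction=1.0, seed=23,
    )
    mat, samples, truth = generate_cohort(cfg)
    return normalize_per_tissue(mat, samples), samples, truth


class TestSplit:
    def test_75_25_split(self):
        samples = make_samples(100)
        train, test = split_individuals(samples, 0.75, seed=0)
        assert len(train) == 75 and len(test) == 25
        assert not set(train) & set(test)

    def test_same_seed_identical(self):
        samples = make_samples(60)
        assert split_individuals(samples, 0.75, 3) == split_individuals(samples, 0.75, 3)

    def test_stratification_keeps_tissue_count_distribution(self):
        """Across 100 seeds, train/test tissue counts should be rank-sum
        compatible (p > 0.05) in at least 90 cases."""
        rng = np.random.default_rng(0)
        rows = []
        for d in range(120):
            k = int(rng.integers(1, 9))
            for t in range(k):
                rows.append((f"x{d}_{t}", f"d{d}", f"tis{t}"))
        samples = make_samples(len(rows))
        samples["sample_id"] = [r[0] for r in rows]
        samples["donor_id"] = [r[1] for r in rows]
        samples["tissue"] = [r[2] for r in rows]
        counts = samples.groupby("donor_id")["tissue"].nunique()
        ok = 0
        for seed in range(100):
            train, test = split_individuals(samples, 0.75, seed)
            p = stats.ranksums(counts[train], counts[test]).pvalue
            ok += p > 0.05
        assert ok >= 90

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_individuals(make_samples(20), 1.2, 0)


class TestPrefilter:
    def test_linear_gene_retained(self, predict_cohort):
        mat, samples, truth = predict_cohort
        train, _ = split_individuals(samples, 0.75, 0)
        genes = prefilter_genes(mat, samples, "t0", train, r_min=0.3)
        lin = set(truth.gene_effect_class[truth.gene_effect_class == "monotonic_linear"].index)
        assert len(set(genes) & lin) / len(lin) > 0.8

    def test_planted_genes_recovered_at_spec_threshold(self):
        """50 genes planted at |r| ~ 0.55 among 2000: >= 45 retained at
        r_min = 0.4 with ~100 training samples."""
        cfg = SyntheticConfig(
            n_donors=135, tissues={"t0": 1.0}, n_genes=2000,
            effect_class_fractions={"none": 0.975, "monotonic_linear": 0.025},
            target_r=0.55, n_covariates=0, protein_coding_fraction=1.0, seed=29,
        )
        mat, samples, truth = generate_cohort(cfg)
        mat = normalize_per_tissue(mat, samples)
        train, _ = split_individuals(samples, 0.75, 1)
        genes = prefilter_genes(mat, samples, "t0", train, r_min=0.4)
        lin = truth.gene_effect_class[truth.gene_effect_class == "monotonic_linear"].index
        assert len(lin) in range(40, 61)
        assert len(set(genes) & set(lin)) >= 0.9 * len(lin)

    def test_non_coding_genes_excluded(self, predict_cohort):
        mat, samples, _ = predict_cohort
        train, _ = split_individuals(samples, 0.75, 0)
        genes = prefilter_genes(mat, samples, "t0", train, r_min=0.0)
        assert set(mat.biotype.loc[genes]) == {"protein_coding"}

    def test_test_set_pmi_never_read(self, predict_cohort):
        """Scrambling test-set PMI leaves the prefiltered gene list identical."""
        mat, samples, _ = predict_cohort
        train, test = split_individuals(samples, 0.75, 0)
        genes_a = prefilter_genes(mat, samples, "t0", train, r_min=0.3)
        scrambled = samples.copy()
        mask = scrambled["donor_id"].isin(test)
        scrambled.loc[mask, "sample_pmi_minutes"] = 99999.0
        genes_b = prefilter_genes(mat, scrambled, "t0", train, r_min=0.3)
        assert genes_a == genes_b


class TestTraining:
    def test_noiseless_linear_target_high_training_r2(self):
        n = 60
        samples = make_samples(n, donor_ids=[f"d{i}" for i in range(n)])
        pmi = samples["sample_pmi_minutes"].to_numpy()
        rng = np.random.default_rng(0)
        mat = make_matrix(rng.integers(10, 100, (5, n)))
        log = mat.log_rpkm.copy()
        log.loc["g0"] = pmi / 100.0
        mat = mat.with_log_layer(log)
        bundle = train_tissue_ensemble(
            mat, samples, "muscle", ["g0", "g1"], list(samples["donor_id"]),
            FAST, seed=5,
        )
        assert bundle.training_r2 >= 0.99
        assert len(bundle.models) == FAST.ensemble_size
        for p in bundle.best_params:
            assert p["depth"] in FAST.depths and p["rounds"] <= FAST.max_rounds

    def test_trained_bundles_bit_identical_under_test_scramble(self, predict_cohort):
        """Leakage guard: scrambling test-individual PMI must leave the
        fitted boosters byte-identical."""
        mat, samples, _ = predict_cohort
        train, test = split_individuals(samples, 0.75, 0)
        genes = prefilter_genes(mat, samples, "t0", train, r_min=0.3, max_genes=20)
        b1 = train_tissue_ensemble(mat, samples, "t0", genes, train, FAST, seed=7)
        scrambled = samples.copy()
        mask = scrambled["donor_id"].isin(test)
        scrambled.loc[mask, "sample_pmi_minutes"] = 123456.0
        b2 = train_tissue_ensemble(mat, scrambled, "t0", genes, train, FAST, seed=7)
        assert b1.raw_bytes() == b2.raw_bytes()

    def test_constant_target_errors(self):
        n = 30
        samples = make_samples(n, pmi=np.full(n, 500.0))
        mat = make_matrix(np.random.default_rng(1).integers(10, 100, (3, n)))
        with pytest.raises(ValueError, match="constant"):
            train_tissue_ensemble(mat, samples, "muscle", ["g0"],
                                  list(samples["donor_id"]), FAST)


class _Oracle:
    """Duck-typed regressor predicting the first feature column (scaled)."""

    def __init__(self, scale):
        self.scale = scale

    def predict(self, X):
        return X[:, 0] * self.scale


def _oracle_bundle(tissue, genes, scale=1.0):
    return TissueModelBundle(
        tissue=tissue, genes=genes, models=[_Oracle(scale)] * 3,
        seeds=[0, 1, 2], best_params=[], training_r2=1.0,
    )


class TestPredictAndAggregate:
    def test_identical_models_average_to_single_prediction(self):
        n = 10
        samples = make_samples(n)
        mat = make_matrix(np.random.default_rng(2).integers(10, 100, (2, n)))
        bundle = _oracle_bundle("muscle", ["g0", "g1"], scale=100.0)
        out = predict_and_correct(bundle, mat, samples, list(samples["donor_id"]))
        single = mat.log_rpkm.loc["g0", out["sample_id"]].to_numpy() * 100.0
        np.testing.assert_allclose(out["prediction"], single)
        np.testing.assert_allclose(out["corrected"], single - out["elapsed"])

    def test_oracle_models_give_exactly_zero_individual_error(self):
        """Perfect tissue predictors + arbitrary elapsed times: individual
        prediction equals the donor PMI exactly."""
        rng = np.random.default_rng(3)
        n_donors = 12
        rows = []
        for d in range(n_donors):
            donor_pmi = rng.uniform(100, 1200)
            for t, elapsed in zip("abc", rng.uniform(5, 400, 3)):
                rows.append((f"s{d}{t}", f"d{d}", t, donor_pmi, elapsed))
        samples = make_samples(len(rows))
        samples["sample_id"] = [r[0] for r in rows]
        samples["donor_id"] = [r[1] for r in rows]
        samples["tissue"] = [r[2] for r in rows]
        samples["donor_pmi_minutes"] = [r[3] for r in rows]
        samples["elapsed_minutes"] = [r[4] for r in rows]
        samples["sample_pmi_minutes"] = samples["donor_pmi_minutes"] + samples["elapsed_minutes"]
        mat = make_matrix(
            np.ones((2, len(rows)), int), sample_ids=list(samples["sample_id"])
        )
        log = mat.log_rpkm.copy()
        log.loc["g0"] = samples.set_index("sample_id")["sample_pmi_minutes"]
        mat = mat.with_log_layer(log)
        corrected = pd.concat(
            [predict_and_correct(_oracle_bundle(t, ["g0", "g1"]), mat, samples,
                                 list(samples["donor_id"].unique()))
             for t in "abc"],
            ignore_index=True,
        )
        truth = samples.drop_duplicates("donor_id").set_index("donor_id")["donor_pmi_minutes"]
        res = aggregate_individual(corrected, truth)
        np.testing.assert_allclose(res["signed_error"], 0.0, atol=1e-9)
        np.testing.assert_allclose(res["cv"], 0.0, atol=1e-12)

    def test_cv_arithmetic(self):
        corrected = pd.DataFrame(
            {"donor_id": ["d"] * 2, "tissue": ["a", "b"],
             "sample_id": ["s1", "s2"], "prediction": [450.0, 650.0],
             "elapsed": [50.0, 50.0], "corrected": [400.0, 600.0]}
        )
        res = aggregate_individual(corrected)
        assert res.loc[0, "individual_pmi_pred"] == pytest.approx(500.0)
        assert res.loc[0, "cv"] == pytest.approx(np.sqrt(2) * 100 / 500, rel=1e-9)  # ~0.283


class TestSubsetSearch:
    @staticmethod
    def _corrected(errors_by_donor, real=500.0):
        rows = []
        for donor, errs in errors_by_donor.items():
            for t, e in errs.items():
                rows.append((donor, t, f"{donor}{t}", real - e))
        df = pd.DataFrame(rows, columns=["donor_id", "tissue", "sample_id", "corrected"])
        return df, pd.Series(real, index=list(errors_by_donor))

    def test_known_optimal_pair(self):
        corrected, truth = self._corrected({"d1": {"A": 10.0, "B": -10.0, "C": 200.0}})
        freq, best = subset_search(corrected, truth, sizes=(2,))
        assert best.loc[0, "tissues"] == ("A", "B")
        assert best.loc[0, "abs_error"] == pytest.approx(0.0)

    def test_five_tissue_hand_computed(self):
        errs = {"d1": {"A": 5.0, "B": -5.0, "C": 100.0, "D": 120.0, "E": -90.0}}
        corrected, truth = self._corrected(errs)
        freq, best = subset_search(corrected, truth, sizes=(2, 3, 5))
        b = best.set_index("size")
        assert b.loc[2, "tissues"] == ("A", "B")  # mean error 0
        # size 3: best triple is {C, D, E} (mean error (100+120-90)/3 ~ 43.3)?
        # enumerate by hand: {A,B,E}: -30; {A,B,C}: 33.3; {A,B,D}: 40;
        # {A,C,E}: 5; {B,C,E}: 1.67; {A,D,E}: 11.7; {B,D,E}: 8.3;
        # {C,D,E}: 43.3; {A,C,D}: 75; {B,C,D}: 71.7 -> best {B,C,E}
        assert b.loc[3, "tissues"] == ("B", "C", "E")
        assert b.loc[5, "tissues"] == tuple("ABCDE")  # single combination

    def test_uniformly_best_tissue_dominates_optimal_subsets(self):
        # other tissues overestimate with a one-sided bias so their errors
        # cannot cancel; the accurate tissue must join every optimal subset
        rng = np.random.default_rng(4)
        errors = {}
        for d in range(40):
            errs = {t: rng.uniform(100, 300) for t in "ABCDE"}
            errs["best"] = rng.normal(0, 1)
            errors[f"d{d}"] = errs
        corrected, truth = self._corrected(errors)
        freq, _ = subset_search(corrected, truth, sizes=(2, 3, 4))
        f = freq.set_index(["size", "tissue"])
        for size in (2, 3, 4):
            assert f.loc[(size, "best"), "frequency"] >= 0.9

    def test_oversized_subsets_skipped(self):
        corrected, truth = self._corrected({"d1": {"A": 1.0, "B": 2.0}})
        freq, best = subset_search(corrected, truth, sizes=(2, 4))
        assert set(best["size"]) == {2}


class TestStratifiedEval:
    def test_identical_predictions_identical_r2(self):
        rng = np.random.default_rng(5)
        real = rng.uniform(100, 1000, 60)
        pred = real + rng.normal(0, 100, 60)
        res = pd.DataFrame(
            {"individual_id": [f"d{i}" for i in range(60)],
             "individual_pmi_pred": np.r_[pred, pred][:60],
             "real_pmi": real}
        )
        classes = pd.Series(["heart"] * 30 + ["other"] * 30,
                            index=[f"d{i}" for i in range(60)])
        # same generative process in both classes: R2 within sampling error
        out = stratified_eval(res, classes).set_index("death_class")
        assert abs(out.loc["heart", "r2"] - out.loc["other", "r2"]) < 0.25
        assert not out["low_n"].any()

    def test_small_class_flagged(self):
        res = pd.DataFrame(
            {"individual_id": ["a", "b", "c"],
             "individual_pmi_pred": [1.0, 2.0, 3.0], "real_pmi": [1.0, 2.0, 3.0]}
        )
        classes = pd.Series(["x", "x", "y"], index=["a", "b", "c"])
        out = stratified_eval(res, classes).set_index("death_class")
        assert out["low_n"].all()


class TestStability:
    def test_test_r2_iqr_small_over_repartitions(self):
        """Over 50 train/test repartitions of a fixed cohort, the test R^2
        interquartile range stays below 0.2."""
        cfg = SyntheticConfig(
            n_donors=90, tissues={"t0": 1.0}, n_genes=250,
            effect_class_fractions={"none": 0.8, "monotonic_linear": 0.2},
            effect_size_log2=1.0, pmi_latent_r2=0.7, n_covariates=0, seed=41,
        )
        mat, samples, _ = generate_cohort(cfg)
        mat = normalize_per_tissue(mat, samples)
        target = samples.set_index("sample_id")["sample_pmi_minutes"]
        r2 = [
            _single_tissue_r2(mat, samples, target, FAST, seed, "t0")
            for seed in range(50)
        ]
        q1, q3 = np.percentile(r2, [25, 75])
        assert q3 - q1 < 0.2
        assert np.median(r2) > 0.3


def test_alternate_feature_matrix_contract(predict_cohort):
    """The pipeline accepts any per-gene per-sample feature matrix (e.g.
    transcript-integrity scores) in place of expression: only the input
    matrix changes."""
    mat, samples, _ = predict_cohort
    rng = np.random.default_rng(9)
    pmi = samples.set_index("sample_id")["sample_pmi_minutes"]
    tin = pd.DataFrame(
        rng.normal(70, 5, mat.log_rpkm.shape),
        index=mat.gene_ids, columns=mat.sample_ids,
    )
    tin.loc[mat.gene_ids[0]] = 80 - pmi[mat.sample_ids].to_numpy() / 100.0
    tin_mat = mat.with_log_layer(tin)
    train, test = split_individuals(samples, 0.75, 0)
    genes = prefilter_genes(tin_mat, samples, "t0", train, r_min=0.4)
    assert mat.gene_ids[0] in genes
    bundle = train_tissue_ensemble(tin_mat, samples, "t0", genes, train, FAST, seed=1)
    out = predict_and_correct(bundle, tin_mat, samples, test)
    assert len(out) > 0 and out["prediction"].notna().all()
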
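"""PSI computation and filters, inclusion tests, splicing entropy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pmikit import (
    blood_differential_inclusion,
    build_psi_table,
    psi_pmi_correlation,
    shannon_entropy,
    splicing_entropy_profile,
)
from pmikit.synthetic import SyntheticConfig, generate_cohort, generate_isoform_data

from conftest import make_samples


def long_table(inc: np.ndarray, exc: np.ndarray, exons=None, samples=None):
    exons = exons or [f"e{i}" for i in range(inc.shape[0])]
    samples = samples or [f"s{j}" for j in range(inc.shape[1])]
    rows = []
    for i, e in enumerate(exons):
        for j, s in enumerate(samples):
            rows.append((e, f"gene_{e}", s, int(inc[i, j]), int(exc[i, j])))
    return pd.DataFrame(
        rows, columns=["exon_id", "gene_id", "sample_id", "inclusion_reads", "exclusion_reads"]
    )


class TestBuildPsi:
    def test_psi_ratio_convention(self):
        junc = long_table(np.full((1, 20), 8), np.full((1, 20), 2))
        junc.loc[0, "inclusion_reads"] = 9  # break sd=0 / range filters
        psi = build_psi_table(junc, min_psi_range=0.0)
        assert psi.psi.iloc[0, 1] == pytest.approx(0.8)

    def test_low_coverage_cell_is_missing(self):
        inc = np.full((1, 30), 8)
        exc = np.full((1, 30), 2)
        inc[0, 0], exc[0, 0] = 3, 1  # total 4 < 5
        inc[0, 1] = 10
        psi = build_psi_table(long_table(inc, exc), min_psi_range=0.0)
        assert np.isnan(psi.psi.iloc[0, 0])
        assert psi.psi.iloc[0, 1] == pytest.approx(10 / 12)

    def test_three_filters_on_toy_fixture(self):
        """5-exon toy: one constant (sd=0), one with range 0.05, one with 30%
        missing; exactly 2 survive."""
        n = 10
        rng = np.random.default_rng(0)
        inc = np.zeros((5, n), int)
        exc = np.zeros((5, n), int)
        # e0: healthy, variable
        inc[0] = np.linspace(2, 18, n).astype(int)
        exc[0] = 20 - inc[0]
        # e1: constant PSI 0.5 -> sd = 0
        inc[1], exc[1] = 10, 10
        # e2: tiny range (PSI 0.50 to 0.55 over 100 reads)
        inc[2] = np.linspace(50, 55, n).astype(int)
        exc[2] = 100 - inc[2]
        # e3: 30% missing (3 of 10 cells below 5 reads)
        inc[3] = np.linspace(2, 18, n).astype(int)
        exc[3] = 20 - inc[3]
        inc[3, :3], exc[3, :3] = 1, 1
        # e4: healthy, variable
        inc[4] = rng.integers(1, 19, n)
        exc[4] = 20 - inc[4]
        psi = build_psi_table(long_table(inc, exc))
        assert sorted(psi.exon_ids) == ["e0", "e4"]

    def test_absent_exon_dropped(self):
        inc = np.array([[0] * 10, [8] * 10])
        exc = np.array([[0] * 10, [3] * 10])
        inc[1, 0] = 2  # give e1 some variability
        psi = build_psi_table(long_table(inc, exc), min_psi_range=0.0)
        assert "e0" not in psi.psi.index

    def test_psi_missing_iff_low_total(self):
        rng = np.random.default_rng(1)
        total = rng.integers(0, 15, (8, 40))
        inc = rng.binomial(total, 0.5)
        psi = build_psi_table(long_table(inc, total - inc), max_missing_fraction=1.1,
                              min_psi_range=0.0)
        cols = [f"s{j}" for j in range(40)]
        for e in psi.psi.index:
            i = int(e[1:])
            expect_missing = total[i] < 5
            np.testing.assert_array_equal(
                psi.psi.loc[e, cols].isna().to_numpy(), expect_missing
            )


class TestPsiPmiCorrelation:
    def test_linear_psi_gives_r_one(self):
        n = 30
        samples = make_samples(n, pmi=np.linspace(50, 1400, n))
        frac = np.linspace(0.1, 0.9, n)
        inc = np.round(frac * 1000).astype(int)[None, :]
        exc = 1000 - inc
        psi = build_psi_table(long_table(inc, exc))
        res = psi_pmi_correlation(psi, samples)
        assert res.loc[0, "r"] == pytest.approx(1.0, abs=1e-3)

    def test_planted_exons_recovered(self):
        cfg = SyntheticConfig(
            n_donors=150, tissues={"muscle": 1.0}, n_genes=10,
            n_isoform_genes=60, psi_assoc_fraction=0.5,
            psi_slope_per_minute=4.5e-4, psi_mean_total_reads=80.0,
            pmi_range_minutes=(17.0, 1300.0),
            elapsed_delay_range_minutes=(1.0, 30.0), seed=31,
        )
        _, samples, _ = generate_cohort(cfg)
        _, junc, truth = generate_isoform_data(cfg, samples)
        psi = build_psi_table(junc)
        res = psi_pmi_correlation(psi, samples).set_index("exon_id")
        planted = truth.exon_true_assoc[truth.exon_true_assoc].index
        planted = [e for e in planted if e in res.index]
        recall = np.mean([res.loc[e, "significant"] for e in planted])
        assert recall >= 0.8
        nulls = [e for e in truth.exon_true_assoc[~truth.exon_true_assoc].index if e in res.index]
        fpr = np.mean([res.loc[e, "significant"] for e in nulls])
        assert fpr <= 0.05


class TestBloodInclusion:
    def test_identical_groups_not_significant(self):
        n = 20
        samples = make_samples(n, pmi=np.r_[np.full(10, -300.0), np.linspace(100, 1200, 10)])
        rng = np.random.default_rng(2)
        inc = rng.integers(5, 15, (3, n))
        exc = 20 - inc
        psi = build_psi_table(long_table(inc, exc), min_psi_range=0.0)
        res, summary = blood_differential_inclusion(psi, samples)
        assert not res["significant"].any()

    def test_exact_enumeration_on_separated_groups(self):
        """Pre PSI 0.9 vs post 0.5 at n=10 each: exact two-sided rank-sum
        p = 2 * 10! * 10! / 20!, dPSI = -0.4, significant."""
        n = 20
        samples = make_samples(n, pmi=np.r_[np.full(10, -300.0), np.linspace(100, 1200, 10)])
        # tiny monotone jitter keeps values tie-free within groups
        pre_psi = 0.9 + np.linspace(0, 0.036, 10)
        post_psi = 0.5 + np.linspace(0, 0.036, 10)
        inc = np.round(np.r_[pre_psi, post_psi] * 1000).astype(int)[None, :]
        exc = 1000 - inc
        psi = build_psi_table(long_table(inc, exc), min_psi_range=0.0)
        res, summary = blood_differential_inclusion(psi, samples)
        expected_p = 2 * 1 / 184756  # 2 / C(20, 10)
        assert res.loc[0, "pvalue"] == pytest.approx(expected_p, rel=1e-9)
        assert res.loc[0, "delta_psi"] == pytest.approx(-0.4, abs=0.01)
        assert bool(res.loc[0, "significant"])
        assert summary["fraction_more_included_premortem"] == 1.0

    def test_small_delta_gated_regardless_of_p(self):
        n = 40
        samples = make_samples(n, pmi=np.r_[np.full(20, -300.0), np.linspace(100, 1200, 20)])
        pre = 0.55 + np.linspace(0, 0.004, 20)
        post = 0.50 + np.linspace(0, 0.004, 20)
        inc = np.round(np.r_[pre, post] * 10000).astype(int)[None, :]
        exc = 10000 - inc
        psi = build_psi_table(long_table(inc, exc), min_psi_range=0.0)
        res, _ = blood_differential_inclusion(psi, samples)
        assert res.loc[0, "pvalue"] < 1e-5
        assert not bool(res.loc[0, "significant"])  # |dPSI| = 0.05 < 0.1

    def test_label_swap_negates_delta_and_preserves_p(self):
        n = 16
        rng = np.random.default_rng(3)
        pmi_a = np.r_[np.full(8, -300.0), np.linspace(100, 1200, 8)]
        samples_a = make_samples(n, pmi=pmi_a)
        samples_b = make_samples(n, pmi=pmi_a[::-1])
        inc = rng.integers(2, 18, (4, n))
        exc = 20 - inc
        psi = build_psi_table(long_table(inc, exc), min_psi_range=0.0)
        res_a, _ = blood_differential_inclusion(psi, samples_a)
        res_b, _ = blood_differential_inclusion(psi, samples_b)
        np.testing.assert_allclose(res_a["pvalue"], res_b["pvalue"])
        np.testing.assert_allclose(res_a["delta_psi"], -res_b["delta_psi"])


class TestEntropy:
    @pytest.mark.parametrize(
        "ratios,expected",
        [([0.5, 0.5], np.log(2)),
         ([1.0], 0.0),
         ([1.0, 0.0, 0.0], 0.0),
         ([0.5, 0.25, 0.25], 1.5 * np.log(2)),
         ([1 / 3] * 3, np.log(3))],
    )
    def test_known_values(self, ratios, expected):
        assert shannon_entropy(np.array(ratios)) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=10**6))
    def test_bounds_and_permutation_invariance(self, k, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k))
        e = shannon_entropy(p)
        assert -1e-12 <= e <= np.log(k) + 1e-12
        assert shannon_entropy(rng.permutation(p)) == pytest.approx(e, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=5),
           st.floats(min_value=0.05, max_value=0.95),
           st.integers(min_value=0, max_value=10**6))
    def test_mixing_toward_uniform_raises_entropy(self, k, lam, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k) * 0.5)
        mixed = (1 - lam) * p + lam / k
        assert shannon_entropy(mixed) >= shannon_entropy(p) - 1e-12


class TestEntropyProfile:
    def _iso(self, data, samples):
        return pd.DataFrame(
            data["values"],
            index=pd.MultiIndex.from_tuples(data["index"], names=["gene_id", "isoform_id"]),
            columns=samples,
        )

    def test_gene_selection_rules(self):
        samples = make_samples(10)
        sample_ids = list(samples["sample_id"])
        vals = np.ones((5, 10))
        vals[2, :] = 0.0  # g1's second isoform never expressed: still 2 isoforms
        vals[4, :2] = 0.0
        idx = [("g0", "i1"), ("g0", "i2"), ("g1", "i1"), ("g2", "i1"), ("g2", "i2")]
        iso = self._iso({"values": vals, "index": idx}, sample_ids)
        entropy, assoc, major = splicing_entropy_profile(iso, samples)
        assert "g1" not in entropy.index  # single isoform
        assert "g0" in entropy.index

    def test_zero_total_gives_missing_entropy(self):
        samples = make_samples(10)
        ids = list(samples["sample_id"])
        vals = np.ones((2, 10))
        vals[:, 0] = 0.0
        iso = self._iso({"values": vals, "index": [("g0", "a"), ("g0", "b")]}, ids)
        entropy, _, _ = splicing_entropy_profile(iso, samples, min_expressed_fraction=0.8)
        assert np.isnan(entropy.loc["g0", ids[0]])
        assert entropy.loc["g0", ids[1]] == pytest.approx(np.log(2))

    def test_drift_sign_recovered(self):
        cfg = SyntheticConfig(
            n_donors=150, tissues={"lung": 1.0}, n_genes=10,
            n_isoform_genes=40, entropy_drift=5e-4, entropy_drift_fraction=0.5,
            pmi_range_minutes=(17.0, 1500.0),
            elapsed_delay_range_minutes=(1.0, 30.0), seed=17,
        )
        _, samples, _ = generate_cohort(cfg)
        iso, _, truth = generate_isoform_data(cfg, samples)
        _, assoc, major = splicing_entropy_profile(iso, samples)
        assoc = assoc.set_index("gene_id")
        drift = [g for g in truth.entropy_drift_genes if g in assoc.index]
        assert len(drift) >= 10
        signs = (assoc.loc[drift, "r"] > 0).mean()
        assert signs >= 0.95
        # dominant-isoform share falls as entropy rises with PMI
        pmi = samples.set_index("sample_id")["sample_pmi_minutes"]
        shares = major.loc[drift].mean(axis=0)
        assert np.corrcoef(shares, pmi[shares.index])[0, 1] < 0
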
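import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dynlat import (bh_fdr, chi_square_2x2, clinical_correlations,
                    demographics_table, group_compare, handedness_score,
                    spearman_corr, spearman_p_from_rho, two_sample_ttest)
from dynlat.stats import StatsError


class TestTwoSampleTtest:
    def test_identical_samples(self):
        t, df, p = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_hand_computed(self):
        t, df, p = two_sample_ttest([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4
        assert p == pytest.approx(0.288, abs=5e-4)

    def test_scale_invariance(self):
        x, y = [1.0, 2.0, 5.0], [2.0, 4.0, 4.5]
        t1, _, _ = two_sample_ttest(x, y)
        t2, _, _ = two_sample_ttest([3 * v for v in x], [3 * v for v in y])
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            x = rng.standard_normal(rng.integers(2, 30))
            y = rng.standard_normal(rng.integers(2, 30))
            t, df, p = two_sample_ttest(x, y)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_welch_matches_scipy(self, rng):
        x = rng.standard_normal(12)
        y = 3 * rng.standard_normal(25)
        t, df, p = two_sample_ttest(x, y, equal_var=False)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance(self):
        t, df, p = two_sample_ttest([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        with pytest.raises(StatsError):
            two_sample_ttest([2.0, 2.0], [3.0, 3.0])

    def test_too_small(self):
        with pytest.raises(StatsError):
            two_sample_ttest([1.0], [1.0, 2.0])


def bh_oracle(pvals, alpha):
    """Textbook step-up: largest k with p_(k) <= k*alpha/m rejected."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * alpha / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestBhFdr:
    def test_worked_example(self):
        q, rej = bh_fdr([0.01, 0.02, 0.03, 0.2], alpha=0.05)
        np.testing.assert_array_equal(rej, [True, True, True, False])

    def test_uniform_strong_signal(self):
        q, rej = bh_fdr([0.01] * 10)
        assert rej.all()
        np.testing.assert_allclose(q, 0.01)

    def test_empty(self):
        q, rej = bh_fdr([])
        assert q.size == 0 and rej.size == 0

    def test_invalid_p(self):
        with pytest.raises(StatsError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(StatsError):
            bh_fdr([0.5, -0.1])

    def test_q_at_least_p(self, rng):
        p = rng.random(50)
        q, _ = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)

    def test_oracle_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            q, rej = bh_fdr(p, alpha=0.05)
            np.testing.assert_array_equal(rej, bh_oracle(p, 0.05))
            ref_rej, ref_q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_array_equal(rej, ref_rej)
            np.testing.assert_allclose(q, ref_q, atol=1e-12)


class TestSpearman:
    def test_reported_p_value(self):
        # |rho| = 0.320 at n = 48 -> two-tailed p = 0.0266.  (A published
        # rho of 0.320 rounded from |rho| >= 0.3203 would print p = 0.026;
        # at face value the t-approximation lands just past the 0.0265
        # rounding boundary.)
        assert spearman_p_from_rho(-0.320, 48) == pytest.approx(0.0266, abs=5e-4)
        assert round(spearman_p_from_rho(-0.3205, 48), 3) == 0.026

    def test_t_approx_disagreement_case(self):
        # rho = 0.243, n = 48: two-tailed ~ 0.096; one-tailed ~ 0.048
        assert spearman_p_from_rho(0.243, 48) == pytest.approx(0.096, abs=5e-4)
        assert round(spearman_p_from_rho(0.243, 48, "greater"), 3) == 0.048

    def test_monotone_function_gives_one(self, rng):
        x = rng.standard_normal(20)
        res = spearman_corr(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        g = np.random.default_rng(seed)
        x = g.standard_normal(15)
        y = g.standard_normal(15)
        base = spearman_corr(x, y)
        trans = spearman_corr(np.exp(x / 3), y**3)
        assert trans.rho == pytest.approx(base.rho, abs=1e-12)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25) + 0.3 * x
            res = spearman_corr(x, y)
            ref = sps.spearmanr(x, y)
            assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_ties_use_midranks(self):
        x = [1, 1, 2, 3, 3]
        y = [2, 2, 3, 4, 5]
        res = spearman_corr(x, y)
        assert res.rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_flagged(self):
        res = spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined
        assert np.isnan(res.rho)

    def test_too_few_pairs(self):
        with pytest.raises(StatsError):
            spearman_corr([1, 2], [3, 4])


class TestChiSquare:
    def test_reported_gender_table(self):
        chi2, p = chi_square_2x2([[26, 22], [27, 21]])
        assert round(p, 3) == 0.837

    def test_perfect_homogeneity(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_diagonal_table(self):
        chi2, p = chi_square_2x2([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0)
        assert p < 1e-9

    def test_matches_scipy_uncorrected(self, rng):
        for _ in range(30):
            table = rng.integers(1, 40, size=(2, 2))
            chi2, p = chi_square_2x2(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_margin(self):
        with pytest.raises(StatsError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


def _metric_frame(rng, n_per_group=10, units=("U1", "U2"), shift=None):
    rows = []
    for grp, n in (("NC", n_per_group), ("BD", n_per_group)):
        for i in range(n):
            sid = f"{grp}{i}"
            for u in units:
                mli = rng.standard_normal()
                if shift and grp == "BD" and u == shift[0]:
                    mli += shift[1]
                rows.append({"subject_id": sid, "group": grp, "unit_id": u,
                             "unit_level": "subnetwork", "state": "ALL",
                             "mli": mli, "lf": abs(rng.standard_normal()),
                             "n_windows_used": 93})
    return pd.DataFrame(rows)


class TestGroupCompare:
    def test_determinism(self, rng):
        df = _metric_frame(rng)
        r1 = group_compare(df, "BD", "NC")
        r2 = group_compare(df, "BD", "NC")
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        df = _metric_frame(rng, n_per_group=40, units=("U1", "U2", "U3"),
                           shift=("U2", 2.0))
        res = group_compare(df, "BD", "NC")
        hit = res[(res["unit_id"] == "U2") & (res["metric"] == "MLI")]
        assert hit["significant"].all()
        assert (hit["t"] > 0).all()

    def test_fdr_family_is_level_metric_state(self, rng):
        df = _metric_frame(rng)
        res = group_compare(df, "BD", "NC")
        for _, fam in res.groupby("family"):
            q, rej = bh_fdr(fam["p"].to_numpy())
            np.testing.assert_allclose(fam["q"], q, atol=1e-12)
            np.testing.assert_array_equal(fam["significant"], rej)

    def test_q_at_least_p(self, rng):
        res = group_compare(_metric_frame(rng), "BD", "NC")
        assert np.all(res["q"] >= res["p"] - 1e-15)

    def test_missing_state_metrics_dropped_with_warning(self, rng):
        df = _metric_frame(rng)
        df.loc[df.index[:2], "mli"] = np.nan
        with pytest.warns(UserWarning, match="dropped"):
            res = group_compare(df, "BD", "NC")
        assert len(res)

    def test_underpopulated_unit_excluded(self, rng):
        df = _metric_frame(rng, n_per_group=2)
        df = df[~((df["group"] == "BD") & (df["unit_id"] == "U2")
                  & (df["subject_id"] != "BD0"))]
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = group_compare(df, "BD", "NC")
        assert "U2" not in set(res["unit_id"])


class TestClinicalCorrelations:
    def test_recovers_planted_sign(self):
        rng = np.random.default_rng(2)
        df = _metric_frame(rng, n_per_group=30)
        patients = df[(df["group"] == "BD") & (df["unit_id"] == "U1")]
        scores = pd.DataFrame({
            "subject_id": patients["subject_id"],
            "BPRS": 50 + 10 * patients["mli"].to_numpy()
                    + rng.standard_normal(len(patients)),
        }).set_index("subject_id")
        selection = pd.DataFrame([{"unit_id": "U1", "unit_level": "subnetwork",
                                   "metric": "MLI", "state": "ALL"}])
        res = clinical_correlations(df, scores, selection, "BD")
        assert len(res) == 1
        assert res["rho"].iloc[0] > 0.8
        assert res["n"].iloc[0] == 30

    def test_constant_scores_flagged(self, rng):
        df = _metric_frame(rng, n_per_group=5)
        sids = df[df["group"] == "BD"]["subject_id"].unique()
        scores = pd.DataFrame({"subject_id": sids, "YMRS": 10.0}).set_index(
            "subject_id")
        selection = pd.DataFrame([{"unit_id": "U1", "unit_level": "subnetwork",
                                   "metric": "MLI", "state": "ALL"}])
        res = clinical_correlations(df, scores, selection, "BD")
        assert not res["defined"].iloc[0]

    def test_too_few_patients_skipped(self, rng):
        df = _metric_frame(rng, n_per_group=5)
        scores = pd.DataFrame({"subject_id": ["BD0", "BD1"],
                               "SANS": [10.0, 20.0]}).set_index("subject_id")
        selection = pd.DataFrame([{"unit_id": "U1", "unit_level": "subnetwork",
                                   "metric": "MLI", "state": "ALL"}])
        with pytest.warns(UserWarning, match="fewer than 3"):
            res = clinical_correlations(df, scores, selection, "BD")
        assert res.empty


class TestDemographics:
    @staticmethod
    def _demo(rng, n=20, identical=False):
        rows = []
        for grp in ("NC", "BD"):
            g = np.random.default_rng(0) if identical else rng
            for i in range(n):
                rows.append({"subject_id": f"{grp}{i}", "group": grp,
                             "age": float(g.normal(34, 9)),
                             "gender": "M" if i % 2 else "F",
                             "education": float(g.normal(15, 2)),
                             "handscore": float(g.normal(0.9, 0.1))})
        return pd.DataFrame(rows)

    def test_identical_groups(self, rng):
        demo = self._demo(rng, identical=True)
        table = demographics_table(demo, "BD", "NC")
        cont = table[table["test"] == "t"]
        assert np.allclose(cont["p"], 1.0)
        gender = table[table["test"] == "chi2"]
        assert gender["p"].iloc[0] == pytest.approx(1.0)

    def test_reported_gender_split(self, rng):
        demo = self._demo(rng, n=48)
        genders_nc = ["M"] * 26 + ["F"] * 22
        genders_bd = ["M"] * 27 + ["F"] * 21
        demo.loc[demo["group"] == "NC", "gender"] = genders_nc
        demo.loc[demo["group"] == "BD", "gender"] = genders_bd
        table = demographics_table(demo, "BD", "NC")
        p = table.loc[table["test"] == "chi2", "p"].iloc[0]
        assert round(p, 3) == 0.837

    def test_missing_field(self, rng):
        demo = self._demo(rng).drop(columns=["education"])
        with pytest.raises(StatsError, match="education"):
            demographics_table(demo, "BD", "NC")

    def test_missing_value_lists_subject(self, rng):
        demo = self._demo(rng)
        demo.loc[demo["subject_id"] == "BD3", "age"] = np.nan
        with pytest.raises(StatsError, match="BD3"):
            demographics_table(demo, "BD", "NC")


class TestHandedness:
    def test_all_right(self):
        assert handedness_score([10.0], [0.0])[0] == pytest.approx(1.0)

    def test_balanced(self):
        assert handedness_score([5.0], [5.0])[0] == pytest.approx(0.0)

    def test_zero_total_rejected(self):
        with pytest.raises(StatsError):
            handedness_score([0.0], [0.0])
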
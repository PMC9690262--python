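import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from _oracles import bh_oracle, rm_anova_oracle, wilcoxon_exact_enumeration
from thermoengage.datasets import gmfm88_cohort
from thermoengage.stats import (
    clinical_deltas,
    fdr_adjust,
    paired_t,
    paired_t_arrays,
    rm_anova,
    rm_anova_matrix,
    run_statistics,
    shapiro_wilk,
    wilcoxon_signed_rank,
)


class TestShapiroWilk:
    def test_pvalues_uniform_under_normality(self):
        ps = []
        for seed in range(200):
            x = np.random.default_rng(seed).standard_normal(20)
            ps.append(shapiro_wilk(x)[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_power_against_skew(self):
        rejections = 0
        for seed in range(100):
            x = np.random.default_rng(seed).exponential(size=30)
            rejections += shapiro_wilk(x)[1] < 0.05
        assert rejections > 50  # far above the 5% nominal rate

    def test_degenerate_and_out_of_range(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.full(10, 3.0))
        with pytest.raises(ValueError):
            shapiro_wilk(np.arange(2.0))
        with pytest.raises(ValueError):
            shapiro_wilk(np.arange(51.0))


class TestWilcoxon:
    def test_published_cohort_exact_p(self):
        """Eight all-positive paired improvements give the extreme exact
        two-sided p of 2/2^8 = 0.0078125, printed as 0.008."""
        df = gmfm88_cohort()
        res = wilcoxon_signed_rank(df["t0"], df["t2"], mode="exact")
        assert res.p == 0.0078125
        assert round(res.p, 3) == 0.008
        assert res.n == 8
        assert res.w == 36.0  # all ranks positive

    def test_antisymmetric_differences_center_null(self):
        pre = np.array([10.0, 10.0, 10.0, 10.0])
        post = pre + np.array([1.0, -1.0, 2.0, -2.0])
        res = wilcoxon_signed_rank(pre, post, mode="exact")
        assert res.p == 1.0
        assert res.z == 0.0

    @pytest.mark.parametrize("n", [5, 8, 11])
    def test_exact_matches_full_enumeration(self, n):
        for seed in range(10):
            r = np.random.default_rng(seed)
            pre = r.normal(30, 5, n)
            post = pre + r.normal(0.5, 2, n)
            # induce occasional ties in |d|
            if seed % 3 == 0:
                post[1] = pre[1] + (post[0] - pre[0])
            res = wilcoxon_signed_rank(pre, post, mode="exact")
            w_ref, p_ref = wilcoxon_exact_enumeration(pre, post)
            assert res.w == w_ref
            assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        pre = rng.normal(30, 5, 12)
        post = pre + rng.normal(1, 2, 12)
        res = wilcoxon_signed_rank(pre, post, mode="exact")
        ref = sps.wilcoxon(post, pre, mode="exact")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_exact_matches_monte_carlo_sign_permutation(self, rng):
        pre = rng.normal(30, 5, 10)
        post = pre + rng.normal(1, 2, 10)
        res = wilcoxon_signed_rank(pre, post, mode="exact")
        d = post - pre
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        draws = rng.random((100_000, 10)) < 0.5
        ws = (draws * ranks).sum(axis=1)
        p_mc = 2 * min((ws <= w_obs + 1e-9).mean(), (ws >= w_obs - 1e-9).mean())
        assert res.p == pytest.approx(min(1.0, p_mc), abs=4 * math.sqrt(0.25 / 100_000) * 2)

    def test_normal_approx_z_with_tie_correction(self):
        """The published cohort's differences contain one tied pair (8.3
        twice), so sigma = sqrt(sum r_i^2)/2 = sqrt(203.5)/2; the resulting
        |z| = 2.5236 reproduces the published 2.524 (the no-tie formula
        would give 2.5205)."""
        df = gmfm88_cohort()
        res = wilcoxon_signed_rank(df["t0"], df["t2"], mode="normal_approx")
        assert abs(res.z) == pytest.approx(36.0 / math.sqrt(203.5), rel=1e-12)
        assert round(abs(res.z), 3) == 2.524

    def test_zero_differences_dropped(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        post = np.array([1.0, 3.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(pre, post, mode="exact")
        assert res.n == 3
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(pre, pre)


class TestRmAnova:
    def test_two_sessions_reduce_to_squared_paired_t(self, rng):
        data = rng.normal(34, 0.5, (7, 2))
        res = rm_anova_matrix(data)
        t, p = paired_t_arrays(data[:, 0], data[:, 1])
        assert res.f == pytest.approx(t**2, rel=1e-10)
        assert res.epsilon == pytest.approx(1.0)
        assert res.p == pytest.approx(p, rel=1e-10)

    @pytest.mark.parametrize("n, k", [(4, 3), (6, 3), (8, 4), (5, 4)])
    def test_matches_naive_oracle(self, n, k, rng):
        for _ in range(10):
            data = rng.normal(0, 1, (n, k))
            res = rm_anova_matrix(data)
            f_ref, eps_ref, df1_ref, df2_ref = rm_anova_oracle(data)
            assert res.f == pytest.approx(f_ref, rel=1e-10)
            assert res.epsilon == pytest.approx(eps_ref, rel=1e-10)
            assert res.df1 == pytest.approx(df1_ref, rel=1e-10)
            assert res.df2 == pytest.approx(df2_ref, rel=1e-10)
            assert res.df2 / res.df1 == pytest.approx(n - 1, rel=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = rng.normal(0, 1, (6, 3))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(6), 3),
            "session": np.tile(np.arange(3), 6),
            "value": data.ravel(),
        })
        ref = pingouin.rm_anova(long, dv="value", within="session",
                                subject="subject", correction=True)
        res = rm_anova_matrix(data)
        assert res.f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert res.epsilon == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-8)
        assert res.p == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_epsilon_detects_sphericity_violation(self, rng):
        # compound symmetry: epsilon near 1
        eps_cs, eps_viol = [], []
        for seed in range(40):
            r = np.random.default_rng(seed)
            subj = r.normal(0, 1, (20, 1))
            cs = subj + r.normal(0, 1, (20, 4))
            eps_cs.append(rm_anova_matrix(cs).epsilon)
            # heterogeneous variances/correlations violate sphericity
            base = r.normal(0, 1, (20, 4)) * np.array([0.2, 1.0, 3.0, 6.0])
            viol = base + np.cumsum(r.normal(0, 2, (20, 4)), axis=1)
            eps_viol.append(rm_anova_matrix(viol).epsilon)
        assert np.mean(eps_cs) > 0.85
        assert np.mean(eps_viol) < np.mean(eps_cs) - 0.1

    def test_epsilon_bounds(self, rng):
        for _ in range(20):
            res = rm_anova_matrix(rng.normal(0, 1, (5, 3)))
            assert 0.5 <= res.epsilon <= 1.0

    def test_listwise_deletion_reports_n_complete(self):
        rows = []
        for subj in range(6):
            for sess in range(3):
                if subj == 0 and sess == 2:
                    continue  # incomplete subject
                rows.append(("s%d" % subj, sess, "nose_tip", "mean_temp",
                             34.0 + 0.1 * subj + 0.05 * sess + 0.01 * ((subj * 7 + sess * 3) % 5)))
        df = pd.DataFrame(rows, columns=["subject", "session", "roi", "metric", "value"])
        res = rm_anova(df, "nose_tip", "mean_temp")
        assert res.n_complete == 5
        assert res.df2 / res.df1 == pytest.approx(4.0)

    def test_degenerate_inputs(self, rng):
        with pytest.raises(ValueError):
            rm_anova_matrix(rng.normal(0, 1, (1, 3)))
        with pytest.raises(ValueError):
            rm_anova_matrix(np.tile([[1.0, 2.0, 3.0]], (4, 1)))  # zero error variance


class TestPairedT:
    def test_identical_sessions(self):
        a = np.array([34.0, 34.5, 35.0])
        t, p = paired_t_arrays(a, a.copy())
        assert t == 0.0
        assert p == 1.0

    def test_three_pair_hand_computation(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 7.0])
        d = b - a
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        t, p = paired_t_arrays(b, a)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_ref), df=2), rel=1e-12)

    def test_sign_flip_negates_t_preserves_p(self, rng):
        a = rng.normal(34, 0.5, 8)
        b = a + rng.normal(0.3, 0.2, 8)
        t1, p1 = paired_t_arrays(a, b)
        t2, p2 = paired_t_arrays(b, a)
        assert t1 == pytest.approx(-t2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_variance_differences_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_t_arrays(a, a + 0.5)


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.03]), [0.03])

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2, 0.2]), [0.2] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_bh_properties_and_oracle(self, ps):
        adj = fdr_adjust(ps)
        np.testing.assert_allclose(adj, bh_oracle(ps), atol=1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)          # >= raw
        assert np.all(adj <= np.minimum(1, np.asarray(ps) * len(ps)) + 1e-12)  # <= Bonferroni
        # order preservation on the raw ranks
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)


class TestClinicalDeltas:
    def test_published_consistent_rows(self):
        """Delta and delta% recomputed from the published pre/post scores
        match the printed columns for the arithmetically consistent rows."""
        df = clinical_deltas(gmfm88_cohort())
        consistent = df[df["subject"].isin(["1", "4", "5", "6", "7"])]
        np.testing.assert_array_equal(consistent["delta"], consistent["published_delta"])
        np.testing.assert_array_equal(consistent["delta_pct"],
                                      consistent["published_delta_pct"])

    def test_subject_level_worked_examples(self):
        df = clinical_deltas(pd.DataFrame({"t0": [16.00, 30.00], "t2": [24.30, 36.30]}))
        assert df["delta"].tolist() == [8.3, 6.3]
        assert df["delta_pct"].tolist() == [51.9, 21.0]

    def test_no_change_gives_zero(self):
        df = clinical_deltas(pd.DataFrame({"t0": [20.0], "t2": [20.0]}))
        assert df["delta"].iloc[0] == 0.0
        assert df["delta_pct"].iloc[0] == 0.0

    def test_nonpositive_t0_rejected(self):
        with pytest.raises(ValueError):
            clinical_deltas(pd.DataFrame({"t0": [0.0], "t2": [1.0]}))


class TestRunStatistics:
    def _cohort(self, rng, drift=0.0):
        rows = []
        for subj in range(5):
            for sess in range(3):
                for roi in ("nose_tip", "corrugator"):
                    for metric in ("mean_temp", "std_temp", "sampen"):
                        rows.append((f"s{subj}", sess, roi, metric,
                                     rng.normal(34 + drift * sess, 0.1)))
        return pd.DataFrame(rows, columns=["subject", "session", "roi", "metric", "value"])

    def test_report_has_six_omnibus_entries(self, rng):
        report = run_statistics(self._cohort(rng))
        assert len(report.omnibus) == 6
        keys = set(report.omnibus)
        assert keys == {(roi, m) for roi in ("corrugator", "nose_tip")
                        for m in ("mean_temp", "sampen", "std_temp")}

    def test_pairwise_only_when_omnibus_rejects(self, rng):
        report = run_statistics(self._cohort(rng, drift=-2.0))
        for key in report.pairwise:
            assert report.omnibus[key].p < report.alpha
            assert len(report.pairwise[key]) == 3
            for r in report.pairwise[key]:
                assert r.p_adjusted >= r.p_raw - 1e-12

    def test_clinical_block_present(self, rng):
        clinical = pd.DataFrame({"t0": np.arange(10.0, 18.0),
                                 "t2": np.arange(10.0, 18.0) + rng.uniform(1, 3, 8)})
        report = run_statistics(self._cohort(rng), clinical)
        assert report.clinical["wilcoxon"]["mode"] == "exact"
        assert report.clinical["wilcoxon"]["p"] == pytest.approx(0.0078125)

    def test_markdown_mirrors_pairwise_table(self, rng):
        report = run_statistics(self._cohort(rng, drift=-2.0))
        md = report.to_markdown()
        assert "Adjusted p-Value" in md
        n_rows = sum(len(v) for v in report.pairwise.values())
        assert len(md.strip().splitlines()) == 2 + n_rows
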
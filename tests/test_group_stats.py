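"""Tests of the statistics layer: demographics, effect sizes, Holm, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microstates import (
    GroupSummary,
    bayes_factor_bic,
    chi_square_2x2,
    cohens_d_independent,
    cohens_d_one_sample,
    eta2_to_d,
    gender_table,
    holm_adjust,
    independent_t_from_summary,
    mixed_design_anova,
    pearson_correlation,
)


class TestChiSquare:
    def test_reproduces_demographics_values(self):
        x2, df, p = chi_square_2x2(gender_table("patients", "controls"))
        assert df == 1
        assert x2 == pytest.approx(35.762, abs=5e-4)
        assert p == pytest.approx(2.229e-9, rel=1e-3)

    def test_identical_rows_give_zero(self):
        x2, _, p = chi_square_2x2([[1, 21], [1, 21]])
        assert x2 == 0.0
        assert p == 1.0

    def test_agrees_with_scipy(self, rng):
        from scipy.stats import chi2_contingency

        for _ in range(10):
            t = rng.integers(1, 50, size=(2, 2))
            x2, _, p = chi_square_2x2(t)
            ref = chi2_contingency(t, correction=False)
            assert x2 == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_transpose_and_swap_invariance(self, rng):
        t = rng.integers(1, 50, size=(2, 2))
        x2, _, _ = chi_square_2x2(t)
        assert chi_square_2x2(t.T)[0] == pytest.approx(x2, rel=1e-12)
        assert chi_square_2x2(t[::-1, ::-1])[0] == pytest.approx(x2, rel=1e-12)

    def test_yates_correction_flag(self):
        plain, _, _ = chi_square_2x2([[11, 90], [39, 36]])
        corrected, _, _ = chi_square_2x2([[11, 90], [39, 36]], correction=True)
        assert corrected < plain

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [3, 4]])


class TestTFromSummary:
    def test_equal_means(self):
        t, df, p = independent_t_from_summary(
            GroupSummary(10, 5.0, 1.0), GroupSummary(12, 5.0, 2.0)
        )
        assert t == 0.0
        assert df == 20
        assert p == 1.0

    def test_education_comparison_from_rounded_summaries(self):
        # rounded group summaries reproduce the unrounded-data value to ~0.1
        t, df, _ = independent_t_from_summary(
            GroupSummary(101, 13.4, 2.7), GroupSummary(75, 15.1, 2.9)
        )
        assert df == 174
        assert t == pytest.approx(-3.915, abs=0.1)

    def test_doubling_n_scales_t_by_sqrt2(self):
        t1, _, _ = independent_t_from_summary(
            GroupSummary(20, 1.0, 2.0), GroupSummary(20, 0.0, 2.0)
        )
        t2, _, _ = independent_t_from_summary(
            GroupSummary(40, 1.0, 2.0), GroupSummary(40, 0.0, 2.0)
        )
        assert t2 == pytest.approx(np.sqrt(2.0) * t1, rel=1e-12)


class TestCohensD:
    def test_zero_difference(self):
        es = cohens_d_independent(GroupSummary(10, 3.0, 1.0), GroupSummary(10, 3.0, 1.0))
        assert es.d == 0.0
        assert es.ci_low < 0 < es.ci_high

    def test_unit_difference_unit_sd(self):
        es = cohens_d_independent(GroupSummary(20, 1.0, 1.0), GroupSummary(20, 0.0, 1.0))
        assert es.d == pytest.approx(1.0)

    def test_one_sample_difference_score(self, rng):
        # difference scores with mean -7.21 and SD 12.50 give d ~ -0.577
        x = rng.standard_normal(32)
        x = (x - x.mean()) / x.std(ddof=1) * 12.50 - 7.21
        es = cohens_d_one_sample(x)
        assert es.d == pytest.approx(-7.21 / 12.50, abs=1e-9)
        assert es.d == pytest.approx(-0.576, abs=0.005)

    def test_sign_convention_consistency(self):
        ind = cohens_d_independent(GroupSummary(10, 2.0, 1.0), GroupSummary(10, 1.0, 1.0))
        one = cohens_d_one_sample(np.array([1.0, 1.1, 0.9, 1.05]))
        assert ind.d > 0 and one.d > 0


def _holm_oracle(p, m):
    """Explicit step-down oracle: rank each p, scan sorted order with a
    running maximum, cap at 1."""
    order = np.argsort(p, kind="stable")
    adj = np.empty(len(p))
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


class TestHolm:
    def test_reproduces_published_adjusted_column(self):
        from microstates import demographics_fixtures

        grid = demographics_fixtures()["uncorrected_p"]
        p = grid.to_numpy().ravel()
        adj = holm_adjust(p).reshape(grid.shape)
        adj = pd.DataFrame(adj, index=grid.index, columns=grid.columns)
        assert adj.loc["mean_duration", "B"] == pytest.approx(0.018, abs=5e-4)
        # occurrence class A is raised above 0.882 x 1 by monotonicity
        assert adj.loc["occurrence", "A"] == pytest.approx(0.898, abs=5e-4)
        assert adj.loc["coverage", "A"] == pytest.approx(0.898, abs=5e-4)
        assert adj.loc["coverage", "C"] == pytest.approx(1.742e-6, rel=1e-3)
        assert adj.loc["mean_duration", "D"] == pytest.approx(3.311e-5, rel=1e-3)

    def test_single_p_unchanged(self):
        assert holm_adjust([0.04]).tolist() == [0.04]

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_explicit_oracle(self, p):
        p = np.array(p)
        np.testing.assert_allclose(holm_adjust(p), _holm_oracle(p, len(p)), atol=1e-12)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=12)
        _, ref, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), ref, atol=1e-12)

    def test_family_larger_than_list(self):
        # one p-value from a family of 12 is Bonferroni-scaled
        assert holm_adjust([0.01], m=12)[0] == pytest.approx(0.12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestConversionsAndBayes:
    @pytest.mark.parametrize("eta2, d", [(0.0, 0.0), (0.5, 2.0)])
    def test_eta2_to_d_analytic(self, eta2, d):
        assert eta2_to_d(eta2) == pytest.approx(d)

    def test_eta2_round_trip(self, rng):
        for eta2 in rng.uniform(0.0, 0.99, size=20):
            d = eta2_to_d(eta2)
            assert d**2 / (d**2 + 4.0) == pytest.approx(eta2, abs=1e-12)

    def test_eta2_one_rejected(self):
        with pytest.raises(ValueError):
            eta2_to_d(1.0)

    def test_bic_bayes_factor_analytic(self):
        assert bayes_factor_bic(10.0, 10.0) == 1.0
        assert bayes_factor_bic(10.0, 12.0) == pytest.approx(np.e)

    def test_null_simulation_favors_smaller_model(self, rng):
        # regression null: adding a useless covariate should lose by BIC
        bfs = []
        for _ in range(100):
            n = 40
            y = rng.standard_normal(n)
            x = rng.standard_normal(n)

            def bic(resid, k):
                s2 = (resid**2).mean()
                loglik = -n / 2 * (np.log(2 * np.pi * s2) + 1)
                return k * np.log(n) - 2 * loglik

            r_null = y - y.mean()
            beta = np.polyfit(x, y, 1)
            r_alt = y - np.polyval(beta, x)
            bfs.append(bayes_factor_bic(bic(r_null, 2), bic(r_alt, 3)))
        assert np.median(bfs) > 1.0


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, df, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert df == 8

    def test_orthogonal_centered(self):
        r, _, p = pearson_correlation([1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_published_r_gives_published_p(self, rng):
        # construct data with r = 0.430 at df = 30 and check p ~ 0.014
        n = 32
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        e -= np.polyval(np.polyfit(x, e, 1), x)  # residualize
        x_ = (x - x.mean()) / x.std()
        e_ = (e - e.mean()) / e.std()
        r_target = 0.430
        y = r_target * x_ + np.sqrt(1 - r_target**2) * e_
        r, df, p, p_holm = pearson_correlation(x_, y, holm_m=12)
        assert r == pytest.approx(0.430, abs=1e-9)
        assert df == 30
        assert p == pytest.approx(0.014, abs=5e-4)
        assert p_holm == pytest.approx(12 * p, rel=1e-12)


def _balanced_toy():
    """2 groups x 3 subjects x 2 within levels with hand-computable means."""
    rows = []
    values = {
        ("a", 0): [1.0, 2.0, 3.0],
        ("a", 1): [2.0, 3.0, 4.0],
        ("b", 0): [5.0, 5.0, 5.0],
        ("b", 1): [3.0, 4.0, 5.0],
    }
    for g in "ab":
        for s in range(3):
            for w in (0, 1):
                rows.append(
                    dict(subject=f"{g}{s}", group=g, w=w, y=values[(g, w)][s])
                )
    return pd.DataFrame(rows)


def _split_plot_oracle(df):
    """Closed-form balanced split-plot sums of squares via cell means."""
    w_levels = sorted(df["w"].unique())
    n_w = len(w_levels)
    grand = df["y"].mean()
    subj_means = df.groupby("subject")["y"].mean()
    group_of = df.groupby("subject")["group"].first()
    group_means = subj_means.groupby(group_of).mean()
    n_subj_per_group = group_of.value_counts()

    ss_group = n_w * sum(
        n_subj_per_group[g] * (group_means[g] - grand) ** 2 for g in group_means.index
    )
    ss_subj = n_w * sum(
        (subj_means[s] - group_means[group_of[s]]) ** 2 for s in subj_means.index
    )
    w_means = df.groupby("w")["y"].mean()
    n_per_w = len(subj_means)
    ss_w = n_per_w * sum((w_means[w] - grand) ** 2 for w in w_levels)
    cell = df.groupby(["group", "w"])["y"].mean()
    ss_gw = sum(
        n_subj_per_group[g]
        * (cell[(g, w)] - group_means[g] - w_means[w] + grand) ** 2
        for g in group_means.index
        for w in w_levels
    )
    ss_total = ((df["y"] - grand) ** 2).sum()
    ss_err_w = ss_total - ss_group - ss_subj - ss_w - ss_gw
    return dict(group=ss_group, subj=ss_subj, w=ss_w, gw=ss_gw, err_w=ss_err_w)


class TestMixedDesignAnova:
    def test_no_group_difference_gives_zero_f(self):
        df = _balanced_toy()
        # same subject-level pattern in both groups: group means identical,
        # subject-to-subject variation retained
        offsets = {0: 0.3, 1: -0.1, 2: 0.5}
        df["y"] = df["w"].astype(float) + df["subject"].str[1].astype(int).map(offsets)
        res = mixed_design_anova(df, "y", "subject", "w", between=["group"],
                                 compute_ci=False)
        assert res.loc["group", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_split_plot_oracle(self):
        df = _balanced_toy()
        res = mixed_design_anova(df, "y", "subject", "w", between=["group"],
                                 compute_ci=False)
        oracle = _split_plot_oracle(df)
        assert res.loc["group", "ss"] == pytest.approx(oracle["group"], abs=1e-9)
        assert res.loc["error (between)", "ss"] == pytest.approx(oracle["subj"], abs=1e-9)
        assert res.loc["w", "ss"] == pytest.approx(oracle["w"], abs=1e-9)
        assert res.loc["w:group", "ss"] == pytest.approx(oracle["gw"], abs=1e-9)
        assert res.loc["error (within)", "ss"] == pytest.approx(oracle["err_w"], abs=1e-9)
        f_group = (oracle["group"] / 1) / (oracle["subj"] / 4)
        assert res.loc["group", "F"] == pytest.approx(f_group, rel=1e-9)

    def test_balanced_ss_decomposition(self, rng):
        rows = []
        for i in range(16):
            g = "a" if i < 8 else "b"
            for w in range(4):
                rows.append(dict(subject=i, group=g, w=w, y=rng.standard_normal()))
        df = pd.DataFrame(rows)
        res = mixed_design_anova(df, "y", "subject", "w", between=["group"],
                                 compute_ci=False)
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert res["ss"].sum() == pytest.approx(total, rel=1e-9)

    def test_study_layout_df_pattern(self, rng):
        rows = []
        for i in range(176):
            g = "pat" if i < 101 else "con"
            gen = "f" if rng.random() < 0.4 else "m"
            edu = rng.normal(14, 3)
            for c in "ABCD":
                rows.append(dict(subject=i, group=g, gender=gen, education=edu,
                                 cls=c, y=rng.standard_normal()))
        res = mixed_design_anova(pd.DataFrame(rows), "y", "subject", "cls",
                                 between=["group", "gender"],
                                 covariates=["education"], compute_ci=False)
        assert res.loc["group", "df1"] == 1 and res.loc["group", "df2"] == 171
        assert res.loc["cls:group", "df1"] == 3 and res.loc["cls:group", "df2"] == 513

    def test_eta2_ci_brackets_estimate_for_large_effect(self, rng):
        rows = []
        for i in range(30):
            g = "a" if i < 15 else "b"
            shift = 3.0 if g == "a" else 0.0
            for w in range(2):
                rows.append(dict(subject=i, group=g, w=w,
                                 y=shift + rng.standard_normal() * 0.5))
        res = mixed_design_anova(pd.DataFrame(rows), "y", "subject", "w",
                                 between=["group"])
        lo, hi = res.loc["group", ["eta2_ci_low", "eta2_ci_high"]]
        assert 0.0 <= lo < hi <= 1.0
        assert res.loc["group", "p"] < 0.001

    def test_incomplete_design_rejected(self):
        df = _balanced_toy().iloc[:-1]
        with pytest.raises(ValueError):
            mixed_design_anova(df, "y", "subject", "w", between=["group"])

    def test_nonconstant_covariate_rejected(self):
        df = _balanced_toy()
        df["cov"] = np.arange(len(df), dtype=float)
        with pytest.raises(ValueError, match="constant within subject"):
            mixed_design_anova(df, "y", "subject", "w", between=["group"],
                               covariates=["cov"])
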
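"""Rank-sum tests, regressions and the cohort results table."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from glucest.stats import (
    GROUPS,
    build_results_table,
    exact_two_sided_p_distribution,
    linreg_age,
    rank_sum_null_pmf,
    volume_contrast_correlation,
    wilcoxon_rank_sum,
)


class TestRankSumNull:
    @pytest.mark.parametrize("n,m", [(3, 3), (4, 4), (3, 5)])
    def test_pmf_matches_exhaustive_enumeration(self, n, m):
        w_vals, pmf = rank_sum_null_pmf(n, m)
        ranks = range(1, n + m + 1)
        counts = np.zeros(w_vals.size)
        for combo in itertools.combinations(ranks, n):
            counts[sum(combo) - w_vals[0]] += 1
        assert np.allclose(pmf, counts / counts.sum())

    def test_two_sided_p_distribution_is_proper(self):
        atoms, probs = exact_two_sided_p_distribution(10, 9)
        assert probs.sum() == pytest.approx(1.0)
        assert np.all(atoms > 0) and np.all(atoms <= 1.0)
        assert np.all(np.diff(atoms) > 0)


class TestWilcoxon:
    def test_exact_p_for_separated_triples(self):
        """{1,2,3} vs {4,5,6}: all 20 labelings enumerable by hand, the
        observed split is one of the two most extreme, p = 2 * 1/20."""
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        res = wilcoxon_rank_sum([5.0, 7.0, 9.0], [5.0, 7.0, 9.0])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n,m,seed", [(5, 5, 0), (10, 9, 1), (7, 12, 2)])
    def test_exact_agrees_with_scipy(self, n, m, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=n), rng.normal(0.4, 1.0, size=m)
        ours = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.method == "exact"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_tied_samples_use_corrected_normal_approximation(self):
        a = [1.0, 2.0, 2.0, 3.0, 5.0]
        b = [2.0, 3.0, 3.0, 4.0, 6.0]
        ours = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        assert ours.method == "normal+tie-correction"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @given(
        shift=st.floats(min_value=-5, max_value=5),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_invariant_under_monotone_transform(self, shift, scale):
        rng = np.random.default_rng(17)
        a, b = rng.normal(size=6), rng.normal(0.5, 1, size=7)
        base = wilcoxon_rank_sum(a, b).p_value
        affine = wilcoxon_rank_sum(scale * a + shift, scale * b + shift).p_value
        expo = wilcoxon_rank_sum(np.exp(a / 5), np.exp(b / 5)).p_value
        assert base == pytest.approx(affine)
        assert base == pytest.approx(expo)

    def test_exact_agrees_with_monte_carlo_permutations(self):
        """Exact enumeration versus a 1e5-draw permutation estimate on a
        (5, 5) split, within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(42)
        a, b = rng.normal(size=5), rng.normal(1.0, 1.0, size=5)
        res = wilcoxon_rank_sum(a, b)
        pooled = np.concatenate([a, b])
        n_draws = 100_000
        perms = np.argsort(rng.random((n_draws, 10)), axis=1)[:, :5]
        ranks = sps.rankdata(pooled)
        w_perm = ranks[perms].sum(axis=1)
        w_obs = ranks[:5].sum()
        p_le = (w_perm <= w_obs).mean()
        p_ge = (w_perm >= w_obs).mean()
        p_mc = min(1.0, 2 * min(p_le, p_ge))
        one_sided = min(p_le, p_ge)
        se = 2 * np.sqrt(one_sided * (1 - one_sided) / n_draws)
        assert abs(res.p_value - p_mc) <= 3 * max(se, 1e-6)

    def test_matches_r_wilcox_test_defaults(self):
        """Cross-check against the R implementation used for the study's
        statistics (exact without ties, corrected normal with ties)."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is expected on PATH in this environment")
        script = (
            "a <- c(1.2, 3.4, 2.2, 5.1, 4.0); b <- c(2.0, 6.3, 5.5, 7.1);"
            "r1 <- wilcox.test(a, b); cat(r1$p.value, '\\n');"
            "a2 <- c(1, 2, 2, 3, 5); b2 <- c(2, 3, 3, 4, 6);"
            "r2 <- suppressWarnings(wilcox.test(a2, b2)); cat(r2$p.value, '\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        p_exact_r, p_ties_r = (float(x) for x in out.stdout.split())
        ours_exact = wilcoxon_rank_sum([1.2, 3.4, 2.2, 5.1, 4.0], [2.0, 6.3, 5.5, 7.1])
        ours_ties = wilcoxon_rank_sum([1, 2, 2, 3, 5], [2, 3, 3, 4, 6])
        assert ours_exact.p_value == pytest.approx(p_exact_r, rel=1e-6)
        assert ours_ties.p_value == pytest.approx(p_ties_r, rel=1e-6)


class TestLinearRegression:
    def test_perfect_fit(self):
        ages = np.array([20.0, 30, 40, 50, 60])
        res = linreg_age(2 * ages + 1, ages)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_three_point_closed_form_fixture(self):
        """Hand-computed OLS for (1,1), (2,3), (3,2): slope 1/2, intercept 1,
        R^2 = 1/4, slope p = 2/3 (t with 1 df is Cauchy)."""
        res = linreg_age([1.0, 3.0, 2.0], [1.0, 2.0, 3.0])
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(0.25)
        assert res.p_value == pytest.approx(2.0 / 3.0)

    def test_equal_ages_rejected(self):
        with pytest.raises(ValueError):
            linreg_age([1.0, 2.0, 3.0], [40.0, 40.0, 40.0])

    def test_zero_variance_response_degenerate(self):
        res = linreg_age([2.0, 2.0, 2.0], [30.0, 40.0, 50.0])
        assert res.degenerate
        assert res.r_squared == 0.0 and res.p_value == 1.0

    def test_r_squared_equals_squared_pearson_of_fit(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(20, 70, 15)
        vals = 0.3 * ages + rng.normal(0, 4, 15)
        res = linreg_age(vals, ages)
        fitted = res.slope * ages + res.intercept
        r = np.corrcoef(fitted, vals)[0, 1]
        assert res.r_squared == pytest.approx(r**2)


from conftest import synthetic_cohort


class TestResultsTable:
    def test_layout_matches_ten_regions_by_two_groups(self):
        bundle = build_results_table(synthetic_cohort())
        assert bundle.comparison.region.nunique() == 10
        assert len(bundle.comparison) == 20
        assert set(bundle.comparison.group) == set(GROUPS)
        # age regressions cover the tissue aggregates plus 7 cortical regions
        assert bundle.regressions.region.nunique() == 9
        assert len(bundle.regressions) == 18

    def test_identical_groups_give_p_one(self):
        df = synthetic_cohort(n_ns=8, n_s=8)
        smoker_rows = df[df.group == GROUPS[1]].copy()
        ns_rows = df[df.group == GROUPS[0]].copy()
        smoker_rows["mean_percent"] = ns_rows["mean_percent"].to_numpy()
        bundle = build_results_table(pd.concat([ns_rows, smoker_rows]))
        assert np.allclose(bundle.comparison.p_value, 1.0)

    def test_region_missing_for_most_subjects_excluded_with_warning(self):
        df = synthetic_cohort()
        df.loc[df.region == "PostG", "mean_percent"] = np.nan
        with pytest.warns(UserWarning, match="PostG"):
            bundle = build_results_table(df)
        assert "PostG" not in set(bundle.comparison.region)

    def test_duplicate_subject_region_rows_rejected(self):
        df = synthetic_cohort()
        with pytest.raises(ValueError):
            build_results_table(pd.concat([df, df.iloc[:5]]))

    def test_volume_correlation_trivial_cases(self):
        df = synthetic_cohort(seed=4)
        df.loc[df.region == "GM", "mean_percent"] = 5.0
        out = volume_contrast_correlation(df)
        gm_rows = out[out.tissue == "GM"]
        assert np.allclose(gm_rows.r_squared, 0.0)
        df2 = synthetic_cohort(seed=5)
        sel = df2.region == "WM"
        df2.loc[sel, "mean_percent"] = 3.0 + 10.0 * df2.loc[sel, "wm_fraction"]
        out2 = volume_contrast_correlation(df2)
        wm_rows = out2[out2.tissue == "WM"]
        assert np.allclose(wm_rows.r_squared, 1.0)

    def test_recovers_injected_volume_slope(self):
        df = synthetic_cohort(seed=6)
        sel = (df.region == "GM") & (df.group == GROUPS[0])
        x = df.loc[sel, "gm_fraction"].to_numpy()
        y = 2.0 + 4.0 * x + np.random.default_rng(7).normal(0, 0.05, x.size)
        df.loc[sel, "mean_percent"] = y
        out = volume_contrast_correlation(df)
        row = out[(out.group == GROUPS[0]) & (out.tissue == "GM")].iloc[0]
        fit = sps.linregress(x, y)
        assert row.slope == pytest.approx(fit.slope)
        assert row.r_squared == pytest.approx(fit.rvalue**2)
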
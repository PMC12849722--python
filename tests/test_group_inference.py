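"""Group-level statistics: correlations, Bayes factors, ANOVA/ANCOVA, grouping."""

import numpy as np
import pytest
from scipy import stats

from goalplane.group_inference import (
    ancova_adjusted_comparison,
    correlate,
    correlation_bf10,
    fisher_ci,
    holm_adjust,
    jarque_bera,
    omnibus_group_tests,
    partial_correlation,
    pearson_r,
    quartile_groups,
    ttest_with_bf,
)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, p = pearson_r(x, 3 - 2 * x)
        assert r == pytest.approx(-1.0)
        r, _ = pearson_r(x, x)
        assert r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        r, p = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        # p from the t transform with n-2 df
        t = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert p == pytest.approx(2 * stats.t.sf(t, 2), rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2, 3])


class TestFisherCI:
    def test_reproduces_reference_interval_positive(self):
        lo, hi = fisher_ci(0.49, 42)
        assert lo == pytest.approx(0.22, abs=0.01)
        assert hi == pytest.approx(0.69, abs=0.01)

    def test_reproduces_reference_interval_negative(self):
        lo, hi = fisher_ci(-0.47, 42)
        assert lo == pytest.approx(-0.68, abs=0.01)
        assert hi == pytest.approx(-0.19, abs=0.01)

    def test_symmetric_about_zero_for_null_r(self):
        lo, hi = fisher_ci(0.0, 30)
        assert lo == pytest.approx(-hi)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_ci(1.0, 30)


def bf10_grid_oracle(r, n, kappa=1.0, grid=200001):
    """Brute-force trapezoid quadrature of the stretched-beta correlation BF."""
    from scipy import special

    a = 1 / kappa
    rho = np.linspace(-1 + 1e-9, 1 - 1e-9, grid)
    prior = (1 - rho**2) ** (a - 1) / (special.beta(a, a) * 2 ** (2 * a - 1))
    c = (2 * n - 1) / 2
    like = (
        (1 - rho**2) ** ((n - 1) / 2)
        * (1 - rho * r) ** ((3 - 2 * n) / 2)
        * special.hyp2f1(0.5, 0.5, c, (rho * r + 1) / 2)
    )
    num = np.trapezoid(prior * like, rho)
    return num / special.hyp2f1(0.5, 0.5, c, (r + 1) / 2)


class TestCorrelationBF:
    def test_symmetry_in_sign(self):
        for method in ("jzs", "stretched-beta"):
            assert correlation_bf10(0.4, 30, method) == pytest.approx(
                correlation_bf10(-0.4, 30, method), rel=1e-6
            )

    @pytest.mark.parametrize("r,n", [(0.1, 20), (0.49, 42), (-0.7, 60), (0.9, 15)])
    def test_stretched_beta_matches_grid_oracle(self, r, n):
        assert correlation_bf10(r, n, "stretched-beta") == pytest.approx(
            bf10_grid_oracle(r, n), rel=0.01
        )

    @pytest.mark.parametrize("r,n", [(0.3, 25), (0.49, 42), (-0.47, 42)])
    def test_stretched_beta_matches_pingouin(self, r, n):
        import pingouin as pg

        assert correlation_bf10(r, n, "stretched-beta") == pytest.approx(
            float(pg.bayesfactor_pearson(r, n)), rel=0.01
        )

    @pytest.mark.parametrize(
        "r, expected",
        [(0.49, 25.97), (0.40, 3.37)],
    )
    def test_jzs_reproduces_reference_values(self, r, expected):
        assert correlation_bf10(r, 42) == pytest.approx(expected, rel=0.10)

    def test_correlate_bundles_everything(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = correlate(x, y)
        assert res.ci_low <= res.r <= res.ci_high
        assert res.bf10 > 0
        assert res.n == 40


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self):
        x = [1.0, 2, 3, 4, 5, 6]
        y = [2.0, 1, 4, 3, 6, 5]
        assert partial_correlation(x, y, []) == pytest.approx(pearson_r(x, y))

    def test_covariate_explains_association(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=200)
        x = c + 0.1 * rng.normal(size=200)
        y = c + 0.1 * rng.normal(size=200)
        r_raw, _ = pearson_r(x, y)
        r_part, _ = partial_correlation(x, y, [c])
        assert r_raw > 0.9
        assert abs(r_part) < 0.3

    def test_matches_correlation_matrix_inversion_oracle(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(50, 3))
        data[:, 1] += 0.5 * data[:, 0]
        data[:, 2] += 0.3 * data[:, 0] - 0.4 * data[:, 1]
        x, y, z = data.T
        r_part, _ = partial_correlation(x, y, [z])
        prec = np.linalg.inv(np.corrcoef(data.T))
        oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert r_part == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "y", "z"])
        res = pg.partial_corr(data=df, x="x", y="y", covar="z")
        r_part, p = partial_correlation(df["x"], df["y"], [df["z"]])
        assert r_part == pytest.approx(float(res["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(res["p_val"].iloc[0]), abs=1e-9)

    def test_collinear_covariates_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            partial_correlation(x, x[::-1], [np.ones(10), 2 * np.ones(10)])


def standardized(n, rng=None):
    z = (rng or np.random.default_rng(0)).normal(size=n)
    z = z - z.mean()
    return z / z.std(ddof=1)


class TestTTests:
    def test_balanced_one_sample_t_zero_bf_below_one(self):
        a = 5.0 + standardized(12)  # mean exactly mu0
        res = ttest_with_bf(a, mode="one_sample", mu0=5.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.bf10 < 1
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_constant_paired_difference_rejected(self):
        a = np.arange(10.0)
        with pytest.raises(ValueError):
            ttest_with_bf(a, a + 1.0, mode="paired")

    def test_paired_reference_bayes_factor(self):
        # 18 pairs constructed so t = 2.54 exactly; reference BF ~= 2.84
        z = standardized(18)
        diff = 2.54 / np.sqrt(18) + z
        res = ttest_with_bf(diff, np.zeros(18), mode="paired")
        assert res.statistic == pytest.approx(2.54, abs=1e-9)
        assert res.df == (17.0,)
        assert res.bf10 == pytest.approx(2.84, rel=0.10)

    def test_independent_matches_pingouin_bf(self):
        import pingouin as pg

        rng = np.random.default_rng(6)
        a = rng.normal(0.8, 1, 9)
        b = rng.normal(0, 1, 10)
        res = ttest_with_bf(a, b, mode="independent")
        oracle = float(
            pg.bayesfactor_ttest(res.statistic, 9, 10, paired=False, r=np.sqrt(2) / 2)
        )
        assert res.bf10 == pytest.approx(oracle, rel=0.01)
        # classical parts against scipy
        t, p = stats.ttest_ind(a, b)
        assert res.statistic == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_cohens_d_pooled_definition(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        res = ttest_with_bf(a, b, mode="independent")
        assert res.effect_size == pytest.approx(-1.0)


def mixed_anova_oracle(values, groups, conds, subjects):
    """Balanced 2x2 mixed-design sums of squares, computed from scratch."""
    import pandas as pd

    df = pd.DataFrame({"v": values, "g": groups, "c": conds, "s": subjects})
    grand = df["v"].mean()
    subj = df.groupby("s").agg(v=("v", "mean"), g=("g", "first"))
    n_cond = df["c"].nunique()
    ss_between_subj = n_cond * ((subj["v"] - grand) ** 2).sum()
    ss_group = sum(
        n_cond * len(sub) * (sub["v"].mean() - grand) ** 2
        for _, sub in subj.groupby("g")
    )
    ss_subj_within = ss_between_subj - ss_group
    ss_total = ((df["v"] - grand) ** 2).sum()
    ss_within_subj = ss_total - ss_between_subj
    ss_cond = sum(
        len(sub) * (sub["v"].mean() - grand) ** 2 for _, sub in df.groupby("c")
    )
    cell = df.groupby(["g", "c"])["v"].mean()
    ss_cells = sum(
        len(df[(df.g == g) & (df.c == c)]) * (cell[g, c] - grand) ** 2
        for g, c in cell.index
    )
    ss_inter = ss_cells - ss_group - ss_cond
    ss_err_within = ss_within_subj - ss_cond - ss_inter
    n_subj = subj.shape[0]
    n_groups = df["g"].nunique()
    df_group, df_subj = n_groups - 1, n_subj - n_groups
    df_cond = n_cond - 1
    df_err = df_subj * df_cond
    f_group = (ss_group / df_group) / (ss_subj_within / df_subj)
    f_cond = (ss_cond / df_cond) / (ss_err_within / df_err)
    f_inter = (ss_inter / (df_group * df_cond)) / (ss_err_within / df_err)
    return f_group, f_cond, f_inter


class TestOmnibus:
    def test_identical_groups_flat(self):
        a = np.array([1.0, 2, 3, 4, 5])
        res = omnibus_group_tests(np.r_[a, a], np.r_[["x"] * 5, ["y"] * 5])
        assert res["anova"].statistic == pytest.approx(0.0, abs=1e-12)
        assert res["kruskal"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_mixed_design_matches_ss_oracle(self):
        rng = np.random.default_rng(8)
        n_per_group = 6
        subjects = np.repeat([f"s{i}" for i in range(2 * n_per_group)], 2)
        groups = np.repeat(["low"] * n_per_group + ["high"] * n_per_group, 2)
        conds = np.tile(["neutral", "max"], 2 * n_per_group)
        values = rng.normal(size=subjects.size) + (groups == "low") * 0.5
        res = omnibus_group_tests(values, groups, conds, subject_ids=subjects)
        fg, fc, fi = mixed_anova_oracle(values, groups, conds, subjects)
        assert res["group"].statistic == pytest.approx(fg, rel=1e-6)
        assert res["condition"].statistic == pytest.approx(fc, rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(fi, rel=1e-6)

    def test_fully_between_matches_ss_oracle(self):
        rng = np.random.default_rng(9)
        groups = np.repeat(["a", "b"], 6)
        conds = np.tile(np.repeat(["x", "y"], 3), 2)
        values = rng.normal(size=12)
        res = omnibus_group_tests(values, groups, conds, design="between")
        # brute-force two-way SS decomposition on the balanced design
        import itertools

        grand = values.mean()
        ss_a = sum(6 * (values[groups == g].mean() - grand) ** 2 for g in "ab")
        ss_b = sum(6 * (values[conds == c].mean() - grand) ** 2 for c in "xy")
        ss_cells = sum(
            3 * (values[(groups == g) & (conds == c)].mean() - grand) ** 2
            for g, c in itertools.product("ab", "xy")
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(
            ((values[(groups == g) & (conds == c)]
              - values[(groups == g) & (conds == c)].mean()) ** 2).sum()
            for g, c in itertools.product("ab", "xy")
        )
        ms_err = ss_err / 8
        assert res["group"].statistic == pytest.approx(ss_a / ms_err, rel=1e-9)
        assert res["condition"].statistic == pytest.approx(ss_b / ms_err, rel=1e-9)
        assert res["interaction"].statistic == pytest.approx(ss_ab / ms_err, rel=1e-9)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            omnibus_group_tests(
                np.arange(6.0),
                ["a", "a", "a", "b", "b", "b"],
                ["x", "x", "x", "x", "x", "y"],
                subject_ids=list("pqrstu"),
            )


class TestAncova:
    def test_orthogonal_covariate_preserves_contrast(self):
        rng = np.random.default_rng(10)
        groups = np.repeat(["a", "b"], 20)
        y = rng.normal(size=40) + (groups == "b") * 0.8
        cov = np.tile([-1.0, 1.0], 20)  # orthogonal to group and noise-free of y
        y = y - np.polyval(np.polyfit(cov, y, 1), cov) + y.mean()  # force orthogonality
        res = ancova_adjusted_comparison(y, groups, [cov])
        t_plain = stats.ttest_ind(y[groups == "a"], y[groups == "b"])
        assert res["a vs b"].statistic == pytest.approx(t_plain.statistic, rel=0.05)

    def test_covariate_absorbs_group_difference(self):
        rng = np.random.default_rng(11)
        groups = np.repeat(["a", "b"], 25)
        c = rng.normal(size=50) + (groups == "b") * 2.0
        y = 1.5 * c + 0.01 * rng.normal(size=50)
        res = ancova_adjusted_comparison(y, groups, [c])
        assert abs(res["a vs b"].statistic) < 2.5
        assert res["group"].p > 0.001

    def test_three_group_fixture_matches_ols_oracle(self):
        rng = np.random.default_rng(12)
        groups = np.repeat(["a", "b", "c"], 10)
        cov = rng.normal(size=30)
        y = rng.normal(size=30) + 0.7 * cov + (groups == "c") * 1.2
        res = ancova_adjusted_comparison(y, groups, [cov])
        # normal-equations oracle for the b-vs-c adjusted contrast
        X = np.column_stack(
            [np.ones(30), groups == "b", groups == "c", cov]
        ).astype(float)
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        resid = y - X @ beta
        s2 = resid @ resid / (30 - 4)
        covb = s2 * np.linalg.inv(X.T @ X)
        contrast = np.array([0, 1.0, -1.0, 0])
        t_oracle = (contrast @ beta) / np.sqrt(contrast @ covb @ contrast)
        assert res["b vs c"].statistic == pytest.approx(t_oracle, rel=1e-9)

    def test_collinear_design_rejected(self):
        groups = np.repeat(["a", "b"], 10)
        with pytest.raises(ValueError):
            ancova_adjusted_comparison(
                np.arange(20.0), groups, [(groups == "a").astype(float)]
            )


class TestGrouping:
    def test_one_to_eight_quartiles(self):
        ga = quartile_groups(np.arange(1, 9), ids=np.arange(1, 9))
        assert set(ga.low_ids) == {1, 2}
        assert set(ga.high_ids) == {7, 8}

    def test_reference_distribution_thresholds(self):
        from goalplane.simdata import SimCohortConfig, build_cohort_profiles

        cfg = SimCohortConfig(n_participants=1000, aq_mean=17, aq_sd=6, master_seed=5)
        aq = np.array([p.aq for p in build_cohort_profiles(cfg)])
        ga = quartile_groups(aq)
        assert ga.thresholds[0] == pytest.approx(12.75, abs=1.5)
        assert ga.thresholds[1] == pytest.approx(22, abs=1.5)

    def test_degenerate_scores_flagged(self):
        ga = quartile_groups(np.full(10, 3.0))
        assert ga.degenerate

    def test_median_split_partitions(self):
        ga = quartile_groups(np.arange(9.0), scheme="median")
        assert len(ga.low_ids) + len(ga.high_ids) == 9
        assert set(ga.low_ids).isdisjoint(ga.high_ids)


class TestJarqueBera:
    def test_matches_moment_oracle_on_small_fixture(self):
        x = np.array([1.0, 2.0, 2.5, 3.0, 4.5, 9.0, 2.2, 3.3])
        res = jarque_bera(x)
        jb_scipy, p_scipy = stats.jarque_bera(x)
        assert res.statistic == pytest.approx(jb_scipy, rel=1e-10)
        assert res.p == pytest.approx(p_scipy, rel=1e-10)

    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(13).normal(size=1000)
        assert jarque_bera(x).p > 0.05

    def test_skewed_sample_rejected(self):
        x = np.random.default_rng(14).exponential(size=500)
        assert jarque_bera(x).p < 0.05


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])

    def test_step_down_enumeration(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_ties_all_scaled_by_m(self):
        assert holm_adjust([0.05, 0.05, 0.05]) == pytest.approx([0.15, 0.15, 0.15])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


def test_mixed_anova_interaction_p_uniform_under_null():
    """Interaction p-values are uniform when no effect exists (KS check)."""
    rng = np.random.default_rng(15)
    n_subj = 16
    subjects = np.repeat([f"s{i}" for i in range(n_subj)], 2)
    groups = np.repeat(["low"] * (n_subj // 2) + ["high"] * (n_subj // 2), 2)
    conds = np.tile(["a", "b"], n_subj)
    pvals = []
    for _ in range(300):
        vals = rng.normal(size=subjects.size)
        res = omnibus_group_tests(vals, groups, conds, subject_ids=subjects)
        pvals.append(res["interaction"].p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
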
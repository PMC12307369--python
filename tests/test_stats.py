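import warnings
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import glymphkit as gk
from glymphkit.stats import StatsError

warnings.filterwarnings("ignore", category=FutureWarning)


class TestNormalityGate:
    def test_normal_samples_route_parametric(self):
        # fixed seed chosen so all three Shapiro p-values sit well above
        # the 0.05 gate (any given draw can fail by chance)
        rng = np.random.default_rng(2)
        vals = rng.normal(size=300)
        groups = np.repeat(["a", "b", "c"], 100)
        assert gk.normality_gate(vals, groups) == "parametric"

    def test_lognormal_group_routes_nonparametric(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(size=100), rng.lognormal(0, 1.5, 100)])
        groups = np.repeat(["a", "b"], 100)
        assert gk.normality_gate(vals, groups) == "nonparametric"

    def test_constant_group_routes_nonparametric(self):
        vals = np.concatenate([np.full(10, 2.0), np.random.default_rng(2).normal(size=10)])
        groups = np.repeat(["a", "b"], 10)
        assert gk.normality_gate(vals, groups) == "nonparametric"

    def test_tiny_group_rejected(self):
        with pytest.raises(StatsError):
            gk.normality_gate([1.0, 2.0, 3.0, 4.0], ["a", "a", "a", "b"])


class TestKruskalDunn:
    def test_symmetric_ranks_give_h_zero_p_one(self):
        vals = [1, 2, 3, 1, 2, 3, 1, 2, 3]
        groups = np.repeat(["a", "b", "c"], 3)
        res = gk.kruskal_dunn(vals, groups)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_overall == pytest.approx(1.0)

    def test_h_matches_hand_computed_rank_statistic(self):
        # groups {1,2,3},{4,5,6},{7,8,9}: rank sums 6, 15, 24, no ties
        # H = 12/(9*10) * (36/3 + 225/3 + 576/3) - 3*10 = 7.2
        res = gk.kruskal_dunn([1, 2, 3, 4, 5, 6, 7, 8, 9], np.repeat(list("abc"), 3))
        assert res.statistic == pytest.approx(7.2)

    @pytest.mark.parametrize("trial", range(4))
    def test_small_n_p_matches_exhaustive_permutation(self, trial):
        rng = np.random.default_rng(trial)
        vals = rng.normal(size=7).round(2)
        sizes = (3, 2, 2)
        labels = np.concatenate([["a"] * 3, ["b"] * 2, ["c"] * 2])

        def h_of(order):
            v = vals[list(order)]
            return sps.kruskal(v[:3], v[3:5], v[5:]).statistic

        h_obs = h_of(range(7))
        hs = np.array([h_of(p) for p in permutations(range(7))])
        p_exact = float(np.mean(hs >= h_obs - 1e-12))
        res = gk.kruskal_dunn(vals, labels)
        assert abs(res.p_overall - p_exact) < 0.02

    def test_h_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=60)
        groups = np.repeat(["a", "b", "c"], 20)
        h1 = gk.kruskal_dunn(vals, groups).statistic
        h2 = gk.kruskal_dunn(np.exp(vals), groups).statistic
        h3 = gk.kruskal_dunn(vals**3, groups).statistic
        assert h1 == pytest.approx(h2) == pytest.approx(h3)

    def test_dunn_pairwise_ps_valid_and_adjusted(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30),
                               rng.normal(4, 1, 30)])
        groups = np.repeat(["a", "b", "c"], 30)
        res = gk.kruskal_dunn(vals, groups)
        assert len(res.pairwise) == 3
        assert all(0 <= p <= 1 for p in res.pairwise.values())
        assert res.pairwise[("a", "c")] < res.pairwise[("a", "b")]

    def test_identical_values_rejected(self):
        with pytest.raises(StatsError):
            gk.kruskal_dunn(np.ones(12), np.repeat(["a", "b", "c"], 4))


class TestAncova:
    def test_two_groups_no_covariates_f_is_t_squared(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
        t, _ = sps.ttest_ind(a, b)
        res = gk.ancova_bonferroni(
            np.concatenate([a, b]), np.repeat(["a", "b"], [40, 35])
        )
        assert res.statistic == pytest.approx(t**2, rel=1e-9)

    def test_no_covariates_equals_one_way_anova(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=90)
        groups = np.repeat(["a", "b", "c"], 30)
        res = gk.ancova_bonferroni(vals, groups)
        f, p = sps.f_oneway(vals[:30], vals[30:60], vals[60:])
        assert res.statistic == pytest.approx(f, rel=1e-9)
        assert res.p_overall == pytest.approx(p, rel=1e-9)

    def test_matches_pingouin_ancova(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        n = 120
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "grp": rng.choice(["a", "b", "c"], n),
                "cov": rng.normal(size=n),
            }
        )
        df["y"] += 0.8 * df["cov"] + (df["grp"] == "c") * 0.5
        res = gk.ancova_bonferroni(df["y"], df["grp"], df[["cov"]])
        ref = pingouin.ancova(data=df, dv="y", between="grp", covar="cov")
        assert res.statistic == pytest.approx(
            float(ref.loc[ref.Source == "grp", "F"].iloc[0]), rel=1e-6
        )

    def test_type_one_error_calibrated_under_null(self):
        # equal group means, strong covariate effect: rejection rate at
        # alpha = 0.05 should sit in [0.03, 0.07] over 2,000 replicates
        rng = np.random.default_rng(10)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            n = 300
            groups = rng.integers(0, 3, n).astype(str)
            cov = rng.normal(size=n)
            y = 2.0 * cov + rng.normal(size=n)
            res = gk.ancova_bonferroni(y, groups, pd.DataFrame({"c": cov}))
            rejections += res.p_overall < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_against_one_sd_offset(self):
        # planted 1-SD group-mean offset at n = 50/group: > 90% rejections
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 500
        for _ in range(reps):
            y = np.concatenate(
                [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(1, 1, 50)]
            )
            groups = np.repeat(["a", "b", "c"], 50)
            res = gk.ancova_bonferroni(y, groups)
            rejections += res.p_overall < 0.05
        assert rejections / reps > 0.9

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(12)
        n = 60
        cov = rng.normal(size=n)
        covs = pd.DataFrame({"c1": cov, "c2": 2 * cov})
        with pytest.raises(StatsError, match="rank deficient"):
            gk.ancova_bonferroni(rng.normal(size=n), rng.choice(["a", "b"], n), covs)


class TestPartialCorr:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = gk.partial_corr(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-6)

    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=40)
        cov = rng.normal(size=(40, 2))
        res = gk.partial_corr(x, x, cov)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_matches_inverse_correlation_matrix_formula(self):
        # first-order partial correlation from the precision matrix:
        # r_xy.z = -P_xy / sqrt(P_xx P_yy) for P the inverse correlation
        rng = np.random.default_rng(15)
        n = 200
        z = rng.normal(size=n)
        x = 0.6 * z + rng.normal(size=n)
        y = -0.4 * z + rng.normal(size=n)
        res = gk.partial_corr(x, y, z.reshape(-1, 1))
        corr = np.corrcoef(np.column_stack([x, y, z]), rowvar=False)
        prec = np.linalg.inv(corr)
        r_formula = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert res.r == pytest.approx(r_formula, abs=1e-10)

    def test_symmetric_in_x_and_y(self):
        rng = np.random.default_rng(16)
        x, y = rng.normal(size=60), rng.normal(size=60)
        cov = rng.normal(size=(60, 3))
        assert gk.partial_corr(x, y, cov).r == pytest.approx(
            gk.partial_corr(y, x, cov).r, abs=1e-14
        )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(17)
        n = 100
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("xyzw"))
        res = gk.partial_corr(df.x, df.y, df[["z", "w"]])
        ref = pingouin.partial_corr(data=df, x="x", y="y", covar=["z", "w"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)

    def test_zero_residual_variance_rejected(self):
        z = np.arange(20.0)
        with pytest.raises(StatsError):
            gk.partial_corr(2 * z, np.random.default_rng(0).normal(size=20),
                            z.reshape(-1, 1))


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.linspace(0.1, 5, 30)
        assert gk.spearman(x, np.exp(x)).r == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        x = np.arange(20.0)
        assert gk.spearman(x, -(x**3)).r == pytest.approx(-1.0)

    def test_ties_match_hand_computed_rank_correlation(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([3.0, 1.0, 1.0, 2.0, 5.0])
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        r_hand = np.corrcoef(rx, ry)[0, 1]
        assert gk.spearman(x, y).r == pytest.approx(r_hand, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError):
            gk.spearman(np.ones(10), np.arange(10.0))


class TestChiSquare:
    def test_proportional_table_statistic_zero(self):
        stat, p = gk.chi_square_counts([[10, 20, 30], [20, 40, 60]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_statistic_twenty(self):
        stat, _ = gk.chi_square_counts([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)

    def test_null_p_roughly_uniform_over_seeds(self):
        # independent sex and group: p < 0.05 in about 5% of draws
        rng = np.random.default_rng(18)
        hits = 0
        reps = 400
        for _ in range(reps):
            sex = rng.integers(0, 2, 145)
            grp = np.repeat([0, 1, 2], [89, 24, 32])
            table = pd.crosstab(sex, grp).to_numpy()
            _, p = gk.chi_square_counts(table)
            hits += p < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            gk.chi_square_counts([[0, 0], [5, 5]])


class TestBattery:
    def test_cohort_analysis_on_default_truths(self, groups):
        df = gk.draw_cohort_truths(groups, 3)
        df = df.rename(columns={"lesion_target_volume_mm3": "epvs_total_volume",
                                "lesion_count": "epvs_total_number"})
        df["alps_mean"] = df["alps"]
        out = gk.cohort_analysis(df)
        alps_test = out["group_tests"]["alps_mean"]
        assert alps_test.p_overall < 0.05
        assert all(0 <= p <= 1 for p in alps_test.pairwise.values())
        assert out["sex_chi_square"][1] >= 0.0
        pc = out["partial_correlations"][("alps_mean", "mmse")]
        assert pc.r > 0  # better glymphatic index, better cognition
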
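import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pvl_igt import group_analysis as ga


def _two_groups(n1=20, n2=20):
    return np.array(["g1"] * n1 + ["g2"] * n2)


class TestAncova:
    def test_reduces_to_oneway_anova_without_covariates(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=45)
        g = _two_groups(22, 23)
        r = ga.ancova_group(y, g)
        F, p = stats.f_oneway(y[:22], y[22:])
        assert r.statistic == pytest.approx(F, abs=1e-10)
        assert r.p == pytest.approx(p, rel=1e-8)

    def test_hand_sums_of_squares(self):
        y = np.array([1.0, 2, 3, 3, 4, 5])
        g = _two_groups(3, 3)
        means = [y[:3].mean(), y[3:].mean()]
        ssb = 3 * sum((m - y.mean()) ** 2 for m in means)
        ssw = sum((y[:3] - means[0]) ** 2) + sum((y[3:] - means[1]) ** 2)
        F_hand = (ssb / 1) / (ssw / 4)
        r = ga.ancova_group(y, g)
        assert r.statistic == pytest.approx(F_hand, abs=1e-10)

    def test_identical_groups_zero_f(self):
        vals = np.arange(10.0)
        y = np.concatenate([vals, vals])
        cov = pd.DataFrame({"c1": np.concatenate([vals * 2, vals * 2])})
        r = ga.ancova_group(y, _two_groups(10, 10), cov)
        assert r.statistic == 0.0 and r.p == 1.0

    def test_collinear_covariate_rejected(self):
        g = _two_groups()
        cov = pd.DataFrame({"c1": (g == "g1").astype(float)})
        with pytest.raises(ValueError, match="rank deficient"):
            ga.ancova_group(np.random.default_rng(0).normal(size=40), g, cov)

    def test_study_scale_degrees_of_freedom(self):
        rng = np.random.default_rng(8)
        g = _two_groups(42, 43)
        cov = pd.DataFrame(rng.normal(size=(85, 3)), columns=list(ga.DEFAULT_COVARIATES))
        r = ga.ancova_group(rng.normal(size=85), g, cov)
        assert r.df == (1.0, 80)


class TestMixedBlockAncova:
    def test_flat_data_all_zero_f(self):
        rng = np.random.default_rng(0)
        Y = np.tile(rng.normal(size=30)[:, None], (1, 5))
        mr = ga.mixed_block_ancova(Y, _two_groups(15, 15))
        assert mr.block.statistic == 0.0 and mr.interaction.statistic == 0.0
        assert mr.block.p == 1.0

    def test_matches_pingouin_without_covariates(self):
        import pingouin as pg

        rng = np.random.default_rng(5)
        Y = rng.normal(size=(24, 5)) + np.linspace(0, 1, 5)
        g = _two_groups(12, 12)
        long = pd.DataFrame(
            {
                "y": Y.ravel(),
                "block": np.tile(np.arange(5), 24),
                "subj": np.repeat(np.arange(24), 5),
                "grp": np.repeat(g, 5),
            }
        )
        aov = pg.mixed_anova(long, dv="y", within="block", between="grp", subject="subj")
        mr = ga.mixed_block_ancova(Y, g)
        assert mr.interaction.statistic == pytest.approx(
            float(aov.loc[aov.Source == "Interaction", "F"].iloc[0]), rel=1e-8
        )
        assert mr.group.statistic == pytest.approx(
            float(aov.loc[aov.Source == "grp", "F"].iloc[0]), rel=1e-8
        )
        assert mr.block.statistic == pytest.approx(
            float(aov.loc[aov.Source == "block", "F"].iloc[0]), rel=1e-8
        )

    def test_study_scale_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        g = _two_groups(42, 43)
        cov = pd.DataFrame(rng.normal(size=(85, 3)), columns=list(ga.DEFAULT_COVARIATES))
        mr = ga.mixed_block_ancova(rng.normal(size=(85, 5)), g, cov)
        assert mr.interaction.df == (4.0, 320.0)
        assert mr.group.df == (1.0, 80)

    def test_interaction_power_when_one_group_learns(self):
        """Only one group's block means rise: the interaction is detected
        in nearly all replicates at study-scale n."""
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            Y1 = rng.normal(0, 4, size=(42, 5))  # flat group
            Y2 = rng.normal(0, 4, size=(43, 5)) + np.linspace(0, 8, 5)  # learners
            Y = np.vstack([Y1, Y2])
            mr = ga.mixed_block_ancova(Y, _two_groups(42, 43))
            hits += mr.interaction.p < 0.05
        assert hits >= 90

    def test_per_block_contrasts_tagged_bonferroni(self):
        rng = np.random.default_rng(2)
        out = ga.per_block_group_contrasts(rng.normal(size=(30, 5)), _two_groups(15, 15))
        assert len(out) == 5
        assert all(r.adjustment == "bonferroni_5" for r in out)

    def test_per_group_rm_anova_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(7)
        Y = rng.normal(size=(40, 5))
        g = _two_groups(18, 22)
        ours = ga.per_group_block_anova(Y, g)
        sub = pd.DataFrame(
            {
                "y": Y[:18].ravel(),
                "block": np.tile(np.arange(5), 18),
                "subj": np.repeat(np.arange(18), 5),
            }
        )
        aov = pg.rm_anova(sub, dv="y", within="block", subject="subj")
        assert ours[0].statistic == pytest.approx(float(aov["F"].iloc[0]), rel=1e-8)
        assert ours[0].df == (4.0, 4.0 * 17)

    def test_missing_blocks_rejected(self):
        Y = np.random.default_rng(0).normal(size=(20, 5))
        Y[3, 2] = np.nan
        with pytest.raises(ValueError):
            ga.mixed_block_ancova(Y, _two_groups(10, 10))


class TestMannWhitney:
    def test_complete_separation(self):
        assert ga.mann_whitney([1, 2, 3], [4, 5, 6]).statistic == 0.0

    def test_brute_force_pair_count(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=6)
            r = ga.mann_whitney(x, y)
            u_brute = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
            assert r.extra["u_x"] == pytest.approx(u_brute)

    def test_identical_samples_midpoint(self):
        r = ga.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.statistic == 8.0

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=15),
        st.lists(st.floats(-100, 100), min_size=1, max_size=15),
    )
    def test_u_statistics_sum_to_n1n2(self, x, y):
        r = ga.mann_whitney(x, y)
        assert r.extra["u_x"] + r.extra["u_y"] == len(x) * len(y)
        assert 0 <= r.p <= 1

    def test_exact_and_normal_p_agree_moderate_n(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            p_exact = ga.mann_whitney(x, y).p  # n1*n2 = 100 <= 400 -> exact
            z = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert abs(p_exact - z.pvalue) < 0.02


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert ga.pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert ga.pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_formula_five_points(self):
        x = np.array([1.0, 2, 4, 5, 8])
        y = np.array([2.0, 1, 5, 4, 9])
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert ga.pearson_r(x, y).statistic == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ga.pearson_r([1, 1, 1, 1], [1, 2, 3, 4])

    def test_bootstrap_degenerate_perfect_correlation(self):
        x = np.arange(20.0)
        r = ga.bootstrap_pearson(x, x, n_boot=1000, seed=0)
        assert r.extra["ci_low"] == pytest.approx(1.0)
        assert r.extra["ci_high"] == pytest.approx(1.0)

    def test_bootstrap_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r1 = ga.bootstrap_pearson(x, y, n_boot=2000, seed=5)
        r2 = ga.bootstrap_pearson(x, y, n_boot=2000, seed=5)
        assert (r1.extra["ci_low"], r1.extra["ci_high"]) == (
            r2.extra["ci_low"],
            r2.extra["ci_high"],
        )

    def test_observed_r_invariant_to_bootstrap_settings(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=25), rng.normal(size=25)
        r1 = ga.bootstrap_pearson(x, y, n_boot=1000, seed=1)
        r2 = ga.bootstrap_pearson(x, y, n_boot=3000, seed=99)
        assert r1.statistic == r2.statistic == pytest.approx(stats.pearsonr(x, y)[0])


class TestTTests:
    def test_identical_samples(self):
        x = np.arange(10.0)
        r = ga.welch_t(x, x)
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)

    def test_hand_pooled_formula(self):
        x, y = np.array([1.0, 2, 3]), np.array([3.0, 4, 5])
        sp2 = (2 * x.var(ddof=1) + 2 * y.var(ddof=1)) / 4
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        r = ga.welch_t(x, y)
        assert r.statistic == pytest.approx(t_hand, abs=1e-12)

    def test_study_scale_pooled_df(self):
        rng = np.random.default_rng(10)
        r = ga.welch_t(rng.normal(size=42), rng.normal(size=43))
        assert r.df == (83.0,)

    def test_welch_variant_df_differs(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, size=12)
        y = rng.normal(0, 5, size=40)
        r = ga.welch_t(x, y, pooled=False)
        assert r.df[0] != 50.0 and r.extra["variant"] == "welch"


class TestFullBattery:
    def test_run_standard_analysis_shapes(self, small_cohort):
        from pvl_igt import estimation as est

        seqs = small_cohort.sequences()
        tab = est.fit_mle_cohort(
            seqs, groups=small_cohort.subjects["group"].tolist(), n_starts=2, seed=0
        )
        res = ga.run_standard_analysis(
            small_cohort.scores(), tab, small_cohort.subjects, n_boot=1000, seed=0
        )
        assert res["p"].dropna().between(0, 1).all()
        assert {"ancova_total_net", "mixed_block_x_group", "mann_whitney_A"} <= set(res["test"])
        assert (res.loc[res.test.str.startswith("block"), "adjustment"] == "bonferroni_5").any()
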
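"""The statistical comparison suite: ANOVAs, post hocs, effect sizes,
correlation and regression."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given
from hypothesis import strategies as st

from primellm.errors import AnalysisError, ValidationError
from primellm.stats import (
    cles,
    hedges_g_ci,
    hedges_j,
    holm_adjust,
    mixed_linear,
    ols_model,
    oneway_anova,
    pairwise_paired_t,
    rm_anova,
    spearman_corr,
    tukey_hsd,
    two_sample,
)


class TestHolm:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ((0.01, 0.04, 0.03), (0.03, 0.06, 0.06)),
            ((1.0,), (1.0,)),
            ((0.5, 0.5), (1.0, 1.0)),
        ],
    )
    def test_hand_cases(self, pvals, expected):
        np.testing.assert_allclose(holm_adjust(pvals), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20))
    def test_bracketed_by_raw_and_bonferroni(self, pvals):
        adj = np.asarray(holm_adjust(pvals))
        raw = np.asarray(pvals)
        m = raw.size
        bonf = np.minimum(raw * m, 1.0)
        assert np.all(adj >= raw - 1e-12)
        assert np.all(adj <= bonf + 1e-12)
        # step-down: sorted raw order implies sorted adjusted order
        order = np.argsort(raw, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


def wide(a_by_cond):
    return pd.DataFrame(a_by_cond)


class TestRmAnova:
    def test_hand_decomposition(self):
        res = rm_anova(wide({"A": [1, 2, 3], "B": [3, 2, 4]}))
        assert res.ss["condition"] == pytest.approx(1.5)
        assert res.ss["subject"] == pytest.approx(3.0)
        assert res.ss["error"] == pytest.approx(1.0)
        assert res.F == pytest.approx(3.0)
        assert (res.df_num, res.df_den) == (1, 2)
        assert res.design == "within"

    def test_two_conditions_equal_paired_t_squared(self, rng):
        tbl = wide({"A": rng.normal(size=12), "B": rng.normal(size=12)})
        res = rm_anova(tbl)
        t, p = sps.ttest_rel(tbl["A"], tbl["B"])
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_constant_table_undefined(self):
        res = rm_anova(wide({"A": [2.0, 2.0, 2.0], "B": [2.0, 2.0, 2.0]}))
        assert math.isnan(res.F)

    def test_ss_identity_on_random_tables(self, rng):
        for _ in range(20):
            n, k = rng.integers(3, 10), rng.integers(2, 6)
            tbl = pd.DataFrame(rng.normal(size=(n, k)))
            ss = rm_anova(tbl).ss
            assert ss["condition"] + ss["subject"] + ss["error"] == pytest.approx(
                ss["total"], abs=1e-9
            )

    def test_matches_statsmodels_anova_rm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        n, k = 9, 4
        tbl = pd.DataFrame(rng.normal(size=(n, k)), columns=list("ABCD"))
        long = tbl.reset_index().melt(id_vars="index", var_name="cond")
        sm_res = AnovaRM(long, "value", "index", within=["cond"]).fit()
        res = rm_anova(tbl)
        assert res.F == pytest.approx(float(sm_res.anova_table["F Value"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(sm_res.anova_table["Pr > F"].iloc[0]), rel=1e-9)

    def test_missing_cells_rejected(self):
        tbl = wide({"A": [1.0, 2.0, np.nan], "B": [1.0, 2.0, 3.0]})
        with pytest.raises(AnalysisError, match="missing"):
            rm_anova(tbl)


class TestPairwisePairedT:
    def test_identical_columns(self):
        tbl = wide({"A": [1, 2, 3], "B": [1, 2, 3], "C": [1, 2, 3]})
        out = pairwise_paired_t(tbl)
        assert len(out) == 3
        assert out.method == "holm_paired_t"
        assert (out.frame["mean_difference"] == 0).all()
        assert (out.frame["p_adjusted"] == 1.0).all()

    def test_constant_shift_degenerates(self):
        out = pairwise_paired_t(wide({"A": [1, 2, 3], "B": [2, 3, 4]}))
        row = out.frame.iloc[0]
        assert math.isinf(row["t"]) and row["t"] < 0
        assert math.isnan(row["p_raw"])
        assert (row["ci_low"], row["ci_high"]) == (-1.0, -1.0)

    def test_adjustment_and_ci_invariants(self, rng):
        tbl = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("ABCD"))
        out = pairwise_paired_t(tbl).frame
        assert len(out) == 6
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()
        assert ((out["ci_low"] <= out["mean_difference"])
                & (out["mean_difference"] <= out["ci_high"])).all()


class TestOnewayAnova:
    def test_study_shape_df(self, rng):
        groups = [rng.normal(size=3) for _ in range(21)]
        res = oneway_anova(groups)
        assert (res.df_num, res.df_den) == (20, 42)
        assert res.design == "between"

    def test_two_groups_equal_pooled_t_squared(self, rng):
        a, b = rng.normal(size=8), rng.normal(1, 1, size=11)
        res = oneway_anova([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_identical_groups_f_zero(self):
        res = oneway_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == pytest.approx(0.0)

    def test_small_group_rejected(self):
        with pytest.raises(AnalysisError):
            oneway_anova([[1.0], [1.0, 2.0]])
        with pytest.raises(AnalysisError):
            oneway_anova([[1.0, 2.0]])


class TestTukeyHsd:
    def test_identical_groups(self):
        out = tukey_hsd([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert (out.frame["mean_difference"] == 0).all()
        assert np.allclose(out.frame["p_adjusted"], 1.0)

    def test_two_groups_reduce_to_pooled_t(self, rng):
        a, b = rng.normal(size=7), rng.normal(0.8, 1, size=9)
        out = tukey_hsd([a, b]).frame
        _, p = sps.ttest_ind(a, b, equal_var=True)
        assert out["p_adjusted"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_three_groups_against_monte_carlo_oracle(self, rng):
        """Adjusted p within 0.005 of a simulated studentized-range null."""
        groups = [rng.normal(0, 1, 6), rng.normal(0.5, 1, 6), rng.normal(1.2, 1, 6)]
        out = tukey_hsd(groups).frame
        k, n = 3, 6
        df_err = k * n - k
        mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_err
        # MC null draw of the studentized range statistic
        mc_rng = np.random.default_rng(123456)
        z = mc_rng.standard_normal((1_000_000, k))
        q_null = np.ptp(z, axis=1) / np.sqrt(
            mc_rng.chisquare(df_err, size=1_000_000) / df_err
        )
        for (i, j), row in zip(((0, 1), (0, 2), (1, 2)), out.itertuples()):
            q_obs = abs(groups[i].mean() - groups[j].mean()) / math.sqrt(mse / n)
            p_mc = float((q_null > q_obs).mean())
            assert row.p_adjusted == pytest.approx(p_mc, abs=0.005)

    def test_simultaneous_cis_bracket_differences(self, rng):
        groups = [rng.normal(m, 1, 5) for m in (0, 0.5, 1, 2)]
        out = tukey_hsd(groups, labels=list("wxyz")).frame
        assert ((out["ci_low"] <= out["mean_difference"])
                & (out["mean_difference"] <= out["ci_high"])).all()
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()


class TestTwoSample:
    A, B = (1.0, 2.0, 3.0), (2.0, 4.0, 6.0)

    def test_welch_hand_case(self):
        tt, es = two_sample(self.A, self.B, "welch")
        assert tt.t == pytest.approx(-1.549, abs=1e-3)
        assert tt.df == pytest.approx(50 / 17)
        assert es.d == pytest.approx(-2 / math.sqrt(2.5))
        assert es.g == pytest.approx(0.8 * es.d)
        assert es.cles == pytest.approx(1.5 / 9)

    def test_pooled_df(self):
        tt, _ = two_sample(self.A, self.B, "pooled")
        assert tt.df == 4
        assert tt.variance_mode == "pooled"

    def test_welch_df_never_exceeds_pooled(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(0, rng.uniform(0.3, 3), size=rng.integers(3, 12))
            welch, _ = two_sample(a, b, "welch")
            assert welch.df <= a.size + b.size - 2 + 1e-9

    def test_equal_n_equal_variance_welch_equals_pooled(self):
        a, b = (1.0, 2.0, 3.0, 4.0), (2.0, 3.0, 4.0, 5.0)
        assert two_sample(a, b, "welch")[0].t == pytest.approx(
            two_sample(a, b, "pooled")[0].t
        )

    def test_identical_groups(self):
        tt, es = two_sample(self.A, self.A)
        assert tt.t == 0.0
        assert es.d == es.g == 0.0
        assert es.cles == 0.5

    def test_hedges_correction_at_study_size(self):
        assert hedges_j(63) == pytest.approx(1 - 3 / 243)
        assert round(2.60 * hedges_j(63), 2) == 2.57

    def test_effect_sizes_match_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a, b = rng.normal(0.7, 0.1, 12), rng.normal(0.6, 0.15, 9)
        _, es = two_sample(a, b)
        assert es.d == pytest.approx(
            pingouin.compute_effsize(a, b, eftype="cohen"), rel=1e-9
        )
        assert es.g == pytest.approx(
            pingouin.compute_effsize(a, b, eftype="hedges"), rel=1e-9
        )
        assert es.cles == pytest.approx(
            pingouin.compute_effsize(a, b, eftype="cles"), rel=1e-9
        )

    def test_zero_variance_nonzero_shift(self):
        tt, es = two_sample((1.0, 1.0), (2.0, 2.0))
        assert math.isinf(tt.t) and tt.t < 0
        assert tt.p > 0  # bounded away from an exact zero

    def test_cles_symmetry(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=13)
        assert cles(a, b) + cles(b, a) == pytest.approx(1.0)
        assert cles(a, a) == 0.5


class TestSpearman:
    def test_monotone_and_reversed(self):
        assert spearman_corr([1, 2, 3, 5], [2, 4, 9, 11])[0] == pytest.approx(1.0)
        assert spearman_corr([1, 2, 3, 5], [11, 9, 4, 2])[0] == pytest.approx(-1.0)

    def test_hand_rank_case(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_input_undefined(self):
        rho, p = spearman_corr([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho) and math.isnan(p)


def question_frame(rng, n_questions=40, n_models=8, gamma_sd=0.0, noise_sd=0.02):
    """Question-level accuracy with known fixed effects for regression tests."""
    domains = np.resize(["DT", "DD", "FD", "M", "Q"], n_questions)
    beta = {"DT": 0.0, "DD": -0.08, "FD": 0.13, "M": 0.05, "Q": 0.08}
    gamma = rng.normal(0, gamma_sd, n_questions)
    rows = []
    for q in range(n_questions):
        for m in range(n_models):
            reasoning = m % 2
            mu = 0.6 + beta[domains[q]] + 0.04 * reasoning + gamma[q]
            rows.append(
                ("q%02d" % q, domains[q],
                 ["pediatric", "young_adult"][q % 2], ["female", "male"][(q // 2) % 2],
                 "m%d" % m, bool(reasoning),
                 float(np.clip(mu + rng.normal(0, noise_sd), 0, 1)))
            )
    return pd.DataFrame(
        rows,
        columns=["question_id", "domain", "age_group", "sex", "model_id",
                 "reasoning", "accuracy"],
    )


class TestMixedLinear:
    def test_constant_response_degenerate(self):
        df = question_frame(np.random.default_rng(0), n_questions=10, noise_sd=0.0)
        df["accuracy"] = 0.7
        res = mixed_linear(df)
        assert res.coefficients["Intercept"][0] == pytest.approx(0.7)
        assert res.random_intercept_variance == 0.0
        assert res.singular

    def test_zero_question_variance_matches_ols(self, rng):
        import statsmodels.formula.api as smf

        df = question_frame(rng, gamma_sd=0.0)
        res = mixed_linear(df)
        formula = ("accuracy ~ C(domain, Treatment('DT')) + C(age_group) "
                   "+ C(sex) + reasoning")
        ols = smf.ols(formula, df.assign(reasoning=df["reasoning"].astype(int))).fit()
        for term, (beta, *_rest) in res.coefficients.items():
            assert beta == pytest.approx(ols.params[term], abs=1e-6)

    def test_out_of_range_accuracy_rejected(self, rng):
        df = question_frame(rng, n_questions=10)
        df.loc[0, "accuracy"] = 1.2
        with pytest.raises(ValidationError):
            mixed_linear(df)

    def test_recovers_domain_effect_signs(self, rng):
        df = question_frame(rng, gamma_sd=0.05)
        res = mixed_linear(df)
        pref = "C(domain, Treatment('DT'))[T."
        assert res.coefficients[pref + "DD]"][0] < 0
        for d in ("FD", "M", "Q"):
            assert res.coefficients[pref + d + "]"][0] > 0
        assert res.random_intercept_variance > 0


class TestOls:
    def test_exact_linear_relation(self):
        df = pd.DataFrame({"x": [0.0, 1, 2, 3, 4], "prime_score": [0.0, 2, 4, 6, 8]})
        res = ols_model(df, response="prime_score", predictors=("x",))
        assert res.coefficients["x"][0] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_binary_factor_is_difference_in_means(self):
        df = pd.DataFrame({
            "reasoning": [True] * 3 + [False] * 3,
            "prime_score": [0.76, 0.76, 0.76, 0.67, 0.67, 0.67],
        })
        res = ols_model(df)
        assert res.coefficients["reasoning"][0] == pytest.approx(0.09)

    def test_null_ci_coverage_near_nominal(self, rng):
        covered = 0
        reps = 200
        for _ in range(reps):
            df = pd.DataFrame({
                "x": rng.normal(size=20),
                "prime_score": rng.normal(size=20),
            })
            _, lo, hi, _ = ols_model(df, predictors=("x",)).coefficients["x"]
            covered += lo <= 0 <= hi
        assert 0.90 <= covered / reps <= 0.99

    def test_collinear_design_named(self):
        df = pd.DataFrame({
            "x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8], "prime_score": [1.0, 2, 3, 4],
        })
        with pytest.raises(AnalysisError, match="y"):
            ols_model(df, predictors=("x", "y"))
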
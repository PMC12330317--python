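"""Statistical stages: multilevel model, ANOVAs, correlations, t tests."""

import numpy as np
import pandas as pd
import pytest

from vpcue.inference import (
    CollinearityError,
    InferenceError,
    compute_vifs,
    fit_sai_recalibration_model,
    group_comparison,
    one_sample_t,
    pearson_r,
    predictor_residuals,
    rm_anova_2x2,
)


def _model_table(n=20, seed=0, slope_p_conflict=1.8, noise=5.0, re_sd=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n):
        u = rng.normal(0, re_sd)
        for session in ("conflict", "veridical"):
            rp, rv = rng.normal(10, 5), rng.normal(30, 8)
            dsai = 100.0 + u + rng.normal(0, noise)
            if session == "conflict":
                dsai += slope_p_conflict * rp
            rows.append(
                dict(participant=pid, session=session, delta_sai=dsai,
                     recal_p=rp, recal_v=rv)
            )
    return pd.DataFrame(rows)


class TestSaiModel:
    def test_constant_outcome_gives_zero_slopes(self):
        table = _model_table(noise=0.0, slope_p_conflict=0.0)
        fit = fit_sai_recalibration_model(table)
        assert fit.term("intercept").beta == pytest.approx(100.0, abs=1e-6)
        for name in ("conflict:recal_p", "conflict:recal_v",
                     "veridical:recal_p", "veridical:recal_v"):
            assert fit.term(name).beta == pytest.approx(0.0, abs=1e-6)

    def test_matches_ols_oracle_without_participant_variance(self):
        import statsmodels.api as sm

        table = _model_table(n=30, seed=3, re_sd=0.0)
        fit = fit_sai_recalibration_model(table)
        X = pd.DataFrame(index=table.index)
        for session in ("veridical", "conflict"):
            m = (table.session == session).astype(float)
            X[f"{session}:recal_p"] = m * table.recal_p
            X[f"{session}:recal_v"] = m * table.recal_v
        ols = sm.OLS(table.delta_sai, sm.add_constant(X)).fit()
        for name, expected in zip(
            ["intercept", "veridical:recal_p", "veridical:recal_v",
             "conflict:recal_p", "conflict:recal_v"],
            ols.params,
        ):
            assert fit.term(name).beta == pytest.approx(expected, abs=1e-5)

    def test_residual_df_convention(self):
        fit = fit_sai_recalibration_model(_model_table(n=22))
        assert fit.n_observations == 44
        assert fit.term("conflict:recal_p").df == 39  # 44 observations - 5 terms

    def test_recovers_generative_slope(self):
        fit = fit_sai_recalibration_model(_model_table(n=200, seed=1, re_sd=8.0))
        t = fit.term("conflict:recal_p")
        assert t.beta == pytest.approx(1.8, abs=0.2)
        assert fit.term("veridical:recal_p").ci_low < 0 < fit.term("veridical:recal_p").ci_high

    def test_incomplete_participants_dropped_with_warning(self):
        table = _model_table(n=6).iloc[:-1]  # last participant misses a session
        with pytest.warns(UserWarning):
            fit = fit_sai_recalibration_model(table)
        assert fit.n_participants == 5

    def test_ci_brackets_beta(self):
        fit = fit_sai_recalibration_model(_model_table(n=15, seed=2))
        for t in fit.terms:
            assert t.ci_low <= t.beta <= t.ci_high


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        vifs = compute_vifs(X)
        assert vifs["a"] == pytest.approx(1.0)
        assert vifs["b"] == pytest.approx(1.0)

    def test_duplicated_predictor_raises(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(CollinearityError):
            compute_vifs(X)


class TestPredictorResiduals:
    def test_orthogonal_other_returns_centered_target(self):
        table = pd.DataFrame({"t": [1.0, 2, 3, 4], "o": [1.0, -1, -1, 1]})
        res = predictor_residuals(table, "t", "o")["t_resid"]
        np.testing.assert_allclose(res, [-1.5, -0.5, 0.5, 1.5])

    def test_fully_explained_target_gives_zero_residuals(self):
        table = pd.DataFrame({"t": [2.0, 4, 6], "o": [1.0, 2, 3]})
        res = predictor_residuals(table, "t", "o")["t_resid"]
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_known_error_recovered(self):
        rng = np.random.default_rng(0)
        o = rng.normal(0, 1, 50)
        e = rng.normal(0, 1, 50)
        table = pd.DataFrame({"t": o + e, "o": o})
        res = predictor_residuals(table, "t", "o")["t_resid"].to_numpy()
        import statsmodels.api as sm

        expected = sm.OLS(e, sm.add_constant(o)).fit().resid
        np.testing.assert_allclose(res, expected, atol=1e-9)

    def test_zero_variance_other_centers_target(self):
        table = pd.DataFrame({"t": [1.0, 2, 3], "o": [5.0, 5, 5]})
        res = predictor_residuals(table, "t", "o")["t_resid"]
        np.testing.assert_allclose(res, [-1, 0, 1])


def _long_2x2(cells, noise_sd=0.0, n=6, seed=0):
    """cells: {(a, b): mean}; adds a per-participant additive offset."""
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n):
        offset = rng.normal(0, 3)
        for (a, b), mu in cells.items():
            rows.append(
                dict(participant=pid, A=a, B=b,
                     value=mu + offset + rng.normal(0, noise_sd))
            )
    return pd.DataFrame(rows)


def _anova_ss_oracle(df):
    """Textbook sums-of-squares decomposition for a 2x2 within design."""
    cells = df.pivot_table(index="participant", columns=["A", "B"], values="value")
    n = len(cells)
    grand = cells.to_numpy().mean()
    out = {}
    for effect, signs in (
        ("A", {(0, 0): -1, (0, 1): -1, (1, 0): 1, (1, 1): 1}),
        ("B", {(0, 0): -1, (0, 1): 1, (1, 0): -1, (1, 1): 1}),
        ("interaction", {(0, 0): 1, (0, 1): -1, (1, 0): -1, (1, 1): 1}),
    ):
        levels_a = sorted(df.A.unique())
        levels_b = sorted(df.B.unique())
        contrast = sum(
            signs[(i, j)] * cells[(levels_a[i], levels_b[j])]
            for i in (0, 1) for j in (0, 1)
        ) / 2.0
        ss_effect = n * contrast.mean() ** 2
        ss_error = ((contrast - contrast.mean()) ** 2).sum()
        out[effect] = (ss_effect / 1) / (ss_error / (n - 1))
    return out


class TestRmAnova:
    def test_identical_cells_give_zero_f(self):
        df = _long_2x2({(a, b): 10.0 for a in "xy" for b in "uv"})
        res = rm_anova_2x2(df, "participant", "A", "B", "value")
        for r in res.values():
            assert r.statistic == pytest.approx(0.0, abs=1e-20)

    def test_pure_main_effect_has_zero_interaction(self):
        df = _long_2x2({("x", "u"): 0, ("x", "v"): 0, ("y", "u"): 5, ("y", "v"): 5})
        res = rm_anova_2x2(df, "participant", "A", "B", "value")
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-18)
        assert res["A"].p < 1e-6

    def test_matches_sums_of_squares_oracle(self):
        df = _long_2x2(
            {("x", "u"): 1.0, ("x", "v"): 3.0, ("y", "u"): 2.0, ("y", "v"): 7.0},
            noise_sd=2.0, n=5, seed=4,
        )
        res = rm_anova_2x2(df, "participant", "A", "B", "value")
        oracle = _anova_ss_oracle(df)
        for effect in ("A", "B", "interaction"):
            assert res[effect].statistic == pytest.approx(oracle[effect], abs=1e-9)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        df = _long_2x2(
            {("x", "u"): 1.0, ("x", "v"): 3.5, ("y", "u"): 2.0, ("y", "v"): 7.0},
            noise_sd=2.0, n=8, seed=5,
        )
        res = rm_anova_2x2(df, "participant", "A", "B", "value")
        pg = pingouin.rm_anova(
            data=df, dv="value", within=["A", "B"], subject="participant", detailed=True
        ).set_index("Source")
        assert res["A"].statistic == pytest.approx(pg.loc["A", "F"], rel=1e-6)
        assert res["B"].statistic == pytest.approx(pg.loc["B", "F"], rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(pg.loc["A * B", "F"], rel=1e-6)

    def test_missing_cells_rejected(self):
        df = _long_2x2({(a, b): 1.0 for a in "xy" for b in "uv"}).iloc[:-1]
        with pytest.raises(InferenceError):
            rm_anova_2x2(df, "participant", "A", "B", "value")


class TestGroupComparison:
    def test_equal_group_means_give_zero_f(self):
        values = np.array([1.0, 2, 3, 3, 2, 1, 2, 1, 3])
        groups = np.repeat(["a", "b", "c"], 3)
        res = group_comparison(values, groups, "anova_tukey")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pairwise is None

    def test_hand_computed_f(self):
        values = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9])
        groups = np.repeat(["a", "b", "c"], 3)
        # SS_between = 3*((2-5)^2 + 0 + (8-5)^2) = 54; MS_b = 27
        # SS_within = 3 groups * 2 each; MS_w = 6/6 = 1 -> F = 27
        res = group_comparison(values, groups, "anova_tukey")
        assert res.statistic == pytest.approx(27.0, abs=1e-9)
        assert res.effect_size == pytest.approx(54.0 / 60.0)
        assert res.df == (2.0, 6.0)

    def test_tukey_table_on_significant_omnibus(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                                 rng.normal(5, 1, 10)])
        groups = np.repeat(["a", "b", "c"], 10)
        res = group_comparison(values, groups, "anova_tukey")
        assert res.p < 0.05
        assert res.pairwise is not None and len(res.pairwise) == 3

    def test_kruskal_wallis_path(self):
        values = np.array([1.0, 2, 3, 10, 11, 12, 20, 21, 22])
        groups = np.repeat(["a", "b", "c"], 3)
        res = group_comparison(values, groups, "kruskal_wallis")
        assert res.method == "kruskal_wallis"
        assert res.p < 0.05

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(InferenceError):
            group_comparison(np.arange(6.0), np.repeat(["a", "b"], 3))


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_r(x, x).statistic == pytest.approx(1.0)
        assert pearson_r(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        res = pearson_r([1, 2, 3], [2, 1, 3])
        assert res.statistic == pytest.approx(0.5)
        assert res.df == 1

    def test_zero_variance_rejected(self):
        with pytest.raises(InferenceError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestOneSampleT:
    def test_symmetric_values_give_zero(self):
        res = one_sample_t([-2.0, -1.0, 1.0, 2.0], 0.0)
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_t(self):
        res = one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-3)
        assert res.df == 2

    def test_cohens_d_sign_follows_mean(self):
        assert one_sample_t([1.0, 2.0, 3.0], 0.0).effect_size > 0
        assert one_sample_t([1.0, 2.0, 3.0], 10.0).effect_size < 0

    def test_zero_sd_rejected(self):
        with pytest.raises(InferenceError):
            one_sample_t([3.0, 3.0, 3.0])
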
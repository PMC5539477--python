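"""OLS, stepwise variable selection, the four EE model families, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from wearhrv.ee import (
    MODEL_SPECS,
    EEModelSpec,
    anova_2x2,
    evaluate_ee,
    fit_ee,
    ols_fit,
    rmse_cells,
    run_ee,
    select_variables,
)
from wearhrv.generate import simulate_minute_table, table7_style_static_model
from wearhrv.recognition import Fold, loso_folds

from oracles import anova_2x2_oracle, ols_normal_equations_oracle


class TestOLS:
    def test_exact_line_recovered(self):
        x = np.arange(5.0)
        model = ols_fit(x.reshape(-1, 1), 1.0 + 2.0 * x, ["x"])
        np.testing.assert_allclose(model.coef, [1.0, 2.0], atol=1e-12)
        assert model.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_closed_form(self, rng):
        X = rng.normal(size=(50, 5))
        beta = np.array([0.5, 1.0, -2.0, 0.0, 3.0, -1.0])
        y = beta[0] + X @ beta[1:]
        model = ols_fit(X, y)
        design = np.column_stack([np.ones(50), X])
        ref = ols_normal_equations_oracle(design, y)
        np.testing.assert_allclose(model.coef, ref, atol=1e-9)
        np.testing.assert_allclose(model.coef, beta, atol=1e-9)

    def test_residual_orthogonality(self, rng):
        X = rng.normal(size=(60, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 2.0]) + rng.normal(size=60)
        model = ols_fit(X, y)
        design = np.column_stack([np.ones(60), X])
        resid = y - design @ model.coef
        np.testing.assert_allclose(design.T @ resid, 0.0, atol=1e-8)

    def test_inference_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(40, 3))
        y = 1.0 + X @ np.array([2.0, 0.0, -1.0]) + rng.normal(size=40)
        mine = ols_fit(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(mine.coef, ref.params, atol=1e-10)
        np.testing.assert_allclose(mine.stderr, ref.bse, atol=1e-10)
        np.testing.assert_allclose(mine.pvalues, ref.pvalues, atol=1e-10)
        assert mine.r_squared == pytest.approx(ref.rsquared)

    def test_duplicated_column_names_rank_deficiency(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.column_stack([x, x])
        with pytest.raises(ValueError, match="rank deficient"):
            ols_fit(X, rng.normal(size=20), ["a", "a_copy"])


class TestSelectVariables:
    @staticmethod
    def _planted(rng, n=500, k=10, support=(0, 3, 7), noise=1.0):
        X = rng.normal(size=(n, k))
        beta = np.zeros(k)
        for i in support:
            beta[i] = 1.0
        y = X @ beta + noise * rng.normal(size=n)
        cols = [f"v{i}" for i in range(k)]
        df = pd.DataFrame(X, columns=cols)
        df["ee_kcal_min"] = y
        return df, cols, {f"v{i}" for i in support}

    def test_recovers_planted_support(self):
        """Backward elimination retains the three true predictors in nearly
        every replicate; exact recovery (no surviving false positive) is
        bounded by (1-alpha)^7 ~ 0.70 with seven null candidates, so the
        exact-match rate is asserted against that binomial expectation."""
        contains = exact = 0
        for seed in range(100):
            df, cols, truth = self._planted(np.random.default_rng(seed))
            kept = set(select_variables(df, cols))
            contains += kept >= truth
            exact += kept == truth
        assert contains >= 95
        assert 50 <= exact <= 88

    def test_pure_noise_survivors_near_alpha_rate(self):
        """Under the global null each variable survives the final p < 0.05
        test at roughly the nominal rate."""
        survived = total = 0
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            df, cols, _ = self._planted(rng, n=200, support=(), noise=1.0)
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                kept = select_variables(df, cols)
            survived += len(kept)
            total += len(cols)
        rate = survived / total
        assert 0.005 <= rate <= 0.10

    def test_elimination_to_empty_warns(self, rng):
        df, cols, _ = self._planted(rng, n=100, k=3, support=(), noise=1.0)
        with pytest.warns(UserWarning, match="intercept-only"):
            kept = select_variables(df, cols[:1])
        assert kept == [] or len(kept) <= 1

    def test_forward_direction_agrees_on_strong_signal(self, rng):
        df, cols, truth = self._planted(rng, noise=0.5)
        assert set(select_variables(df, cols, direction="forward")) == truth


class TestFitEvaluate:
    def test_candidate_pool_sizes(self):
        assert len(MODEL_SPECS[0].candidates()) == 6     # anthropometrics + IMU
        assert len(MODEL_SPECS[1].candidates()) == 37    # + 31 HRV

    def test_activity_specific_runs_fit_26_models(self, fast_table):
        rep = run_ee(fast_table, MODEL_SPECS[3])
        assert rep.n_models == 26
        assert len(rep.models) == 13

    def test_static_and_dynamic_models_see_disjoint_minutes(self, fast_table):
        """Category routing partitions every fold's training minutes."""
        static = {"SI", "ST", "REST"}
        dynamic = {"WK", "AS", "RU"}
        cats = set(fast_table["activity"])
        assert static | dynamic == cats and not static & dynamic

    def test_perfect_predictor_zero_rmse(self, fast_table):
        sub = fast_table[fast_table["subject_id"] == "S01"].copy()
        from wearhrv.ee import RegressionModel

        model = RegressionModel(
            variables=("ee_truth",), coef=np.array([0.0, 1.0]),
            stderr=np.zeros(2), pvalues=np.zeros(2), r_squared=1.0,
            resid_var=0.0, n_obs=len(sub),
        )
        sub["ee_truth"] = sub["ee_kcal_min"]
        rmse = evaluate_ee({"single": model}, sub)
        assert np.nanmax(rmse.to_numpy()) == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_rmse_is_population_sd(self, fast_table):
        sub = fast_table[(fast_table["subject_id"] == "S01")
                         & (fast_table["activity"] == "WK")].copy()
        from wearhrv.ee import RegressionModel

        y = sub["ee_kcal_min"].to_numpy()
        model = RegressionModel(
            variables=(), coef=np.array([y.mean()]), stderr=np.zeros(1),
            pvalues=np.zeros(1), r_squared=0.0, resid_var=0.0, n_obs=y.size,
        )
        rmse = evaluate_ee({"single": model}, sub)
        assert rmse["WK"] == pytest.approx(float(np.std(y)), rel=1e-12)

    def test_static_truth_coefficients_recovered(self):
        """With EE truth built on the published-static-equation variable set
        and plentiful minutes, OLS on the true support recovers every
        coefficient within 3 standard errors."""
        model = table7_style_static_model()
        tab = simulate_minute_table(n_subjects=20, ee_model=model, seed=21)
        static = tab[tab["activity"].isin(["SI", "ST", "REST"])]
        assert len(static) == 500
        varnames = model.variables(static=True)
        fit = ols_fit(static[varnames].to_numpy(),
                      static["ee_kcal_min"].to_numpy(), varnames)
        truth = model.static_coef
        assert abs(fit.coef[0] - truth["intercept"]) <= 3 * fit.stderr[0]
        for i, name in enumerate(varnames, start=1):
            assert abs(fit.coef[i] - truth[name]) <= 3 * fit.stderr[i], name

    def test_missing_category_in_training_raises(self, fast_table):
        only_static = fast_table[fast_table["activity"].isin(
            ["SI", "ST", "REST"])]
        fold = loso_folds(list(dict.fromkeys(only_static["subject_id"])),
                          validation=False)[0]
        with pytest.raises(ValueError, match="dynamic"):
            fit_ee(only_static, MODEL_SPECS[3], fold)


class TestANOVA:
    @staticmethod
    def _toy_cells():
        rows = []
        vals = {
            ("IMU", "single"): [1.0, 1.2, 1.1],
            ("IMU", "specific"): [0.9, 1.0, 1.1],
            ("ECG", "single"): [0.6, 0.7, 0.8],
            ("ECG", "specific"): [0.4, 0.5, 0.6],
        }
        for (a, b), ys in vals.items():
            for y in ys:
                rows.append({"data_type": a, "model_type": b, "rmse": y})
        return pd.DataFrame(rows)

    def test_matches_hand_sums_of_squares(self):
        cells = self._toy_cells()
        mine = anova_2x2(cells)
        ref = anova_2x2_oracle(cells["rmse"], cells["data_type"],
                               cells["model_type"])
        assert mine["data_type"]["F"] == pytest.approx(ref["F_a"], abs=1e-9)
        assert mine["model_type"]["F"] == pytest.approx(ref["F_b"], abs=1e-9)
        assert mine["interaction"]["F"] == pytest.approx(ref["F_ab"], abs=1e-9)
        assert mine["data_type"]["df"] == (1, ref["df_err"])

    def test_matches_statsmodels_anova_lm(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols as sm_ols

        cells = self._toy_cells()
        fit = sm_ols("rmse ~ C(data_type) * C(model_type)", data=cells).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        mine = anova_2x2(cells)
        assert mine["data_type"]["F"] == pytest.approx(
            ref.loc["C(data_type)", "F"], rel=1e-9)
        assert mine["interaction"]["p"] == pytest.approx(
            ref.loc["C(data_type):C(model_type)", "PR(>F)"], rel=1e-9)

    def test_sums_of_squares_decompose(self, rng):
        cells = self._toy_cells()
        cells["rmse"] += rng.normal(0, 0.01, size=len(cells))
        mine = anova_2x2(cells)
        total = (mine["data_type"]["ss"] + mine["model_type"]["ss"]
                 + mine["interaction"]["ss"] + mine["ss_error"])
        assert total == pytest.approx(mine["ss_total"], abs=1e-9)

    def test_equal_cells_give_zero_f(self):
        cells = self._toy_cells()
        cells["rmse"] = np.tile([1.0, 1.1, 0.9], 4)
        mine = anova_2x2(cells)
        assert mine["data_type"]["F"] == pytest.approx(0.0, abs=1e-12)
        assert mine["model_type"]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_unbalanced_layout_rejected(self):
        cells = self._toy_cells().iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            anova_2x2(cells)

    def test_dominant_data_effect_pattern(self):
        """When the data-type shift dwarfs the model-type shift and there is
        no interaction, F_data > F_model and the interaction p is large."""
        rng = np.random.default_rng(0)
        rows = []
        for a, da in (("IMU", 0.6), ("ECG", 0.0)):
            for b, db in (("single", 0.1), ("specific", 0.0)):
                for _ in range(30):
                    rows.append({"data_type": a, "model_type": b,
                                 "rmse": 1.0 + da + db + rng.normal(0, 0.3)})
        mine = anova_2x2(pd.DataFrame(rows))
        assert mine["data_type"]["F"] > mine["model_type"]["F"]
        assert mine["interaction"]["p"] > 0.05

    def test_full_four_model_run_produces_balanced_cells(self, fast_table):
        reps = [run_ee(fast_table, spec) for spec in MODEL_SPECS]
        cells = rmse_cells(reps)
        out = anova_2x2(cells)
        assert out["data_type"]["df"] == (1, 308)
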
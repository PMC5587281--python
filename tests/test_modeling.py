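import numpy as np
import pandas as pd
import pytest
from scipy import stats

from squatcrf import (
    CohortParams,
    ContractError,
    PUBLISHED_MODELS,
    SchemaError,
    SingularDesignError,
    SubjectRecord,
    UndefinedResultError,
    bland_altman,
    design_matrix,
    fit_ols,
    fitness_category,
    loocv,
    partial_correlation,
    predict,
    read_subject_table,
    rmse_by_category,
    simulate_cohort,
    stepwise_forward,
    subjects_to_frame,
    write_subject_table,
)


def _linear_cohort(n=30, noise_sd=0.0, seed=0):
    """Synthetic cohort with a known generating model (healthy defaults)."""
    return simulate_cohort(
        CohortParams(n=n, seed=seed, noise_sd=noise_sd, link_sd=4.0)
    )


GENERATING = PUBLISHED_MODELS["model_1a"]


class TestPredict:
    def test_worked_example_cad_group_means(self):
        # Independent hand calculation:
        # 4.624 + 0.00311*93.7 - 0.0516*56.6 + 0.123*4.6 = 2.560647
        subject = {"weight": 93.7, "age": 56.6, "rfsmax": 4.6}
        assert predict(PUBLISHED_MODELS["model_2"], subject) == pytest.approx(
            2.560647, abs=1e-9
        )

    def test_intercept_identity_at_zero_predictors(self):
        subject = {"weight": 0.0, "age": 0.0, "sex": "female", "rfsmax": 0.0}
        assert predict(PUBLISHED_MODELS["model_1a"], subject) == 1.587

    def test_deterministic(self):
        s = SubjectRecord(
            subject_id="s1", weight=80.0, height=180.0, age=40.0, sex="male",
            vo2peak=3.0, rfsmax=15.0,
        )
        model = PUBLISHED_MODELS["model_1a"]
        assert predict(model, s) == predict(model, s)

    def test_missing_predictor_named_in_error(self):
        with pytest.raises(ContractError, match="rfsmax"):
            predict(PUBLISHED_MODELS["model_2"], {"weight": 90.0, "age": 55.0})

    def test_sex_coding_linearity(self):
        base = {"weight": 70.0, "age": 30.0, "rfsmax": 12.0}
        model = PUBLISHED_MODELS["model_1b"]
        female = predict(model, {**base, "sex": "female"})
        male = predict(model, {**base, "sex": "male"})
        assert male - female == pytest.approx(0.18, abs=1e-12)


class TestFitOLS:
    def test_noiseless_data_recovers_generating_coefficients(self):
        df = _linear_cohort(noise_sd=0.0)
        spec, fit = fit_ols(df, GENERATING.predictors)
        np.testing.assert_allclose(spec.coefficients, GENERATING.coefficients, atol=1e-8)
        assert fit.r == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_normal_equations_oracle(self, seed):
        df = _linear_cohort(noise_sd=0.4, seed=seed)
        X = design_matrix(df, GENERATING.predictors)
        y = df["vo2peak"].to_numpy()
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        spec, _ = fit_ols(df, GENERATING.predictors)
        np.testing.assert_allclose(spec.coefficients, beta_oracle, rtol=1e-9, atol=1e-12)

    def test_residual_mean_is_zero_with_intercept(self):
        df = _linear_cohort(noise_sd=0.5, seed=3)
        spec, _ = fit_ols(df, ("weight", "age"))
        X = design_matrix(df, ("weight", "age"))
        resid = df["vo2peak"].to_numpy() - X @ spec.coefficients
        assert abs(resid.mean()) < 1e-10

    def test_rank_deficient_design_rejected(self):
        df = _linear_cohort(noise_sd=0.1, seed=4)
        df["weight2"] = df["weight"]
        with pytest.raises(SingularDesignError):
            fit_ols(df, ("weight", "weight2"))

    def test_inference_columns_match_statsmodels_shapes(self):
        df = _linear_cohort(noise_sd=0.3, seed=5)
        _, fit = fit_ols(df, GENERATING.predictors)
        assert fit.terms == ("intercept",) + GENERATING.predictors
        assert len(fit.params) == len(fit.se) == len(fit.t) == len(fit.p) == 5
        assert fit.df_resid == len(df) - 5


class TestStepwiseForward:
    def test_single_informative_candidate_enters(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            df = pd.DataFrame(
                {
                    "weight": rng.normal(75, 10, n),
                    "age": rng.normal(40, 8, n),
                    "rfsmax": rng.normal(15, 5, n),
                }
            )
            # only rfsmax is predictive; weight/age are pure noise
            df["vo2peak"] = 1.0 + 0.1 * df["rfsmax"] + rng.normal(0, 0.1, n)
            spec = stepwise_forward(df, ("weight", "age", "rfsmax"), p_enter=0.05)
            if "rfsmax" in spec.predictors and len(spec.predictors) <= 2:
                hits += 1
        assert hits >= 15  # majority behavior across seeds

    def test_permissive_threshold_reproduces_forced_entry(self):
        df = _linear_cohort(noise_sd=0.4, seed=6)
        spec = stepwise_forward(df, GENERATING.predictors, p_enter=1.1)
        assert set(spec.predictors) == set(GENERATING.predictors)
        # the final fit is order-independent: term-by-term agreement with a
        # forced-entry fit in canonical order
        forced, _ = fit_ols(df, GENERATING.predictors)
        by_term = dict(zip(("intercept",) + spec.predictors, spec.coefficients))
        expected = dict(zip(("intercept",) + GENERATING.predictors, forced.coefficients))
        for term, value in expected.items():
            assert by_term[term] == pytest.approx(value, rel=1e-10)

    def test_all_noise_yields_intercept_only(self):
        rng = np.random.default_rng(7)
        n = 40
        df = pd.DataFrame(
            {
                "weight": rng.normal(75, 10, n),
                "age": rng.normal(40, 8, n),
                "vo2peak": rng.normal(3, 0.5, n),
            }
        )
        spec = stepwise_forward(df, ("weight", "age"), p_enter=1e-9)
        assert spec.predictors == ()
        assert spec.coefficients[0] == pytest.approx(df["vo2peak"].mean())


class TestLOOCV:
    def test_noiseless_limit(self):
        df = _linear_cohort(noise_sd=0.0, seed=8)
        cv = loocv(df, GENERATING.predictors)
        assert cv.rmse_cv < 1e-6
        assert cv.r_cv > 0.999

    def test_four_subject_manual_fold_oracle(self):
        # Hand-sized dataset, one predictor; each fold solved independently
        # through explicit 2x2 normal equations.
        df = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "group": "healthy",
                "sex": "male",
                "weight": [70.0, 80.0, 90.0, 100.0],
                "height": [175.0] * 4,
                "age": [30.0] * 4,
                "vo2peak": [2.0, 2.6, 2.9, 3.6],
                "rfsmax": [10.0] * 4,
            }
        )
        preds = []
        for i in range(4):
            rest = df.drop(index=i)
            w = rest["weight"].to_numpy()
            v = rest["vo2peak"].to_numpy()
            A = np.array([[3.0, w.sum()], [w.sum(), (w**2).sum()]])
            b = np.array([v.sum(), (w * v).sum()])
            a0, a1 = np.linalg.solve(A, b)
            preds.append(a0 + a1 * df.loc[i, "weight"])
        expected_rmse = np.sqrt(np.mean((np.array(preds) - df["vo2peak"].to_numpy()) ** 2))
        cv = loocv(df, ("weight",))
        np.testing.assert_allclose(cv.predictions, preds, rtol=1e-10)
        assert cv.rmse_cv == pytest.approx(expected_rmse, rel=1e-10)

    def test_matches_sklearn_leave_one_out(self):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.linear_model import LinearRegression
        from sklearn.model_selection import LeaveOneOut

        df = _linear_cohort(noise_sd=0.4, seed=9)
        X = design_matrix(df, GENERATING.predictors)[:, 1:]
        y = df["vo2peak"].to_numpy()
        preds = np.empty(len(y))
        for train, test in LeaveOneOut().split(X):
            model = LinearRegression().fit(X[train], y[train])
            preds[test] = model.predict(X[test])
        cv = loocv(df, GENERATING.predictors)
        np.testing.assert_allclose(cv.predictions, preds, rtol=1e-8)

    def test_cv_error_dominates_in_sample_error(self, reference_cohort):
        healthy = reference_cohort[reference_cohort["group"] == "healthy"]
        _, fit = fit_ols(healthy, GENERATING.predictors)
        cv = loocv(healthy, GENERATING.predictors)
        assert cv.rmse_cv >= fit.rmse
        wins = 0
        for seed in range(100):
            df = _linear_cohort(n=30, noise_sd=0.4, seed=100 + seed)
            _, f = fit_ols(df, GENERATING.predictors)
            c = loocv(df, GENERATING.predictors)
            wins += c.rmse_cv >= f.rmse
        assert wins >= 95

    def test_minimum_n_enforced(self):
        df = _linear_cohort(noise_sd=0.1, seed=10).head(2)
        with pytest.raises(ContractError, match="at least 3"):
            loocv(df, ("weight",))

    def test_rank_deficient_fold_names_fold(self):
        df = _linear_cohort(noise_sd=0.1, seed=11).head(6).copy()
        df["flat"] = 1.0
        with pytest.raises(SingularDesignError, match="fold"):
            loocv(df, ("weight", "flat"))


class TestBlandAltman:
    def test_identity_gives_zero_bias_and_loa(self):
        v = np.array([2.0, 2.5, 3.0])
        bias, upper, lower = bland_altman(v, v)
        assert bias == 0.0 and upper == 0.0 and lower == 0.0

    def test_two_point_hand_calculation(self):
        # d = (+0.1, -0.1): bias 0, SD = sqrt(2)*0.1, LoA = ±1.96*SD
        bias, upper, lower = bland_altman(
            np.array([3.1, 2.9]), np.array([3.0, 3.0])
        )
        sd = np.sqrt(((0.1 - 0.0) ** 2 + (-0.1 - 0.0) ** 2) / 1)
        assert bias == pytest.approx(0.0, abs=1e-15)
        assert upper == pytest.approx(1.96 * sd)
        assert lower == pytest.approx(-1.96 * sd)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            bland_altman(np.ones(3), np.ones(4))

    def test_loa_symmetry_about_bias(self):
        rng = np.random.default_rng(12)
        pred, meas = rng.normal(3, 0.5, 20), rng.normal(3, 0.5, 20)
        bias, upper, lower = bland_altman(pred, meas)
        assert upper - bias == pytest.approx(bias - lower)


class TestPartialCorrelation:
    def test_no_controls_reduces_to_pearson(self):
        df = _linear_cohort(noise_sd=0.4, seed=13)
        expected = stats.pearsonr(df["rfsmax"], df["vo2peak"])[0]
        assert partial_correlation(df, "rfsmax", ()) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("predictor", ["weight", "age", "rfsmax"])
    def test_matches_residualization_oracle(self, predictor):
        df = _linear_cohort(noise_sd=0.4, seed=14)
        controls = [p for p in ("weight", "age", "rfsmax") if p != predictor]
        Z = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy() for c in controls]
        )
        def resid(v):
            return v - Z @ np.linalg.solve(Z.T @ Z, Z.T @ v)
        expected = stats.pearsonr(
            resid(df[predictor].to_numpy()), resid(df["vo2peak"].to_numpy())
        )[0]
        got = partial_correlation(df, predictor, controls)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        df = _linear_cohort(noise_sd=0.4, seed=15)
        expected = pingouin.partial_corr(
            data=df, x="rfsmax", y="vo2peak", covar=["weight", "age"]
        )["r"].iloc[0]
        got = partial_correlation(df, "rfsmax", ("weight", "age"))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_degenerate_residuals_rejected(self):
        df = _linear_cohort(noise_sd=0.0, seed=16).copy()
        df["flat"] = 2.0  # constant predictor: residuals on the intercept vanish
        with pytest.raises(UndefinedResultError):
            partial_correlation(df, "flat", ())


class TestFitnessCategory:
    @pytest.mark.parametrize(
        "vo2peak, weight, rel, label, ntl, clamped",
        [
            (3.0, 70.0, 42.857, "40-50", False, False),
            (2.1, 70.0, 30.0, "30-40", True, False),  # lower-inclusive bin edge
            (1.5, 70.0, 21.43, "20-30", True, False),
            (4.2, 70.0, 60.0, "40-50", False, True),  # above range: edge bin
            (1.0, 80.0, 12.5, "20-30", True, True),  # below range: edge bin
        ],
    )
    def test_binning_and_flags(self, vo2peak, weight, rel, label, ntl, clamped):
        cat = fitness_category(vo2peak=vo2peak, weight=weight)
        assert cat.rel_fitness == pytest.approx(rel, abs=0.01)
        assert cat.label == label
        assert cat.normal_to_low is ntl
        assert cat.clamped is clamped

    def test_reference_cohort_has_17_normal_to_low_healthy(self, reference_cohort):
        healthy = reference_cohort[reference_cohort["group"] == "healthy"]
        flags = [
            fitness_category(vo2peak=v, weight=w).normal_to_low
            for v, w in zip(healthy["vo2peak"], healthy["weight"])
        ]
        assert sum(flags) == 17


class TestRmseByCategory:
    def test_single_bin_equals_global(self):
        df = _linear_cohort(noise_sd=0.3, seed=17).copy()
        # force everyone into [30, 40)
        df["vo2peak"] = df["weight"] * 35.0 / 1000.0
        cv = loocv(df, ("weight", "age"))
        by_cat = rmse_by_category(cv, df)
        assert list(by_cat) == ["30-40"]
        assert by_cat["30-40"]["rmse_cv"] == pytest.approx(cv.rmse_cv)
        assert by_cat["30-40"]["n"] == len(df)

    def test_two_bin_toy_hand_computation(self):
        df = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "group": "healthy",
                "sex": "male",
                "weight": [100.0, 100.0, 100.0, 100.0],
                "height": [175.0] * 4,
                "age": [30.0] * 4,
                "vo2peak": [2.5, 2.6, 3.5, 3.6],  # bins 20-30 and 30-40
                "rfsmax": [10.0] * 4,
            }
        )
        from squatcrf import CVResult

        preds = np.array([2.7, 2.4, 3.4, 3.8])
        bias, upper, lower = bland_altman(preds, df["vo2peak"].to_numpy())
        cv = CVResult(
            predictions=preds, measured=df["vo2peak"].to_numpy(),
            rmse_cv=0.0, rmse_cv_pct=0.0, r_cv=0.0,
            bias=bias, loa_upper=upper, loa_lower=lower,
        )
        by_cat = rmse_by_category(cv, df)
        rmse_low = np.sqrt((0.2**2 + 0.2**2) / 2)
        rmse_high = np.sqrt((0.1**2 + 0.2**2) / 2)
        assert by_cat["20-30"]["rmse_cv"] == pytest.approx(rmse_low)
        assert by_cat["30-40"]["rmse_cv"] == pytest.approx(rmse_high)
        assert by_cat["20-30"]["rmse_cv_pct"] == pytest.approx(100 * rmse_low / 2.55)
        assert by_cat["30-40"]["rmse_cv_pct"] == pytest.approx(100 * rmse_high / 3.55)


class TestSubjectTableIO:
    def test_roundtrip_csv(self, tmp_path, reference_cohort):
        path = tmp_path / "subjects.csv"
        write_subject_table(reference_cohort, path)
        back = read_subject_table(path)
        pd.testing.assert_frame_equal(back, reference_cohort)

    def test_roundtrip_xlsx(self, tmp_path, reference_cohort):
        path = tmp_path / "subjects.xlsx"
        reference_cohort.to_excel(path, index=False)
        back = read_subject_table(path)
        np.testing.assert_allclose(back["vo2peak"], reference_cohort["vo2peak"])

    def test_alias_columns_and_sex_codes_accepted(self, tmp_path):
        path = tmp_path / "alias.csv"
        pd.DataFrame(
            {
                "Subject": ["s1"],
                "Group": ["healthy"],
                "Sex": ["F"],
                "Weight_kg": [70.0],
                "Height_cm": [170.0],
                "Age_yr": [30.0],
                "VO2peak_Lmin": [2.5],
                "RFS_max": [15.0],
            }
        ).to_csv(path, index=False)
        df = read_subject_table(path)
        assert df.loc[0, "sex"] == "female"
        assert df.loc[0, "weight"] == 70.0

    def test_missing_columns_listed(self, tmp_path):
        path = tmp_path / "partial.csv"
        pd.DataFrame({"subject_id": ["s1"], "sex": ["male"]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="rfsmax"):
            read_subject_table(path)

    def test_subject_records_to_frame(self):
        records = [
            SubjectRecord(
                subject_id="s1", weight=70.0, height=170.0, age=30.0,
                sex="female", vo2peak=2.5, rfsmax=15.0,
            )
        ]
        df = subjects_to_frame(records)
        assert df.loc[0, "subject_id"] == "s1"
        assert df.loc[0, "group"] == "healthy"
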
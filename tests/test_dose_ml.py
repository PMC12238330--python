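import numpy as np
import pandas as pd
import pytest

from planardose.dose_ml import (
    FEATURES,
    CohortTable,
    ModelSpec,
    evaluate,
    fit_normalization,
    metric_report,
    paired_comparison,
    percent_error,
    predict,
    preprocess,
    save_model,
    load_model,
    split,
    train,
    transform,
)
from planardose.phantom import make_cohort


@pytest.fixture
def linear_cohort():
    return make_cohort(120, generator="linear", noise_sd=0.0, seed=11)


@pytest.fixture
def nonlinear_cohort():
    return make_cohort(500, generator="nonlinear", noise_sd=1.0, seed=0)


class TestPreprocess:
    def test_missing_target_rows_dropped(self, linear_cohort):
        df = linear_cohort.records.head(10).copy()
        df.loc[3, "target_dose_Gy"] = np.nan
        out = preprocess(CohortTable(records=df))
        assert len(out) == 9

    def test_missing_feature_mean_imputed(self, linear_cohort):
        df = linear_cohort.records.copy()
        df.loc[5, "age_y"] = np.nan
        expected = df["age_y"].mean(skipna=True)
        out = preprocess(CohortTable(records=df))
        # row 5 survives with the column mean imputed
        assert out.records["age_y"].notna().all()
        assert out.records.loc[5, "age_y"] == pytest.approx(expected)

    def test_outlier_rows_removed(self, linear_cohort):
        df = linear_cohort.records.copy()
        df.loc[0, "bmi_kg_m2"] = 1e6
        out = preprocess(CohortTable(records=df))
        assert 1e6 not in out.records["bmi_kg_m2"].values
        assert "P0000" not in out.records["patient_id"].values
        # a tight threshold can only remove more rows than a loose one
        tight = preprocess(CohortTable(records=df), {"z_max": 2.0})
        assert len(tight) <= len(out)


class TestSplit:
    def test_75_25_proportions(self, linear_cohort):
        tr, te = split(linear_cohort, seed=1)
        assert len(tr) == round(0.75 * len(linear_cohort))
        assert len(tr) + len(te) == len(linear_cohort)

    def test_n8_gives_6_2(self):
        tr, te = split(make_cohort(8, seed=0), seed=0)
        assert (len(tr), len(te)) == (6, 2)

    def test_deterministic_under_seed(self, linear_cohort):
        tr1, te1 = split(linear_cohort, seed=5)
        tr2, te2 = split(linear_cohort, seed=5)
        pd.testing.assert_frame_equal(tr1.records, tr2.records)
        pd.testing.assert_frame_equal(te1.records, te2.records)

    def test_too_few_records(self):
        df = make_cohort(8, seed=0).records.head(3)
        with pytest.raises(ValueError):
            split(CohortTable(records=df), seed=0)


class TestNormalization:
    def test_zscore_has_zero_mean_unit_sd(self, linear_cohort):
        tr, _ = split(linear_cohort, seed=2)
        params = fit_normalization(tr)
        out = transform(tr, params)
        col = out.records["age_y"]
        assert col.mean() == pytest.approx(0.0, abs=1e-12)
        assert col.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_imaging_features_minmax(self, linear_cohort):
        tr, _ = split(linear_cohort, seed=2)
        out = transform(tr, fit_normalization(tr))
        for col in ("I_A_cps", "I_B_cps"):
            assert out.records[col].min() == pytest.approx(0.0)
            assert out.records[col].max() == pytest.approx(1.0)

    def test_minmax_worked_example(self):
        df = make_cohort(8, seed=0).records.copy()
        df = df.head(3).reset_index(drop=True)
        df["I_A_cps"] = [10.0, 20.0, 30.0]
        t = CohortTable(records=df)
        params = {"I_A_cps": {"kind": "minmax", "min": 10.0, "max": 30.0}}
        out = transform(t, params)
        assert list(out.records["I_A_cps"]) == [0.0, 0.5, 1.0]

    def test_test_split_uses_train_constants_only(self, linear_cohort):
        tr, te = split(linear_cohort, seed=2)
        params = fit_normalization(tr)
        te1 = transform(te, params)
        te2 = transform(te1, params)  # idempotent: no refit, no double-apply
        pd.testing.assert_frame_equal(te1.records, te2.records)
        # constants really are the train split's, not the test split's
        assert params["age_y"]["mean"] == pytest.approx(
            tr.records["age_y"].mean()
        )

    def test_constant_feature_warned_and_passed_through(self):
        df = make_cohort(10, seed=1).records.copy()
        df["mu_e_cm1"] = 0.11
        with pytest.warns(UserWarning, match="constant"):
            params = fit_normalization(CohortTable(records=df))
        assert params["mu_e_cm1"] == {"kind": "identity"}


class TestTrain:
    def test_linreg_recovers_generating_coefficients(self, linear_cohort):
        model = train(ModelSpec("linreg"), linear_cohort)
        coef = dict(zip(model.feature_columns, model.estimator.coef_))
        truth = linear_cohort.metadata["coefficients"]
        for feat in FEATURES:
            assert coef[feat] == pytest.approx(truth[feat], abs=1e-6)
        yhat = predict(model, CohortTable(records=linear_cohort.records,
                                          normalized=True))
        y = linear_cohort.records["target_dose_Gy"].to_numpy()
        assert np.mean((y - yhat) ** 2) < 1e-12

    def test_lbfgs_linreg_matches_closed_form(self, linear_cohort):
        closed = train(ModelSpec("linreg"), linear_cohort)
        lbfgs = train(ModelSpec("linreg", {"solver": "lbfgs"}), linear_cohort)
        table = CohortTable(records=linear_cohort.records, normalized=True)
        assert np.allclose(predict(closed, table), predict(lbfgs, table),
                           rtol=1e-5, atol=1e-5)

    def test_tree_unsplittable_predicts_mean(self):
        df = make_cohort(10, seed=3).records.copy()
        for col in FEATURES:
            df[col] = 1.0
        df["organ"] = "liver"
        df["target_dose_Gy"] = np.arange(10, dtype=float)
        t = CohortTable(records=df, normalized=True)
        model = train(ModelSpec("tree"), t)
        assert model.estimator.get_n_leaves() == 1
        assert np.allclose(predict(model, t), 4.5)

    def test_nan_features_rejected_with_rows(self, linear_cohort):
        df = linear_cohort.records.copy()
        df.loc[2, "bmi_kg_m2"] = np.nan
        with pytest.raises(ValueError, match=r"rows \[2\]"):
            train(ModelSpec("linreg"), CohortTable(records=df, normalized=True))

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="unrecognized"):
            ModelSpec("svr", {"n_estimators": 10})

    @pytest.mark.parametrize("family", ["tree", "linreg"])
    def test_bitwise_determinism(self, linear_cohort, family):
        m1 = train(ModelSpec(family, seed=7), linear_cohort)
        m2 = train(ModelSpec(family, seed=7), linear_cohort)
        table = CohortTable(records=linear_cohort.records, normalized=True)
        assert np.array_equal(predict(m1, table), predict(m2, table))

    @pytest.mark.parametrize("family", ["mlp", "svr"])
    def test_seeded_determinism(self, nonlinear_cohort, family):
        cohort = preprocess(nonlinear_cohort)
        tr, _ = split(cohort, seed=0)
        tr = transform(tr, fit_normalization(tr))
        m1 = train(ModelSpec(family, seed=7), tr)
        m2 = train(ModelSpec(family, seed=7), tr)
        assert np.allclose(predict(m1, tr), predict(m2, tr), atol=1e-6)

    def test_mlp_learns_nonlinear_cohort(self, nonlinear_cohort):
        from sklearn.metrics import r2_score

        cohort = preprocess(nonlinear_cohort)
        tr, te = split(cohort, seed=0)
        params = fit_normalization(tr)
        tr, te = transform(tr, params), transform(te, params)
        model = train(ModelSpec("mlp", seed=0), tr)
        yhat = predict(model, te)
        assert r2_score(te.records["target_dose_Gy"], yhat) >= 0.8


class TestMetrics:
    def test_perfect_prediction_zeroes(self):
        rep = metric_report([1.0, 2.0], [1.0, 2.0])
        assert rep.mse == rep.mae == rep.rmse == 0.0

    def test_hand_example_unit_errors(self):
        rep = metric_report([0.0, 2.0], [1.0, 1.0])
        assert (rep.mae, rep.mse, rep.rmse) == (1.0, 1.0, 1.0)

    def test_hand_example_asymmetric(self):
        rep = metric_report([0.0, 4.0], [0.0, 0.0])
        assert rep.mae == 2.0
        assert rep.mse == 8.0
        assert rep.rmse == pytest.approx(2.8284271247461903)

    def test_rmse_squared_is_mse_and_mae_le_rmse(self, linear_cohort):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 10, 50)
        yhat = y + rng.normal(0, 1, 50)
        rep = metric_report(y, yhat)
        assert rep.rmse ** 2 == pytest.approx(rep.mse, abs=1e-12)
        assert rep.mae <= rep.rmse

    def test_per_organ_breakdown(self, linear_cohort):
        model = train(ModelSpec("linreg"), linear_cohort)
        rep = evaluate(model, CohortTable(records=linear_cohort.records,
                                          normalized=True))
        assert set(rep.per_organ) == set(linear_cohort.records["organ"].unique())
        for m in rep.per_organ.values():
            assert m["rmse"] ** 2 == pytest.approx(m["mse"], abs=1e-12)


class TestPercentError:
    def test_signed_values(self):
        assert percent_error(107.9, 100.0) == pytest.approx(7.9)
        assert percent_error(85.2, 100.0) == pytest.approx(-14.8)
        assert percent_error(5.0, 5.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_error(1.0, 0.0)


class TestPairedComparison:
    def test_identical_vectors_degenerate(self):
        res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0
        assert res.mean_percent_error == 0.0

    def test_normal_differences_select_t_test(self):
        rng = np.random.default_rng(0)
        chosen = []
        rejections = 0
        for _ in range(200):
            b = rng.uniform(10, 20, 25)
            a = b + rng.normal(0, 1, 25)
            res = paired_comparison(a, b)
            chosen.append(res.test_name)
            rejections += res.p_value < 0.05
        assert chosen.count("paired_t") > 100
        assert 0.03 <= rejections / 200 <= 0.07

    def test_skewed_differences_select_wilcoxon(self):
        rng = np.random.default_rng(1)
        chosen = []
        for _ in range(100):
            b = rng.uniform(10, 20, 30)
            a = b + rng.exponential(1.0, 30)
            chosen.append(paired_comparison(a, b).test_name)
        assert chosen.count("wilcoxon") > 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_comparison([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, linear_cohort):
        model = train(ModelSpec("tree", seed=3), linear_cohort)
        path = tmp_path / "model.bin"
        save_model(model, path)
        back = load_model(path)
        assert back.family == "tree"
        assert back.seed == 3
        assert back.schema_hash == model.schema_hash
        table = CohortTable(records=linear_cohort.records, normalized=True)
        assert np.array_equal(predict(back, table), predict(model, table))
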
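"""OLS calibration, leave-one-out machinery, resampling validation."""
import numpy as np
import pandas as pd
import pytest

import skinperm as sp
from skinperm.errors import (
    CollinearityError,
    FoldError,
    SampleSizeError,
    SplitError,
    UnitError,
)

PPM_PREDICTORS = ["log_kow", "log_kaw"]


def simple_line(n=5, slope=2.0, intercept=1.0):
    x = np.arange(n, dtype=float)
    return pd.DataFrame({"id": [f"r{i}" for i in range(n)], "x": x,
                         "y": intercept + slope * x})


class TestFitOls:
    def test_perfect_line(self):
        fit = sp.fit_ols(simple_line(), "y", ["x"])
        assert fit.coefficients.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)
        assert fit.q2_loo == pytest.approx(1.0, abs=1e-10)
        assert fit.press_rmse == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_surface_recovery(self):
        df = sp.generate_ppm_dataset(seed=7, sigma=0.0)
        fit = sp.fit_ols(df, "log_kp", PPM_PREDICTORS)
        assert fit.coefficients.intercept == pytest.approx(-5.41, abs=1e-10)
        assert fit.coefficients.coefficients["log_kow"] == pytest.approx(0.46, abs=1e-10)
        assert fit.coefficients.coefficients["log_kaw"] == pytest.approx(0.14, abs=1e-10)

    def test_coefficients_inside_bootstrap_interval(self, ppm_df):
        fit = sp.fit_ols(ppm_df, "log_kp", PPM_PREDICTORS)
        ses = sp.bootstrap_se(ppm_df, "log_kp", PPM_PREDICTORS, n_boot=1000, seed=2)
        truth = {"intercept": -5.41, "log_kow": 0.46, "log_kaw": 0.14}
        est = fit.params
        for key, true_val in truth.items():
            assert abs(est[key] - true_val) < 1.96 * ses[key]

    def test_constant_response_flagged_undefined(self):
        df = simple_line()
        df["y"] = 3.0
        fit = sp.fit_ols(df, "y", ["x"])
        assert fit.r2_undefined
        assert np.isnan(fit.r2)
        assert fit.coefficients.coefficients["x"] == pytest.approx(0.0, abs=1e-10)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_residual_orthogonality(self, ppm_df):
        fit = sp.fit_ols(ppm_df, "log_kp", PPM_PREDICTORS)
        assert np.abs(fit._X.T @ fit.residuals.to_numpy()).max() < 1e-8
        assert abs(fit.residuals.sum()) < 1e-8

    def test_collinear_design_names_columns(self, ppm_df):
        df = ppm_df.copy()
        df["dup"] = df["log_kow"]
        with pytest.raises(CollinearityError) as exc:
            sp.fit_ols(df, "log_kp", ["log_kow", "dup"])
        assert "dup" in exc.value.columns

    def test_too_small_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            sp.fit_ols(simple_line(n=2), "y", ["x"])

    def test_missing_rows_dropped_and_counted(self, ppm_df):
        df = ppm_df.copy()
        df.loc[df.index[:4], "log_kaw"] = np.nan
        fit = sp.fit_ols(df, "log_kp", PPM_PREDICTORS)
        assert fit.n == len(df) - 4
        assert fit.n_dropped == 4


class TestPressQ2:
    def test_toy_set_matches_explicit_refits(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [0.0, 1.0, 2.0, 4.0]})
        fit = sp.fit_ols(df, "y", ["x"])
        q2, press_rmse = sp.press_q2(fit)
        loo = sp.loo_predictions_explicit(df, "y", ["x"])
        press = float(((df["y"] - loo) ** 2).sum())
        tss = float(((df["y"] - df["y"].mean()) ** 2).sum())
        assert press_rmse == pytest.approx(np.sqrt(press / 4), abs=1e-10)
        assert q2 == pytest.approx(1 - press / tss, abs=1e-10)

    def test_shortcut_equals_refit_loop_on_random_sets(self, rng):
        """Hat-matrix LOO must equal n explicit refits on small noisy data."""
        for trial in range(10):
            n = int(rng.integers(8, 31))
            df = pd.DataFrame({
                "x1": rng.normal(0, 1, n),
                "x2": rng.normal(0, 1, n),
            })
            df["y"] = 1.0 - 0.5 * df.x1 + 0.8 * df.x2 + rng.normal(0, 0.5, n)
            fit = sp.fit_ols(df, "y", ["x1", "x2"])
            q2, press_rmse = sp.press_q2(fit)
            loo = sp.loo_predictions_explicit(df, "y", ["x1", "x2"])
            press = float(((df["y"] - loo) ** 2).sum())
            assert press_rmse == pytest.approx(np.sqrt(press / n), abs=1e-10)

    def test_duplicated_dataset_does_not_lower_q2(self, rng):
        n = 20
        df = pd.DataFrame({"x": rng.normal(0, 1, n)})
        df["y"] = 2 * df.x + rng.normal(0, 0.4, n)
        doubled = pd.concat([df, df], ignore_index=True)
        q2_single, _ = sp.press_q2(sp.fit_ols(df, "y", ["x"]))
        q2_double, _ = sp.press_q2(sp.fit_ols(doubled, "y", ["x"]))
        assert q2_double >= q2_single


class TestBootstrapSE:
    def test_exact_data_gives_zero_se(self):
        ses = sp.bootstrap_se(simple_line(n=12), "y", ["x"], n_boot=100, seed=0)
        assert all(v < 1e-10 for v in ses.values())

    def test_ppm_scale_se_bracket(self, ppm_df):
        """At n=175 and sigma=0.47 the log Kow slope SE sits near the
        published +/-0.03."""
        ses = sp.bootstrap_se(ppm_df, "log_kp", PPM_PREDICTORS, n_boot=1000, seed=9)
        assert 0.015 <= ses["log_kow"] <= 0.06

    def test_single_replicate_rejected(self, ppm_df):
        with pytest.raises(SampleSizeError):
            sp.bootstrap_se(ppm_df, "log_kp", PPM_PREDICTORS, n_boot=1)

    def test_deterministic_by_seed(self, ppm_df):
        a = sp.bootstrap_se(ppm_df, "log_kp", PPM_PREDICTORS, n_boot=50, seed=3)
        b = sp.bootstrap_se(ppm_df, "log_kp", PPM_PREDICTORS, n_boot=50, seed=3)
        assert a == b


class TestCrossValidate:
    def test_loo_on_perfect_data_is_exact(self):
        cv = sp.cross_validate(simple_line(n=8), "y", ["x"], scheme="loo")
        assert cv.rmse == pytest.approx(0.0, abs=1e-10)

    def test_kfold_with_k_equals_n_is_loo(self, ppm_df):
        loo = sp.cross_validate(ppm_df, "log_kp", PPM_PREDICTORS, scheme="loo")
        kn = sp.cross_validate(
            ppm_df, "log_kp", PPM_PREDICTORS, scheme="kfold", k=len(ppm_df), seed=123
        )
        assert loo.rmse == kn.rmse
        pd.testing.assert_series_equal(loo.predictions, kn.predictions)

    def test_repeated_kfold_deterministic(self, ppm_df):
        a = sp.cross_validate(
            ppm_df, "log_kp", PPM_PREDICTORS, scheme="repeated_kfold",
            k=10, repeats=3, seed=42,
        )
        b = sp.cross_validate(
            ppm_df, "log_kp", PPM_PREDICTORS, scheme="repeated_kfold",
            k=10, repeats=3, seed=42,
        )
        assert a.rmse == b.rmse
        assert a.fold_metrics == b.fold_metrics
        assert len(a.fold_metrics) == 30

    def test_bootstrap_scheme_runs_and_pools_oob(self, ppm_df):
        cv = sp.cross_validate(
            ppm_df, "log_kp", PPM_PREDICTORS, scheme="bootstrap", n_boot=50, seed=1
        )
        assert cv.rmse > 0
        assert len(cv.fold_metrics) == 50

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(FoldError):
            sp.cross_validate(simple_line(n=6), "y", ["x"], scheme="kfold", k=7)

    def test_cv_rmse_exceeds_resubstitution_in_expectation(self):
        """Held-out error is a less optimistic estimate than training error."""
        wins = 0
        for seed in range(20):
            df = sp.generate_ppm_dataset(seed=seed, n=60)
            fit = sp.fit_ols(df, "log_kp", PPM_PREDICTORS)
            cv = sp.cross_validate(
                df, "log_kp", PPM_PREDICTORS, scheme="kfold", k=10, seed=seed
            )
            wins += cv.rmse >= fit.rmse
        assert wins >= 16  # strict inequality holds in expectation


class TestStepwise:
    def test_recovers_true_pair_among_decoys(self):
        """Two generating descriptors plus four irrelevant candidates:
        selection returns exactly the generating pair. Decoys are drawn
        from a stream independent of the data generator's."""
        df = sp.generate_ppm_dataset(seed=0)
        rng = np.random.default_rng(10_000)
        decoys = ["mw", "log_kocw", "log_bcf", "log_dw"]
        for c in decoys:
            df[c] = rng.standard_normal(len(df))
        res = sp.stepwise_select(df, "log_kp", PPM_PREDICTORS + decoys)
        assert sorted(res.selected) == sorted(PPM_PREDICTORS)
        assert not res.empty_model

    def test_single_perfect_candidate(self):
        df = simple_line(n=10)
        res = sp.stepwise_select(df, "y", ["x"])
        assert res.selected == ["x"]
        assert res.fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_collinear_duplicates_keep_one_via_vif(self, ppm_df):
        df = ppm_df.copy()
        df["dup"] = df["log_kow"]
        res = sp.stepwise_select(df, "log_kp", ["log_kow", "dup"])
        assert len(res.selected) == 1
        assert any("VIF" in line for line in res.trace)

    def test_pure_noise_yields_flagged_empty_model(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(0, 1, 100),
            "a": rng.normal(0, 1, 100),
            "b": rng.normal(0, 1, 100),
        })
        res = sp.stepwise_select(df, "y", ["a", "b"])
        assert res.empty_model
        assert res.selected == []


class TestSplit:
    def test_published_split_sizes(self):
        assert sp.split_train_validation(range(175), 0.8, seed=1).sizes == (140, 35)
        assert sp.split_train_validation(range(79), 64 / 79, seed=1).sizes == (64, 15)

    def test_deterministic_and_disjoint(self):
        ids = [f"c{i}" for i in range(50)]
        a = sp.split_train_validation(ids, 0.7, seed=6)
        b = sp.split_train_validation(ids, 0.7, seed=6)
        assert a == b
        assert set(a.train_ids) | set(a.validation_ids) == set(ids)
        assert not set(a.train_ids) & set(a.validation_ids)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(SplitError):
            sp.split_train_validation(range(10), 0.999, seed=0)
        with pytest.raises(SplitError):
            sp.split_train_validation(range(10), 1.5, seed=0)


class TestCompareModels:
    def test_identical_series_zero_rmse(self):
        x = pd.Series([1.0, 2.0, 3.0])
        res = sp.compare_models(x, x)
        assert res.rmse == 0.0
        assert res.r2 == pytest.approx(1.0)

    def test_constant_series_flagged_undefined(self):
        x = pd.Series([2.0, 2.0, 2.0])
        res = sp.compare_models(x, x)
        assert res.rmse == 0.0
        assert res.r2_undefined

    def test_constant_offset_gives_rmse_delta(self):
        x = pd.Series(np.linspace(-3, 3, 9))
        res = sp.compare_models(x, x + 0.5)
        assert res.rmse == pytest.approx(0.5, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.r2_identity < 1.0

    def test_toy_three_pairs(self):
        ref = pd.Series([0.0, 1.0, 2.0])
        cand = pd.Series([0.5, 1.5, 2.5])
        assert sp.compare_models(ref, cand).rmse == pytest.approx(0.5, abs=1e-12)

    def test_rmse_symmetric(self, rng):
        a = pd.Series(rng.normal(0, 1, 30))
        b = pd.Series(rng.normal(0, 1, 30))
        assert sp.compare_models(a, b).rmse == sp.compare_models(b, a).rmse

    def test_unit_mismatch_rejected(self):
        x = pd.Series([1.0, 2.0])
        with pytest.raises(UnitError):
            sp.compare_models(x, x, reference_unit="cm/h", candidate_unit="cm/s")

    def test_incomplete_pairs_dropped(self):
        ref = pd.Series([1.0, np.nan, 3.0, 4.0])
        cand = pd.Series([1.0, 2.0, np.nan, 4.5])
        res = sp.compare_models(ref, cand)
        assert res.n == 2
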
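"""Regression engine tests: design assembly, OLS, stepwise selection,
standardized coefficients, prediction, reference models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from petbtv.calibration import (
    CalibrationModel,
    assemble_design,
    ols_fit,
    partial_f,
    predict_ts,
    records_to_frame,
    reference_model,
    reference_model_ids,
    simulate_records,
    standardized_coeffs,
    stepwise_forward,
)
from petbtv.roi import MeasurementRecord


def _record(sphere_id, area, tbr, fwhm=6.0, ts=50, esd=5.0):
    return MeasurementRecord(
        scanner_id="S1",
        sphere_id=sphere_id,
        x1_area=area,
        tbr_nominal=tbr,
        tbr_measured=tbr,
        x2=1 - 1 / tbr,
        x3_fwhm=fwhm,
        esd=esd,
        em_iterations=30,
        ts=ts,
        converged=True,
    )


class TestAssembleDesign:
    def test_small_spheres_filtered_by_area_cutoff(self):
        # 10 and 13 mm spheres (78.5 and 132.7 mm^2) fall at or below 133
        records = [
            _record("10mm", np.pi * 5.0**2, 8.0),
            _record("13mm", np.pi * 6.5**2, 8.0),
        ]
        with pytest.raises(ValueError, match="cutoff"):
            assemble_design(records)

    def test_contrast_term_value(self):
        records = [_record("22mm", 380.1, 2.5), _record("28mm", 615.8, 8.0)]
        X, y, removed = assemble_design(records)
        assert removed == 0
        assert X["x2"].iloc[0] == pytest.approx(0.6)
        assert list(X.columns[:5]) == ["area", "x2", "fwhm", "esd", "iterations"]

    def test_zero_cutoff_keeps_everything(self):
        records = [_record("10mm", 78.5, 8.0), _record("28mm", 615.8, 8.0)]
        X, _, removed = assemble_design(records, min_area=0.0)
        assert len(X) == 2 and removed == 0


class TestOls:
    def test_exact_linear_data_recovered(self):
        x = np.linspace(0, 10, 30)
        fit = ols_fit(pd.DataFrame({"x": x}), 5 + 2 * x)
        assert fit.coefficients["intercept"] == pytest.approx(5.0)
        assert fit.coefficients["x"] == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        y = rng.standard_normal(200)
        fit = ols_fit(X, y)
        design = np.column_stack([np.ones(200), X.to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        got = [fit.coefficients[k] for k in ("intercept", "a", "b", "c")]
        np.testing.assert_allclose(got, beta, rtol=1e-8)
        # ANOVA identity
        assert fit.ss_total == pytest.approx(
            fit.ss_regression + fit.ss_residual, rel=1e-6
        )
        assert fit.df_regression == 3 and fit.df_residual == 196

    def test_collinear_columns_named(self):
        x = np.linspace(0, 1, 50)
        X = pd.DataFrame({"a": x, "twice_a": 2 * x})
        with pytest.raises(ValueError, match="twice_a"):
            ols_fit(X, x + 1)

    def test_recovers_generating_equation(self):
        truth = reference_model("discovery_st")
        frame = simulate_records(truth, 1600, noise_sd=3.5, seed=42)
        fit = ols_fit(frame[["x2", "fwhm"]], frame["ts"])
        for name, expected in (("x2", -62.44), ("fwhm", 1.05)):
            assert abs(fit.coefficients[name] - expected) <= 3 * fit.std_errors[name]


class TestPartialF:
    def test_equals_squared_t(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((150, 2)), columns=["a", "b"])
        y = 1 + X["a"] * 2 + rng.standard_normal(150)
        base = ols_fit(X[["a"]], y)
        full = ols_fit(X, y)
        t = full.coefficients["b"] / full.std_errors["b"]
        assert partial_f(base, full) == pytest.approx(t**2, rel=1e-8)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((60, 2)), columns=["a", "b"])
        y = rng.standard_normal(60)
        with pytest.raises(ValueError):
            partial_f(ols_fit(X[["a"]], y), ols_fit(X[["b"]], y))

    def test_null_predictor_f_distribution(self):
        # F-to-enter of a pure-noise predictor exceeds 4 rarely (P ~ 0.046)
        rng = np.random.default_rng(3)
        exceed = 0
        for _ in range(50):
            x = rng.standard_normal(1000)
            noise = rng.standard_normal(1000)
            y = 2 + x + rng.standard_normal(1000)
            X = pd.DataFrame({"x": x, "noise": noise})
            f = partial_f(ols_fit(X[["x"]], y), ols_fit(X, y))
            exceed += f > 4
        assert exceed <= 5  # >= 90% of replicates below 4


class TestStepwise:
    def test_selects_only_the_true_predictor(self):
        rng = np.random.default_rng(4)
        x1 = rng.uniform(0, 1, 500)
        x2 = rng.uniform(0, 1, 500)
        y = 2 + 3 * x1 + rng.standard_normal(500) * 0.1
        model = stepwise_forward(pd.DataFrame({"x1": x1, "x2": x2}), y)
        assert model.selection_order == ("x1",)

    def test_matches_exhaustive_forward_oracle(self):
        # greedy forward selection replayed by brute force over <= 4 candidates
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = pd.DataFrame(
                rng.standard_normal((120, 4)), columns=["a", "b", "c", "d"]
            )
            y = (
                1.0
                + 2.0 * X["a"]
                + 0.8 * X["c"]
                + rng.standard_normal(120) * 0.7
            )
            model = stepwise_forward(X, y)

            # oracle: exhaustive recomputation of each greedy step
            selected = []
            current = ols_fit(X[selected], y)
            while True:
                fs = {}
                for name in X.columns:
                    if name in selected:
                        continue
                    fit = ols_fit(X[selected + [name]], y)
                    fs[name] = (partial_f(current, fit), fit)
                best = max(fs, key=lambda k: fs[k][0])
                f, fit = fs[best]
                if f <= 4 or fit.r2 - current.r2 < 0.01:
                    break
                selected.append(best)
                current = fit
            assert model.selection_order == tuple(selected)

    def test_zero_variance_candidate_never_enters(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(100)
        X = pd.DataFrame({"flat": np.ones(100), "x": x})
        model = stepwise_forward(X, 1 + 2 * x + rng.standard_normal(100) * 0.1)
        assert "flat" not in model.selection_order

    def test_no_candidates_gives_intercept_only(self):
        y = np.random.default_rng(7).standard_normal(30)
        model = stepwise_forward(pd.DataFrame(index=range(30)), y)
        assert model.selection_order == ()
        assert model.intercept == pytest.approx(float(np.mean(y)))

    def test_decoys_rejected_and_contrast_dominates(self):
        truth = reference_model("discovery_st")
        frame = simulate_records(truth, 1600, target_r2=0.85, seed=8)
        model = stepwise_forward(
            frame[["area", "x2", "fwhm", "esd", "iterations"]], frame["ts"]
        )
        assert model.selection_order[0] == "x2"
        assert "esd" not in model.selection_order
        assert "iterations" not in model.selection_order
        beta = model.standardized_beta
        assert beta["x2"] < 0 and abs(beta["x2"]) > abs(beta["fwhm"])


class TestStandardizedCoeffs:
    def test_identity_on_standardized_data(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((400, 2)), columns=["a", "b"])
        X = (X - X.mean()) / X.std(ddof=1)
        y = X["a"] - 0.5 * X["b"] + rng.standard_normal(400) * 0.01
        y = (y - y.mean()) / y.std(ddof=1)
        fit = ols_fit(X, y)
        betas = standardized_coeffs(fit.coefficients, X, y)
        assert betas["a"] == pytest.approx(fit.coefficients["a"])
        assert betas["b"] == pytest.approx(fit.coefficients["b"])

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(
        scale=st.floats(0.01, 100.0),
        shift=st.floats(-50.0, 50.0),
    )
    def test_invariant_under_affine_rescaling(self, scale, shift):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((200, 2)), columns=["a", "b"])
        y = 1 + X["a"] * 2 - X["b"] + rng.standard_normal(200) * 0.5
        base = standardized_coeffs(ols_fit(X, y).coefficients, X, y)
        X2 = X.assign(a=X["a"] * scale + shift)
        again = standardized_coeffs(ols_fit(X2, y).coefficients, X2, y)
        assert again["a"] == pytest.approx(base["a"], rel=1e-8)
        assert again["b"] == pytest.approx(base["b"], rel=1e-8)

    def test_zero_variance_response_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            standardized_coeffs({"a": 1.0}, X, np.ones(3))


class TestPredict:
    def test_worked_example_hirez(self):
        model = reference_model("biograph_hirez")
        result = predict_ts(model, tbr=12.0, fwhm=4.0)
        assert result.percent == 39
        assert result.ts == pytest.approx(39.4, abs=0.05)

    def test_worked_example_discovery_st(self):
        model = reference_model("discovery_st")
        assert predict_ts(model, tbr=70.0, fwhm=6.0).ts == pytest.approx(35.4, abs=0.05)

    def test_contrast_term_vanishes_at_unit_tbr(self):
        model = reference_model("discovery_st")
        expected = model.intercept + model.coefficients["fwhm"] * 6.0
        assert predict_ts(model, tbr=1.0, fwhm=6.0).ts == pytest.approx(expected)

    def test_missing_predictor_rejected(self):
        model = reference_model("gemini_tf")  # needs the area term
        with pytest.raises(ValueError, match="area"):
            predict_ts(model, tbr=8.0, fwhm=6.0)

    def test_prediction_clipped_to_percent_range(self):
        model = CalibrationModel(
            scanner_model="toy",
            intercept=150.0,
            coefficients={"x2": -200.0},
            selection_order=("x2",),
        )
        assert predict_ts(model, tbr=1.0).ts == 100.0
        assert predict_ts(model, tbr=70.0).ts == 1.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        tbr_lo=st.floats(1.5, 30.0),
        bump=st.floats(0.5, 40.0),
        fwhm=st.sampled_from([4.0, 6.0, 8.0, 11.0]),
    )
    def test_strictly_decreasing_in_tbr_when_b2_negative(self, tbr_lo, bump, fwhm):
        model = reference_model("discovery_600")
        lo = predict_ts(model, tbr=tbr_lo, fwhm=fwhm).unclipped
        hi = predict_ts(model, tbr=tbr_lo + bump, fwhm=fwhm).unclipped
        assert hi < lo


class TestReferenceModels:
    def test_all_eight_models_ship(self):
        ids = reference_model_ids()
        assert len(ids) == 8
        for mid in ids:
            model = reference_model(mid)
            assert model.coefficients["x2"] < 0
            if "fwhm" in model.coefficients:
                assert model.coefficients["fwhm"] > 0
            assert model.selection_order[0] == "x2"
            assert 0.74 <= model.multiple_r2 <= 0.92
            assert abs(model.shrinkage) < 0.10

    def test_parameter_recovery_across_all_models(self):
        # stepwise on data generated from each shipped equation recovers
        # exactly its predictors and the coefficients within 3 SE
        for mid in reference_model_ids():
            truth = reference_model(mid)
            frame = simulate_records(truth, 1600, target_r2=0.85, seed=77)
            X = frame[["area", "x2", "fwhm", "esd", "iterations"]]
            model = stepwise_forward(X, frame["ts"])
            assert set(model.selection_order) == set(truth.coefficients), mid
            fit = ols_fit(X[list(model.selection_order)], frame["ts"])
            for name, expected in truth.coefficients.items():
                assert abs(fit.coefficients[name] - expected) <= 3 * fit.std_errors[name]

    def test_unknown_model_id_rejected(self):
        with pytest.raises(KeyError):
            reference_model("discovery_9000")


def test_records_roundtrip_through_frame():
    records = [_record("22mm", 380.1, 8.0, ts=47), _record("37mm", 1075.2, 25.0, ts=38)]
    frame = records_to_frame(records)
    assert list(frame["ts"]) == [47, 38]
    assert frame["x2"].iloc[1] == pytest.approx(1 - 1 / 25.0)
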
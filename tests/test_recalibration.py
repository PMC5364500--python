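"""Coefficient refits, mean linear predictor and Breslow baseline survival."""

import numpy as np
import pandas as pd
import pytest

from cvdrisk.calibration import km_estimate
from cvdrisk.recalibration import (RecalibrationError, adjust_score_spec,
                                   baseline_survival_at, design_matrix,
                                   mean_lp, recalibrate, refit_coefficients)
from cvdrisk.engine import cox_form_risk, linear_predictor, score_cohort
from cvdrisk.specs import model_spec_from_dict

from conftest import make_cohort


def two_term_spec(b_age=0.5, b_smoke=-0.3):
    return model_spec_from_dict({
        "model_id": "toy2", "sex": "male", "family": "cox_form",
        "native_horizon": 5, "baseline_survival": {"5": 0.95}, "mean_lp": 0.0,
        "terms": [
            {"covariate": "age_z", "transform": "identity", "coefficient": b_age},
            {"covariate": "current_smoker", "transform": "identity",
             "coefficient": b_smoke},
        ],
    })


def simulate_from_spec(n, beta_age, beta_smoke, lam=0.02, seed=0, h_admin=6.0):
    """Weibull(k=1) proportional-hazards draw from the two-term model."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "sex": "male",
        "age_z": rng.standard_normal(n),
        "current_smoker": rng.integers(0, 2, n),
    })
    lp = beta_age * df["age_z"] + beta_smoke * df["current_smoker"]
    t = rng.exponential(1.0, n) / (lam * np.exp(lp))
    df["followup_years"] = np.minimum(t, h_admin)
    df["cvd_death"] = (t <= h_admin).astype(int)
    df["all_cause_death"] = df["cvd_death"]
    return df


class TestRefitCoefficients:
    def test_parameter_recovery_two_term_model(self):
        truth = {"age": 0.5, "smoke": -0.3}
        df = simulate_from_spec(8000, truth["age"], truth["smoke"], seed=1)
        new, fit = refit_coefficients(df, two_term_spec())
        for (label, true_b), (_, row) in zip(truth.items(), fit.iterrows()):
            assert abs(row["coefficient"] - true_b) < 3 * row["se"], label

    def test_null_model_recovery(self):
        df = simulate_from_spec(8000, 0.0, 0.0, seed=2)
        _, fit = refit_coefficients(df, two_term_spec())
        assert (fit["coefficient"].abs() < 3 * fit["se"]).all()

    def test_exponential_binary_covariate_closed_form(self):
        # with exponential data the Cox coefficient estimates the log rate
        # ratio; compare with the occurrence/exposure estimator
        df = simulate_from_spec(6000, 0.0, 0.7, seed=3)
        _, fit = refit_coefficients(df, two_term_spec())
        smoke = df["current_smoker"] == 1
        rate1 = df.loc[smoke, "cvd_death"].sum() / df.loc[smoke, "followup_years"].sum()
        rate0 = df.loc[~smoke, "cvd_death"].sum() / df.loc[~smoke, "followup_years"].sum()
        closed_form = np.log(rate1 / rate0)
        b = fit["coefficient"].iloc[1]
        assert b == pytest.approx(closed_form, abs=3 * fit["se"].iloc[1])

    def test_too_few_events_rejected(self):
        df = simulate_from_spec(100, 0.5, -0.3, lam=0.0005, seed=4)
        with pytest.raises(RecalibrationError, match="events"):
            refit_coefficients(df, two_term_spec())

    def test_band_terms_refit_as_indicators(self, builtin_specs, male_cohort):
        spec = builtin_specs["CN-ICVD/male"]
        X, layout = design_matrix(male_cohort, spec)
        # 1 age + 5 SBP bands + 1 BMI band + 2 TC bands + smoker + diabetes
        assert X.shape[1] == 11
        band_cols = [name for _, b, name in layout if b is not None]
        assert all(set(np.unique(X[c])) <= {0.0, 1.0} for c in band_cols)


class TestMeanLp:
    def test_identical_cohort_reduces_to_single_profile(self, builtin_specs):
        spec = builtin_specs["general-FRS/male"]
        df = make_cohort(n=20, seed=1, sex="male")
        for c in ("age", "total_cholesterol", "hdl", "sbp", "bmi",
                  "bp_treated", "current_smoker", "diabetes"):
            df[c] = df[c].iloc[0]
        assert mean_lp(df, spec) == pytest.approx(
            float(linear_predictor(df.iloc[0], spec)))

    def test_zero_coefficient_spec(self):
        spec = two_term_spec(0.0, 0.0)
        df = simulate_from_spec(50, 0, 0, seed=5)
        assert mean_lp(df, spec) == 0.0

    def test_matches_per_row_loop(self, builtin_specs, male_cohort):
        spec = builtin_specs["simplified-FRS/male"]
        loop = np.mean([float(linear_predictor(male_cohort.iloc[i], spec))
                        for i in range(100)])
        assert mean_lp(male_cohort.head(100), spec) == pytest.approx(loop)


class TestBaselineSurvival:
    def test_zero_coefficients_reduce_to_km(self):
        df = simulate_from_spec(4000, 0.0, 0.0, lam=0.05, seed=6)
        spec = two_term_spec(0.0, 0.0)
        s0 = baseline_survival_at(df, spec, 5.0)
        km, _ = km_estimate(df["followup_years"], df["cvd_death"], 5.0)
        assert s0 == pytest.approx(km, abs=0.01)

    def test_recovers_known_baseline(self):
        lam, beta = 0.03, 0.5
        df = simulate_from_spec(20000, beta, 0.0, lam=lam, seed=7)
        spec = two_term_spec(beta, 0.0)
        lbar = mean_lp(df, spec)
        s0 = baseline_survival_at(df, spec, 5.0)
        # S0 refers to the subject at L = lbar: S(5 | lp=lbar) = exp(-lam*5*e^lbar)
        truth = np.exp(-lam * 5.0 * np.exp(lbar))
        assert s0 == pytest.approx(truth, abs=0.01)

    def test_monotone_in_horizon(self):
        df = simulate_from_spec(2000, 0.4, -0.2, lam=0.04, seed=8)
        spec = two_term_spec(0.4, -0.2)
        assert baseline_survival_at(df, spec, 5.0) >= baseline_survival_at(df, spec, 5.9)

    def test_horizon_beyond_followup_rejected(self):
        df = simulate_from_spec(200, 0.2, 0.0, lam=0.05, seed=9)
        spec = two_term_spec()
        with pytest.raises(ValueError, match="horizon"):
            baseline_survival_at(df, spec, 50.0)


class TestRecalibrate:
    def test_self_recalibration_closure(self):
        # recalibrating a model on a large cohort drawn from it leaves
        # per-subject risks nearly unchanged
        beta_age, beta_smoke, lam = 0.5, -0.3, 0.004
        df = simulate_from_spec(50000, beta_age, beta_smoke, lam=lam, seed=10)
        truth = model_spec_from_dict({
            **two_term_spec(beta_age, beta_smoke).to_dict(),
            "baseline_survival": {"5": float(np.exp(-lam * 5.0))},
        })
        # express truth centred at its own cohort mean
        lbar = mean_lp(df, truth)
        truth.mean_lp = lbar
        truth.baseline_survival = {5.0: float(np.exp(-lam * 5.0 * np.exp(lbar - lbar))
                                              ** np.exp(lbar))}
        recal = recalibrate(df, truth, mode="full", h=5.0)
        r_true = score_cohort(df, truth, 5)
        r_new = score_cohort(df, recal, 5)
        assert np.median(np.abs(r_true - r_new)) < 0.002

    def test_mean_only_keeps_coefficients(self, builtin_specs, male_cohort):
        spec = builtin_specs["general-FRS/male"]
        recal = recalibrate(male_cohort, spec, mode="mean_only", h=5.0)
        assert [t.coefficient for t in recal.terms] == \
               [t.coefficient for t in spec.terms]
        assert recal.mean_lp == pytest.approx(mean_lp(male_cohort, spec))
        assert 5.0 in recal.baseline_survival

    def test_provenance_and_validity(self, builtin_specs, male_cohort):
        spec = builtin_specs["general-FRS/male"]
        recal = recalibrate(male_cohort, spec, mode="mean_only", h=5.0,
                            date="2026-09-24")
        prov = recal.metadata["recalibration"]
        assert prov["mode"] == "mean_only" and prov["date"] == "2026-09-24"
        assert len(prov["cohort_hash"]) == 16
        # output passed full spec validation inside recalibrate()

    def test_weibull_spec_rejected(self, builtin_specs, male_cohort):
        with pytest.raises(ValueError, match="cox_form"):
            recalibrate(male_cohort, builtin_specs["SCORE-high/male"])

    def test_mean_only_and_full_agree_when_coefficients_match(self):
        beta_age, beta_smoke = 0.5, -0.3
        df = simulate_from_spec(20000, beta_age, beta_smoke, lam=0.01, seed=11)
        base = two_term_spec(beta_age, beta_smoke)
        full = recalibrate(df, base, mode="full", h=5.0)
        mean_only_of_full = recalibrate(df, full, mode="mean_only", h=5.0)
        assert mean_only_of_full.mean_lp == pytest.approx(full.mean_lp)
        assert mean_only_of_full.baseline_survival[5.0] == pytest.approx(
            full.baseline_survival[5.0])


class TestAdjustScoreSpec:
    def test_default_multipliers(self, builtin_specs):
        spec = builtin_specs["SCORE-low/female"].model_copy(deep=True)
        spec.diabetes_multiplier = None
        adj = adjust_score_spec(spec)
        assert adj.diabetes_multiplier == {"male": 3.0, "female": 5.0}

    def test_unit_multipliers_leave_predictions_unchanged(self, builtin_specs):
        spec = builtin_specs["SCORE-high/female"]
        unit = adjust_score_spec(spec, (1.0, 1.0))
        df = make_cohort(n=40, seed=3, sex="female")
        base = score_cohort(df, spec, 10, diabetes_adjust=False)
        same = score_cohort(df, unit, 10)
        assert np.allclose(base, same)

    def test_diabetic_female_risk_exactly_five_fold_below_cap(self, builtin_specs):
        spec = adjust_score_spec(builtin_specs["SCORE-high/female"])
        df = make_cohort(n=2, seed=4, sex="female")
        df["diabetes"] = [0, 1]
        for c in ("age", "total_cholesterol", "sbp", "current_smoker"):
            df[c] = df[c].iloc[0]
        risks = score_cohort(df, spec, 10)
        assert risks.iloc[1] == pytest.approx(5 * risks.iloc[0])

    def test_sub_unit_multiplier_warns(self, builtin_specs):
        with pytest.warns(UserWarning, match="below 1"):
            adjust_score_spec(builtin_specs["SCORE-low/male"], (0.5, 0.5))
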
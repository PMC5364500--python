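"""Risk-engine arithmetic against hand-computed oracles and invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cvdrisk.engine import (ScoringError, apply_diabetes_multiplier,
                            cox_form_risk, linear_predictor,
                            rescale_baseline_survival, score_cohort,
                            score_cohort_by_sex, weibull_score_risk)
from cvdrisk.specs import model_spec_from_dict
from cvdrisk.units import convert_units

from conftest import make_cohort

MGDL_PER_MMOL = 38.67


def base_profile(**kw):
    p = {"sex": "male", "age": 55.0, "total_cholesterol": 4.42, "hdl": 1.11,
         "sbp": 125.0, "bmi": 23.0, "bp_treated": 0, "current_smoker": 0,
         "diabetes": 0}
    p.update(kw)
    return p


class TestUnits:
    @pytest.mark.parametrize("value, quantity, target, expected", [
        (1.0, "TC", "mg/dL", 38.67),
        (38.67, "TC", "mmol/L", 1.0),
        (5.0, "glucose", "mg/dL", 90.1),
        (2.0, "HDL", "mg/dL", 77.34),
    ])
    def test_conversion_constants(self, value, quantity, target, expected):
        assert convert_units(value, quantity, target) == pytest.approx(expected)

    def test_unknown_quantity_rejected(self):
        with pytest.raises(ValueError, match="unknown quantity"):
            convert_units(1.0, "creatinine", "mg/dL")
        with pytest.raises(ValueError, match="unknown target"):
            convert_units(1.0, "TC", "g/L")

    @given(st.floats(0.1, 50))
    def test_roundtrip_identity(self, x):
        back = convert_units(convert_units(x, "TC", "mg/dL"), "TC", "mmol/L")
        assert back == pytest.approx(x, rel=1e-12)


class TestLinearPredictor:
    def test_cn_icvd_all_referent_reduces_to_age_term(self, builtin_specs):
        spec = builtin_specs["CN-ICVD/male"]
        for age in (42.0, 55.0, 63.0):
            prof = base_profile(age=age, sbp=125, bmi=23, total_cholesterol=3.0)
            assert linear_predictor(prof, spec) == pytest.approx(0.0844 * age)

    def test_zero_coefficient_spec_gives_zero(self):
        spec = model_spec_from_dict({
            "model_id": "zero", "sex": "male", "family": "cox_form",
            "native_horizon": 5, "baseline_survival": {"5": 0.99}, "mean_lp": 0.0,
            "terms": [{"covariate": "age", "transform": "log", "coefficient": 0.0},
                      {"covariate": "sbp", "transform": "identity", "coefficient": 0.0}],
        })
        assert linear_predictor(base_profile(age=61, sbp=170), spec) == 0.0

    def test_general_frs_hand_summation(self, builtin_specs):
        # term-by-term hand evaluation of the six active published terms
        spec = builtin_specs["general-FRS/male"]
        prof = base_profile()
        hand = (5.1215 * math.log(55)
                - 0.2727 * math.log(4.42 * MGDL_PER_MMOL)
                - 0.4596 * math.log(1.11 * MGDL_PER_MMOL)
                + 3.2282 * math.log(125))
        assert linear_predictor(prof, spec) == pytest.approx(hand, rel=1e-12)

    def test_treated_condition_switches_sbp_coefficient(self, builtin_specs):
        spec = builtin_specs["general-FRS/male"]
        lo = linear_predictor(base_profile(bp_treated=0), spec)
        hi = linear_predictor(base_profile(bp_treated=1), spec)
        assert hi - lo == pytest.approx((3.3088 - 3.2282) * math.log(125))

    def test_pce_product_terms_hand_oracle(self, builtin_specs):
        spec = builtin_specs["PCE-white/female"]
        prof = base_profile(sex="female", age=60, total_cholesterol=5.0,
                            hdl=1.3, sbp=140, current_smoker=1)
        la = math.log(60)
        ltc = math.log(5.0 * MGDL_PER_MMOL)
        lhdl = math.log(1.3 * MGDL_PER_MMOL)
        hand = (-22.3973 * la + 1.7899 * la * la + 15.0642 * ltc
                + 3.5038 * la * ltc + 5.1555 * lhdl - 1.4068 * la * lhdl
                + 3.4459 * math.log(140) + 17.8261 - 5.6228 * la)
        assert linear_predictor(prof, spec) == pytest.approx(hand, rel=1e-12)

    def test_missing_covariate_named_in_error(self, builtin_specs):
        spec = builtin_specs["general-FRS/male"]
        prof = base_profile()
        del prof["hdl"]
        with pytest.raises(ScoringError, match="hdl"):
            linear_predictor(prof, spec)

    def test_nonpositive_log_input_rejected(self, builtin_specs):
        spec = builtin_specs["general-FRS/male"]
        with pytest.raises(ScoringError, match="non-positive"):
            linear_predictor(base_profile(total_cholesterol=-1.0), spec)


class TestCoxFormRisk:
    def test_risk_at_mean_lp_equals_one_minus_s0_all_fixtures(self, builtin_specs):
        # forced arithmetic: exp(L - Lbar) = 1 at the population mean
        for key, spec in builtin_specs.items():
            if spec.family != "cox_form":
                continue
            tweaked = spec.model_copy(deep=True)
            tweaked.mean_lp = 0.0
            prof = base_profile(sex=spec.sex)
            prof_df = pd.DataFrame([prof])
            L = linear_predictor(prof_df, tweaked)[0]
            tweaked.mean_lp = L
            s5 = spec.baseline_survival[5.0]
            assert cox_form_risk(prof, tweaked, 5) == pytest.approx(1 - s5, abs=1e-12), key

    def test_limit_behaviour(self, builtin_specs):
        spec = builtin_specs["general-FRS/male"].model_copy(deep=True)
        spec.mean_lp = 1e4  # L - Lbar -> -inf
        assert cox_form_risk(base_profile(), spec, 5) == pytest.approx(0.0, abs=1e-12)
        spec.mean_lp = -1e4  # L - Lbar -> +inf
        assert cox_form_risk(base_profile(), spec, 5) == pytest.approx(1.0, abs=1e-12)

    def test_cn_icvd_women_brute_force(self, builtin_specs):
        spec = builtin_specs["CN-ICVD/female"]
        prof = base_profile(sex="female", age=58, sbp=145, bmi=26.5,
                            total_cholesterol=5.5, current_smoker=1, diabetes=1)
        L = 0.0878 * 58 + 0.4560 - 0.0624 - 0.8578 - 3.3481 + 0.8233
        expected = 1 - 0.9931033 ** math.exp(L - 3.976495)
        assert cox_form_risk(prof, spec, 5) == pytest.approx(expected, rel=1e-12)

    def test_unavailable_horizon_errors_unless_rescaled(self, builtin_specs):
        spec = builtin_specs["general-FRS/male"]
        with pytest.raises(ScoringError, match="horizon"):
            cox_form_risk(base_profile(), spec, 10)
        r10 = cox_form_risk(base_profile(), spec, 10, rescale=True)
        r5 = cox_form_risk(base_profile(), spec, 5)
        assert r10 > r5

    @given(sbp=st.floats(100, 180))
    def test_monotone_in_sbp_with_positive_coefficient(self, builtin_specs, sbp):
        spec = builtin_specs["PCE-white/female"]
        lo = cox_form_risk(base_profile(sex="female", sbp=sbp), spec, 5)
        hi = cox_form_risk(base_profile(sex="female", sbp=sbp + 5), spec, 5)
        assert hi >= lo


class TestWeibullScoreRisk:
    def test_zero_horizon_gives_zero_risk(self, builtin_specs):
        params = builtin_specs["SCORE-high/male"].weibull
        assert weibull_score_risk(base_profile(), params, 0) == 0.0

    def test_covariate_free_reduction(self, builtin_specs):
        # TC 6, SBP 120, nonsmoker: w = 0, risk from alpha/p/age only
        params = builtin_specs["SCORE-high/male"].weibull
        prof = base_profile(total_cholesterol=6.0, sbp=120.0, current_smoker=0)
        total = 0.0
        for c in (params.chd, params.non_chd):
            s = lambda a: math.exp(-math.exp(c.alpha) * (a - 20) ** c.p)
            total += 1 - s(65) / s(55)
        assert weibull_score_risk(prof, params, 10) == pytest.approx(total, rel=1e-12)

    def test_per_cause_hand_evaluation(self):
        from cvdrisk.specs import WeibullCauseParams
        params = WeibullCauseParams.model_validate({
            "region": "high",
            "chd": {"alpha": -22.0, "p": 4.7, "beta_chol": 0.24,
                    "beta_sbp": 0.018, "beta_smoker": 0.7},
            "non_chd": {"alpha": -26.0, "p": 5.6, "beta_chol": 0.13,
                        "beta_sbp": 0.022, "beta_smoker": 0.5},
        })
        prof = base_profile(age=55, total_cholesterol=7.0, sbp=150, current_smoker=1)
        total = 0.0
        for c in (params.chd, params.non_chd):
            w = c.beta_chol * 1.0 + c.beta_sbp * 30.0 + c.beta_smoker
            s = lambda a: math.exp(-math.exp(c.alpha) * (a - 20) ** c.p)
            total += 1 - (s(65) / s(55)) ** math.exp(w)
        assert weibull_score_risk(prof, params, 10) == pytest.approx(total, rel=1e-12)

    def test_age_at_or_below_20_rejected(self, builtin_specs):
        params = builtin_specs["SCORE-high/male"].weibull
        with pytest.raises(ScoringError, match="age"):
            weibull_score_risk(base_profile(age=20), params, 10)


class TestDiabetesMultiplier:
    @pytest.mark.parametrize("risk, sex, diabetic, expected", [
        (0.02, "male", True, 0.06),
        (0.02, "female", False, 0.02),
        (0.30, "female", True, 1.0),
        (0.02, "female", True, 0.10),
    ])
    def test_multiplier_rule(self, risk, sex, diabetic, expected):
        assert apply_diabetes_multiplier(risk, sex, diabetic) == pytest.approx(expected)


class TestRescaleBaselineSurvival:
    def test_identity_at_native_horizon(self):
        assert rescale_baseline_survival(0.99, 10, 10) == pytest.approx(0.99)

    def test_constant_hazard_fraction_exact_case(self):
        assert rescale_baseline_survival(0.9604, 10, 5) == pytest.approx(0.98)

    @given(st.floats(0.5, 0.999), st.floats(1, 10), st.floats(1, 10))
    def test_monotone_in_target_horizon(self, s0, h1, h2):
        lo_h, hi_h = sorted([h1, h2])
        assert (rescale_baseline_survival(s0, 10, lo_h)
                >= rescale_baseline_survival(s0, 10, hi_h))


class TestScoreCohort:
    def test_single_row_matches_scalar_call(self, builtin_specs):
        spec = builtin_specs["general-FRS/male"]
        df = make_cohort(n=1, seed=3, sex="male")
        vec = score_cohort(df, spec, 5)
        assert len(vec) == 1
        assert vec.iloc[0] == pytest.approx(cox_form_risk(df.iloc[0], spec, 5))

    def test_permutation_equivariance(self, builtin_specs):
        spec = builtin_specs["CN-ICVD/female"]
        df = make_cohort(n=60, seed=8, sex="female")
        perm = df.sample(frac=1, random_state=1)
        assert np.allclose(score_cohort(perm, spec, 5).to_numpy(),
                           score_cohort(df, spec, 5).loc[perm.index].to_numpy())

    @pytest.mark.parametrize("key", ["general-FRS/male", "PCE-AA/female",
                                     "SCORE-low/male"])
    def test_vectorized_matches_loop_of_single_calls(self, key, builtin_specs):
        spec = builtin_specs[key]
        df = make_cohort(n=100, seed=11, sex=spec.sex)
        vec = score_cohort(df, spec, 5, rescale=True).to_numpy()
        for i in (0, 17, 42, 99):
            row = df.iloc[i]
            if spec.family == "cox_form":
                single = cox_form_risk(row, spec, 5)
            else:
                single = weibull_score_risk(row, spec.weibull, 5)
                single = apply_diabetes_multiplier(single, row["sex"], row["diabetes"])
            assert vec[i] == pytest.approx(single, rel=1e-12)

    def test_sex_mismatch_raises_with_subject_reference(self, builtin_specs):
        spec = builtin_specs["general-FRS/male"]
        df = make_cohort(n=10, seed=2)
        if (df["sex"] == "male").all():
            df.loc[df.index[0], "sex"] = "female"
        with pytest.raises(ScoringError, match="do not match spec sex"):
            score_cohort(df, spec, 5)

    def test_mixed_cohort_routed_by_sex(self, builtin_specs):
        m, f = builtin_specs["general-FRS/male"], builtin_specs["general-FRS/female"]
        df = make_cohort(n=80, seed=5)
        both = score_cohort_by_sex(df, m, f, 5)
        males = df["sex"] == "male"
        assert np.allclose(both[males], score_cohort(df[males], m, 5))
        assert np.allclose(both[~males], score_cohort(df[~males], f, 5))
        assert ((both >= 0) & (both <= 1)).all()
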
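"""Risk-equation evaluation engine.

Computes absolute CVD-mortality risk for individual profiles or whole
cohorts under any :class:`~cvdrisk.specs.ModelSpec`.  All model math is
driven by the spec file; the engine only knows the two families:

* ``cox_form``:  risk(h) = 1 - S0(h) ** exp(L - Lbar)
* ``weibull_score``:  per-cause Weibull survival S0(a) = exp(-exp(alpha) *
  (a - 20)**p), proportional hazards on w, risk over h = 1 - S(a+h)/S(a),
  summed over the CHD and non-CHD causes.

Canonical profile units are the cohort-file units: mmol/L for lipids and
glucose, mmHg for SBP, kg/m2 for BMI, years for age.  Conversion to a
spec's expected units (``spec.units``) happens here, at the term boundary.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .specs import Band, ModelSpec, TermSpec, WeibullCauseParams
from .units import convert_units

__all__ = [
    "linear_predictor",
    "cox_form_risk",
    "weibull_score_risk",
    "apply_diabetes_multiplier",
    "rescale_baseline_survival",
    "score_cohort",
    "score_cohort_by_sex",
]

#: covariates whose canonical unit is mmol/L
_MMOL_COVARIATES = {"total_cholesterol", "hdl", "glucose"}

AGE_RANGE = (20.0, 100.0)


class ScoringError(ValueError):
    """Raised when a profile cannot be scored under a spec."""


def _as_frame(profile) -> pd.DataFrame:
    if isinstance(profile, pd.DataFrame):
        return profile
    if isinstance(profile, pd.Series):
        return profile.to_frame().T
    if isinstance(profile, Mapping):
        return pd.DataFrame([profile])
    raise TypeError(f"profile must be a mapping, Series or DataFrame, got {type(profile)}")


def _covariate_values(df: pd.DataFrame, name: str, spec: ModelSpec) -> np.ndarray:
    if name not in df.columns:
        raise ScoringError(f"profile is missing covariate {name!r} required by {spec.model_id}")
    x = df[name].to_numpy()
    if name in _MMOL_COVARIATES and spec.units.get(name) == "mg/dL":
        x = convert_units(x.astype(float), name, "mg/dL")
    return x


def _transformed(df: pd.DataFrame, covariate: str, transform: str, spec: ModelSpec) -> np.ndarray:
    x = _covariate_values(df, covariate, spec)
    if transform == "identity":
        return x.astype(float)
    if transform == "log":
        x = x.astype(float)
        if np.any(x <= 0):
            raise ScoringError(
                f"non-positive value for log-transformed covariate {covariate!r}"
            )
        return np.log(x)
    raise ScoringError(f"unsupported factor transform {transform!r}")


def _band_value(x: np.ndarray, bands: list[Band]) -> np.ndarray:
    """Coefficient of the half-open band [lo, hi) containing each x."""
    edges = np.array([b.lo if b.lo is not None else -np.inf for b in bands] +
                     [np.inf])
    coefs = np.array([b.coefficient for b in bands])
    idx = np.searchsorted(edges, x, side="right") - 1
    return coefs[np.clip(idx, 0, len(coefs) - 1)]


def _condition_mask(df: pd.DataFrame, term: TermSpec, spec: ModelSpec) -> np.ndarray:
    if term.condition is None:
        return np.ones(len(df), dtype=bool)
    cov = term.condition.covariate
    if cov not in df.columns:
        raise ScoringError(f"profile is missing covariate {cov!r} used in a term condition")
    vals = df[cov].to_numpy()
    target = term.condition.equals
    if isinstance(target, bool):
        return vals.astype(bool) == target
    return vals == target


def _term_contribution(df: pd.DataFrame, term: TermSpec, spec: ModelSpec) -> np.ndarray:
    if term.transform == "band":
        x = _covariate_values(df, term.covariate, spec).astype(float)
        contrib = _band_value(x, term.bands)
    elif term.transform == "product":
        f1, f2 = term.factors
        contrib = term.coefficient * (
            _transformed(df, f1.covariate, f1.transform, spec)
            * _transformed(df, f2.covariate, f2.transform, spec)
        )
    else:
        contrib = term.coefficient * _transformed(df, term.covariate, term.transform, spec)
    mask = _condition_mask(df, term, spec)
    return np.where(mask, contrib, 0.0)


def linear_predictor(profile, spec: ModelSpec) -> np.ndarray | float:
    """Linear predictor L = sum of coefficient x transformed covariate.

    ``profile`` may be a mapping (single subject), a Series, or a DataFrame
    (one row per subject).  Returns a scalar for single profiles, an array
    otherwise.
    """
    if spec.family != "cox_form":
        raise ScoringError(f"{spec.model_id} is not a cox_form model")
    scalar = not isinstance(profile, pd.DataFrame)
    df = _as_frame(profile)
    L = np.zeros(len(df))
    for term in spec.terms:
        L = L + _term_contribution(df, term, spec)
    return float(L[0]) if scalar and len(L) == 1 else L


def rescale_baseline_survival(s0_native: float, native_h: float, target_h: float) -> float:
    """Move baseline survival between horizons assuming a constant hazard
    fraction: S0(h) = exp(ln S0(H) * h / H).

    This is an explicit, overridable assumption; a cohort-estimated S0 from
    :func:`cvdrisk.recalibration.baseline_survival_at` is preferred when a
    target cohort is available.
    """
    if not (0.0 < s0_native < 1.0):
        raise ValueError(f"s0_native {s0_native} must be strictly in (0, 1)")
    if native_h <= 0 or target_h <= 0:
        raise ValueError("horizons must be positive")
    return float(math.exp(math.log(s0_native) * target_h / native_h))


def _baseline_survival_at(spec: ModelSpec, horizon: float, rescale: bool) -> float:
    bs = spec.baseline_survival
    if horizon in bs:
        return bs[horizon]
    if not rescale:
        raise ScoringError(
            f"{spec.model_id} has no baseline survival at horizon {horizon} "
            f"(available: {sorted(bs)}); pass rescale=True to use the "
            "constant-hazard-fraction rescaling"
        )
    native_h = spec.native_horizon if spec.native_horizon in bs else max(bs)
    return rescale_baseline_survival(bs[native_h], native_h, horizon)


def cox_form_risk(profile, spec: ModelSpec, horizon: float | None = None,
                  rescale: bool = False) -> np.ndarray | float:
    """Absolute risk 1 - S0(h)^exp(L - Lbar), clipped to [0, 1]."""
    if horizon is None:
        horizon = spec.native_horizon
    s0 = _baseline_survival_at(spec, float(horizon), rescale)
    L = linear_predictor(profile, spec)
    with np.errstate(over="ignore"):  # exp overflow -> risk saturates at 1
        risk = 1.0 - np.power(s0, np.exp(np.asarray(L, dtype=float) - spec.mean_lp))
    risk = np.clip(risk, 0.0, 1.0)
    return float(risk) if np.ndim(L) == 0 else risk


def weibull_score_risk(profile, params: WeibullCauseParams, horizon: float,
                       units: Mapping[str, str] | None = None) -> np.ndarray | float:
    """Total CVD-mortality risk over ``horizon`` under a SCORE-family spec.

    Per cause: S0(a) = exp(-exp(alpha) * (a - 20)**p);
    w = beta_chol*(TC - 6) + beta_sbp*(SBP - 120) + beta_smoker*smoker;
    S(a) = S0(a)^exp(w); cause risk = 1 - S(a+h)/S(a).  The two cause risks
    (CHD and non-CHD CVD) are summed and clipped to [0, 1].

    Cholesterol is expected in mmol/L, SBP in mmHg (SCORE's native units).
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    scalar = not isinstance(profile, pd.DataFrame)
    df = _as_frame(profile)
    age = df["age"].to_numpy(dtype=float)
    if np.any(age <= 20):
        raise ScoringError("weibull_score risk is undefined for age <= 20")
    tc = df["total_cholesterol"].to_numpy(dtype=float)
    sbp = df["sbp"].to_numpy(dtype=float)
    smoker = df["current_smoker"].to_numpy(dtype=float)

    total = np.zeros(len(df))
    for cause in (params.chd, params.non_chd):
        w = (cause.beta_chol * (tc - 6.0) + cause.beta_sbp * (sbp - 120.0)
             + cause.beta_smoker * smoker)

        def s(a):
            return np.exp(-np.exp(cause.alpha) * np.power(a - 20.0, cause.p))

        surv_ratio = np.power(s(age + horizon) / s(age), np.exp(w))
        total += 1.0 - surv_ratio
    total = np.clip(total, 0.0, 1.0)
    return float(total[0]) if scalar and len(total) == 1 else total


def apply_diabetes_multiplier(risk, sex, diabetic, male_factor: float = 3.0,
                              female_factor: float = 5.0):
    """Scale predicted risk for diabetic subjects (x3 men, x5 women),
    capping at 1. Non-diabetic risks pass through unchanged."""
    risk = np.asarray(risk, dtype=float)
    scalar = risk.ndim == 0
    risk = np.atleast_1d(risk)
    sex = np.atleast_1d(np.asarray(sex))
    diabetic = np.atleast_1d(np.asarray(diabetic)).astype(bool)
    m = np.where(sex == "male", male_factor, female_factor)
    out = np.where(diabetic, np.minimum(1.0, m * risk), risk)
    return float(out[0]) if scalar else out


def score_cohort(cohort: pd.DataFrame, spec: ModelSpec, horizon: float | None = None,
                 diabetes_adjust: bool | None = None, rescale: bool = False) -> pd.Series:
    """Vectorized per-subject risk under one spec.

    All rows must match ``spec.sex`` (use :func:`score_cohort_by_sex` for a
    mixed cohort).  Returns a Series indexed like ``cohort``.

    ``diabetes_adjust``: ``None`` applies a multiplier only if the spec
    carries one (see :func:`cvdrisk.recalibration.adjust_score_spec`);
    ``True`` forces the default x3/x5 rule; ``False`` disables it.
    """
    if "sex" in cohort.columns:
        mismatched = cohort.index[cohort["sex"] != spec.sex]
        if len(mismatched):
            raise ScoringError(
                f"{len(mismatched)} subject(s) (e.g. id index {mismatched[0]!r}) do not "
                f"match spec sex {spec.sex!r}; score sexes with their paired specs"
            )
    if horizon is None:
        horizon = spec.native_horizon
    if spec.family == "cox_form":
        risk = cox_form_risk(cohort, spec, horizon, rescale=rescale)
    else:
        risk = weibull_score_risk(cohort, spec.weibull, horizon)
    if diabetes_adjust is None:
        diabetes_adjust = spec.diabetes_multiplier is not None
    if diabetes_adjust:
        mult = spec.diabetes_multiplier or {"male": 3.0, "female": 5.0}
        risk = apply_diabetes_multiplier(
            risk, cohort["sex"].to_numpy() if "sex" in cohort.columns else spec.sex,
            cohort["diabetes"].to_numpy(),
            male_factor=mult.get("male", 3.0), female_factor=mult.get("female", 5.0),
        )
    return pd.Series(np.atleast_1d(risk), index=cohort.index, name=spec.model_id)


def score_cohort_by_sex(cohort: pd.DataFrame, spec_male: ModelSpec,
                        spec_female: ModelSpec, horizon: float | None = None,
                        diabetes_adjust: bool | None = None,
                        rescale: bool = False) -> pd.Series:
    """Score a mixed-sex cohort with the paired sex-specific specs."""
    out = pd.Series(np.nan, index=cohort.index, dtype=float,
                    name=spec_male.model_id)
    for spec in (spec_male, spec_female):
        mask = cohort["sex"] == spec.sex
        if mask.any():
            out.loc[mask] = score_cohort(cohort.loc[mask], spec, horizon,
                                         diabetes_adjust, rescale)
    return out
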
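"""Recalibration of risk equations to a target cohort.

Two modes reproduce the two published constructions:

``mean_only``
    Keep the original coefficients; replace the mean linear predictor
    ("Mean (Coefficient x Value)") and the baseline survival S0(h) with
    cohort estimates.

``full``
    Additionally refit all coefficients by Cox partial likelihood using
    exactly the spec's covariate structure (same transforms, bands,
    interactions and treated/untreated split), then recompute the mean
    linear predictor and baseline survival.

The baseline survival is a Breslow cumulative-hazard estimate centered at
the mean linear predictor, matching the risk formula
``1 - S0(h)^exp(L - Lbar)``.
"""

from __future__ import annotations

import hashlib
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .engine import _term_contribution, linear_predictor
from .specs import ModelSpec, TermSpec, model_spec_from_dict

__all__ = ["refit_coefficients", "mean_lp", "baseline_survival_at",
           "recalibrate", "adjust_score_spec", "design_matrix"]


class RecalibrationError(RuntimeError):
    """Raised when a coefficient refit fails to converge or separates."""


def _term_column_name(i: int, term: TermSpec) -> str:
    if term.label:
        return f"t{i}:{term.label}"
    return f"t{i}:{term.covariate or 'product'}:{term.transform}"


def design_matrix(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, list]:
    """Per-term design columns for a partial-likelihood refit.

    Simple and product terms contribute one column of the transformed
    (condition-masked) covariate; band terms contribute one indicator
    column per non-referent band (referent bands are the baseline).
    Returns ``(X, layout)`` where ``layout`` maps columns back to terms.
    """
    if spec.family != "cox_form":
        raise ValueError("design_matrix requires a cox_form spec")
    cols = {}
    layout = []  # (term_index, band_index or None, column_name)
    for i, term in enumerate(spec.terms):
        if term.transform == "band":
            from .engine import _covariate_values, _condition_mask
            x = _covariate_values(cohort, term.covariate, spec).astype(float)
            mask = _condition_mask(cohort, term, spec)
            for j, band in enumerate(term.bands):
                if band.coefficient == 0.0:
                    continue  # referent band
                lo = band.lo if band.lo is not None else -np.inf
                hi = band.hi if band.hi is not None else np.inf
                name = f"{_term_column_name(i, term)}[{band.lo},{band.hi})"
                cols[name] = ((x >= lo) & (x < hi) & mask).astype(float)
                layout.append((i, j, name))
        else:
            unit = term.model_copy(deep=True)
            unit.coefficient = 1.0
            name = _term_column_name(i, term)
            cols[name] = _term_contribution(cohort, unit, spec)
            layout.append((i, None, name))
    return pd.DataFrame(cols, index=cohort.index), layout


def refit_coefficients(cohort: pd.DataFrame, spec: ModelSpec,
                       min_events: int = 30) -> tuple[ModelSpec, pd.DataFrame]:
    """Cox partial-likelihood refit of the spec's coefficients on a cohort.

    Returns ``(spec_with_new_coefficients, fit_table)`` where the fit table
    carries per-column coefficients and standard errors.  The returned spec
    still has the *original* mean_lp / baseline_survival; use
    :func:`recalibrate` for the complete construction.
    """
    n_events = int(cohort["cvd_death"].sum())
    if n_events < min_events:
        raise RecalibrationError(
            f"cohort has {n_events} events; at least {min_events} required for a refit")
    X, layout = design_matrix(cohort, spec)
    data = X.copy()
    data["followup_years"] = cohort["followup_years"].to_numpy()
    data["cvd_death"] = cohort["cvd_death"].to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="followup_years", event_col="cvd_death")
    except ConvergenceError as exc:
        raise RecalibrationError(
            f"partial-likelihood fit did not converge (possible separation "
            f"or collinearity): {exc}") from exc
    coefs = cph.params_
    if not np.isfinite(coefs).all() or np.abs(coefs).max() > 1e3:
        raise RecalibrationError(
            "fit produced unstable coefficients (possible separation): "
            f"{coefs.to_dict()}")
    new = spec.model_copy(deep=True)
    for term_idx, band_idx, name in layout:
        if band_idx is None:
            new.terms[term_idx].coefficient = float(coefs[name])
        else:
            new.terms[term_idx].bands[band_idx].coefficient = float(coefs[name])
    fit = pd.DataFrame({"coefficient": cph.params_, "se": cph.standard_errors_})
    return new, fit


def mean_lp(cohort: pd.DataFrame, spec: ModelSpec) -> float:
    """Mean over subjects of the linear predictor ("Mean (Coefficient x Value)")."""
    return float(np.mean(linear_predictor(cohort, spec)))


def baseline_survival_at(cohort: pd.DataFrame, spec: ModelSpec, h: float) -> float:
    """Breslow baseline survival at ``h``, centered at the cohort's mean
    linear predictor: a subject with L = Lbar has survival S0(h)."""
    times = cohort["followup_years"].to_numpy(dtype=float)
    events = cohort["cvd_death"].to_numpy().astype(bool)
    if h > times.max():
        raise ValueError(f"horizon {h} exceeds the maximum follow-up {times.max():.3g}")
    L = np.asarray(linear_predictor(cohort, spec), dtype=float)
    lbar = L.mean()
    order = np.argsort(times, kind="stable")
    tt = times[order]
    ee = events[order]
    rr = np.exp(L - lbar)[order]
    risk_sum = np.cumsum(rr[::-1])[::-1]  # sum of exp(L - Lbar) over the risk set
    uniq, counts = np.unique(tt[ee & (tt <= h)], return_counts=True)
    pos = np.searchsorted(tt, uniq, side="left")
    h0 = float(np.sum(counts / risk_sum[pos]))
    return float(np.exp(-h0))


def recalibrate(cohort: pd.DataFrame, spec: ModelSpec, mode: str = "full",
                h: float = 5.0, min_events: int = 30,
                date: Optional[str] = None) -> ModelSpec:
    """Produce a recalibrated ModelSpec from a cohort.

    ``mode="mean_only"`` keeps the original coefficients and replaces
    mean_lp and baseline_survival[h]; ``mode="full"`` refits the
    coefficients first.  The output spec carries provenance metadata
    (mode, cohort hash, optional date) and passes all spec invariants.
    """
    if spec.family != "cox_form":
        raise ValueError("recalibrate applies to cox_form specs; use "
                         "adjust_score_spec for weibull_score models")
    if mode not in ("mean_only", "full"):
        raise ValueError(f"mode must be 'mean_only' or 'full', got {mode!r}")
    if mode == "full":
        new, _fit = refit_coefficients(cohort, spec, min_events=min_events)
    else:
        new = spec.model_copy(deep=True)
    lbar = mean_lp(cohort, new)
    new.mean_lp = lbar
    s0 = baseline_survival_at(cohort, new, h)
    new.baseline_survival = {float(h): s0}
    new.native_horizon = float(h)
    raw = pd.util.hash_pandas_object(cohort.reset_index(drop=True)).values.tobytes()
    provenance = {"mode": mode,
                  "cohort_hash": hashlib.sha256(raw).hexdigest()[:16],
                  "horizon": float(h)}
    if date is not None:
        provenance["date"] = date
    new.metadata = dict(new.metadata, recalibration=provenance)
    return model_spec_from_dict(new.to_dict())  # re-validate invariants


def adjust_score_spec(spec: ModelSpec, multipliers: tuple[float, float] = (3.0, 5.0)
                      ) -> ModelSpec:
    """Attach the diabetes multiplier rule (male, female) to a SCORE-family
    spec; the engine applies it at scoring time."""
    if spec.family != "weibull_score":
        raise ValueError("adjust_score_spec applies to weibull_score specs")
    male, female = multipliers
    if male < 1 or female < 1:
        import warnings
        warnings.warn("diabetes multiplier below 1 reduces predicted risk")
    new = spec.model_copy(deep=True)
    new.diabetes_multiplier = {"male": float(male), "female": float(female)}
    return new
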
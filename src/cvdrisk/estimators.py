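"""Scikit-learn style estimators wrapping the risk engine and recalibration.

These compose with sklearn model-selection utilities: ``get_params`` /
``set_params`` work, fitted attributes carry a trailing underscore, and
``predict`` accepts a cohort DataFrame.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import recalibration
from .engine import score_cohort, score_cohort_by_sex
from .specs import ModelSpec

__all__ = ["RiskScorer", "RiskRecalibrator"]


class RiskScorer(BaseEstimator):
    """Stateless predictor of absolute CVD-mortality risk under a spec.

    Parameters
    ----------
    spec : ModelSpec
        Equation to evaluate; for a mixed-sex cohort pass ``spec_female``
        too and rows are routed by their ``sex`` column.
    spec_female : ModelSpec, optional
        Paired female spec when ``spec`` is the male one.
    horizon : float, optional
        Prediction horizon in years (default: the spec's native horizon).
    diabetes_adjust : bool
        Apply the diabetes multiplier (x3 men, x5 women) to predictions.
    rescale : bool
        Allow constant-hazard-fraction rescaling of the baseline survival
        to a horizon the spec does not tabulate.
    """

    def __init__(self, spec: ModelSpec = None, spec_female: ModelSpec = None,
                 horizon: float | None = None, diabetes_adjust: bool | None = None,
                 rescale: bool = False):
        self.spec = spec
        self.spec_female = spec_female
        self.horizon = horizon
        self.diabetes_adjust = diabetes_adjust
        self.rescale = rescale

    def fit(self, X: pd.DataFrame = None, y=None) -> "RiskScorer":
        """No-op; present for pipeline compatibility."""
        if self.spec is None:
            raise ValueError("RiskScorer requires a spec")
        self.n_features_in_ = 0 if X is None else X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Per-subject absolute risk over the horizon."""
        if self.spec is None:
            raise ValueError("RiskScorer requires a spec")
        if self.spec_female is not None:
            s = score_cohort_by_sex(X, self.spec, self.spec_female,
                                    self.horizon, self.diabetes_adjust,
                                    self.rescale)
        else:
            s = score_cohort(X, self.spec, self.horizon,
                             self.diabetes_adjust, self.rescale)
        return s.to_numpy()


class RiskRecalibrator(BaseEstimator):
    """Fit a recalibrated version of a risk equation on a cohort.

    Parameters
    ----------
    spec : ModelSpec
        Base cox-form equation.
    mode : {"full", "mean_only"}
        Refit coefficients too, or only replace the mean linear predictor
        and baseline survival.
    horizon : float
        Horizon (years) at which the baseline survival is re-estimated.
    min_events : int
        Minimum events required for a coefficient refit.

    Attributes
    ----------
    spec_ : ModelSpec
        The recalibrated specification.
    mean_lp_ : float
        Cohort mean linear predictor.
    baseline_survival_ : float
        Breslow baseline survival at ``horizon``.
    """

    def __init__(self, spec: ModelSpec = None, mode: str = "full",
                 horizon: float = 5.0, min_events: int = 30):
        self.spec = spec
        self.mode = mode
        self.horizon = horizon
        self.min_events = min_events

    def fit(self, X: pd.DataFrame, y=None) -> "RiskRecalibrator":
        """Recalibrate on a cohort DataFrame carrying ``followup_years``
        and ``cvd_death`` columns (``y`` is ignored)."""
        if self.spec is None:
            raise ValueError("RiskRecalibrator requires a base spec")
        self.spec_ = recalibration.recalibrate(
            X, self.spec, mode=self.mode, h=self.horizon,
            min_events=self.min_events)
        self.mean_lp_ = self.spec_.mean_lp
        self.baseline_survival_ = self.spec_.baseline_survival[float(self.horizon)]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Absolute risk under the recalibrated equation."""
        if not hasattr(self, "spec_"):
            raise ValueError("RiskRecalibrator is not fitted")
        return score_cohort(X, self.spec_, self.horizon).to_numpy()
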
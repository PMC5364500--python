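"""Cross-model risk stratification, agreement and rank correlation."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .specs import ModelSpec

__all__ = ["stratify", "crosstab_agreement", "extreme_misclassification",
           "spearman_rho", "DEFAULT_FOUR_TO_THREE"]

#: declared mapping from the four-category PCE scale onto the three-category
#: low/intermediate/high scale used by the other model families
DEFAULT_FOUR_TO_THREE = {
    "<7.5%": "low",
    "7.5-9.9%": "intermediate",
    "10.0-19.9%": "intermediate",
    ">=20%": "high",
}


def _labels(spec: ModelSpec) -> list[str]:
    if spec.category_labels:
        return list(spec.category_labels)
    k = len(spec.thresholds) + 1
    if k == 3:
        return ["low", "intermediate", "high"]
    return [f"cat{i}" for i in range(k)]


def stratify(risk, spec: ModelSpec) -> pd.Categorical | str:
    """Risk category under the spec's thresholds (half-open intervals,
    upper category inclusive of its threshold: risk >= top cutpoint is the
    highest category)."""
    scalar = np.ndim(risk) == 0
    r = np.atleast_1d(np.asarray(risk, dtype=float))
    if np.any((r < 0) | (r > 1)):
        raise ValueError("risks must lie in [0, 1]")
    labels = _labels(spec)
    idx = np.searchsorted(spec.thresholds, r, side="right")
    cats = pd.Categorical.from_codes(idx, categories=labels, ordered=True)
    return cats[0] if scalar else cats


def _ordered(series) -> pd.Series:
    s = pd.Series(series)
    if not isinstance(s.dtype, pd.CategoricalDtype):
        s = s.astype(pd.CategoricalDtype(pd.unique(s), ordered=True))
    return s


def crosstab_agreement(cats_a, cats_b, mapping: dict | None = None
                       ) -> tuple[pd.DataFrame, float]:
    """Full contingency table and percent agreement between two category
    vectors.

    When the two category sets differ (e.g. four-category vs three-category
    scales) ``mapping`` translates the first vector's labels onto the
    second's before computing agreement; :data:`DEFAULT_FOUR_TO_THREE` is
    used when it applies.  The returned table is always the unmapped
    cross-tabulation.
    """
    a, b = _ordered(cats_a), _ordered(cats_b)
    if len(a) != len(b):
        raise ValueError(f"category vectors differ in length: {len(a)} vs {len(b)}")
    table = pd.crosstab(a.to_numpy(), b.to_numpy(), rownames=["model_a"],
                        colnames=["model_b"], dropna=False)
    set_a = set(a.cat.categories)
    set_b = set(b.cat.categories)
    four = set(DEFAULT_FOUR_TO_THREE)
    if mapping is not None:
        agree = (a.map(mapping).to_numpy() == b.astype(object).to_numpy()).mean()
    elif set_a != set_b and set_a <= four and not (set_b <= four):
        # map the four-category side onto the three-category side
        agree = (a.map(DEFAULT_FOUR_TO_THREE).to_numpy()
                 == b.astype(object).to_numpy()).mean()
    elif set_a != set_b and set_b <= four and not (set_a <= four):
        agree = (b.map(DEFAULT_FOUR_TO_THREE).to_numpy()
                 == a.astype(object).to_numpy()).mean()
    else:
        agree = (a.astype(object).to_numpy() == b.astype(object).to_numpy()).mean()
    return table, float(100.0 * agree)


def extreme_misclassification(cats_a, cats_b) -> int:
    """Number of subjects placed in the lowest category by one model and
    the highest by the other (either direction)."""
    a, b = _ordered(cats_a), _ordered(cats_b)
    if len(a) != len(b):
        raise ValueError(f"category vectors differ in length: {len(a)} vs {len(b)}")
    lo_a, hi_a = a.cat.categories[0], a.cat.categories[-1]
    lo_b, hi_b = b.cat.categories[0], b.cat.categories[-1]
    av, bv = a.to_numpy(object), b.to_numpy(object)
    return int(np.sum((av == lo_a) & (bv == hi_b)) +
               np.sum((av == hi_a) & (bv == lo_b)))


def spearman_rho(scores_a, scores_b) -> float:
    """Spearman rank correlation with midranks for ties; NaN (with a
    warning) when either vector is constant."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be aligned")
    if len(a) < 3:
        raise ValueError("need at least 3 subjects")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        warnings.warn("rank correlation undefined for a constant score vector")
        return float("nan")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)
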
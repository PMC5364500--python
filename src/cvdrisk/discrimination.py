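"""ROC-based discrimination metrics.

AUC (C-statistic) with DeLong confidence intervals, the paired DeLong test
for comparing two models on the same subjects, and operating-point metrics
(sensitivity, specificity, likelihood ratios) at recommended or
Youden-optimal cut-offs.

The event is binary CVD death within follow-up (not a censoring-adjusted
time-dependent AUC), matching how validation metrics are conventionally
tabulated for these models.  Classification at a threshold is inclusive:
positive iff score >= cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "DiscriminationResult", "roc_points", "auc_ci", "compare_auc_paired",
    "sens_spec_at", "optimal_cutoff",
]


@dataclass
class DiscriminationResult:
    """Operating-point and ranking metrics for one model.

    Sensitivity/specificity are percentages with 95% Clopper-Pearson CIs;
    likelihood ratios may be ``inf`` when a denominator is zero.
    """

    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    lr_pos: float
    lr_neg: float
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None
    model_id: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id, "cutoff": self.cutoff,
            "sensitivity": self.sensitivity, "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity, "specificity_ci": list(self.specificity_ci),
            "lr_pos": self.lr_pos, "lr_neg": self.lr_neg,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
            "metadata": self.metadata,
        }


def _check_two_classes(events: np.ndarray) -> None:
    if events.all() or not events.any():
        raise ValueError("both event and non-event subjects are required")


def _as_arrays(scores, events) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    events = np.asarray(events).astype(bool)
    if scores.shape != events.shape:
        raise ValueError(f"scores {scores.shape} and events {events.shape} differ in length")
    return scores, events


def roc_points(scores, events) -> np.ndarray:
    """Ordered (FPR, TPR) points, one per distinct threshold, from (0,0) to
    (1,1); tied scores are grouped."""
    scores, events = _as_arrays(scores, events)
    _check_two_classes(events)
    fpr, tpr, _ = roc_curve(events, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(scores, events):
    """DeLong structural components; returns (auc, var) for one model."""
    aucs, cov = _delong_cov(np.asarray(scores, float)[None, :], np.asarray(events, bool))
    return aucs[0], cov[0, 0]


def _delong_cov(score_mat: np.ndarray, events: np.ndarray):
    """AUCs and DeLong covariance matrix for k models scored on the same
    subjects (fast midrank algorithm)."""
    pos = score_mat[:, events]
    neg = score_mat[:, ~events]
    m, n = pos.shape[1], neg.shape[1]
    k = score_mat.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        all_r = np.concatenate([pos[r], neg[r]])
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(all_r)
        auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        aucs[r] = auc
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    cov = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return aucs, cov


def auc_ci(scores, events, level: float = 0.95) -> tuple[float, float, float]:
    """AUC (Mann-Whitney concordance, ties credited 0.5) with a DeLong
    normal-approximation confidence interval, clipped to [0, 1]."""
    scores, events = _as_arrays(scores, events)
    _check_two_classes(events)
    auc, var = _delong_variance(scores, events)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def compare_auc_paired(scores_a, scores_b, events) -> float:
    """Two-sided paired DeLong test p-value for AUC_a == AUC_b on the same
    subjects.  Identical score vectors give p = 1."""
    scores_a, events = _as_arrays(scores_a, events)
    scores_b, _ = _as_arrays(scores_b, events)
    _check_two_classes(events)
    if np.array_equal(scores_a, scores_b):
        return 1.0
    aucs, cov = _delong_cov(np.vstack([scores_a, scores_b]), events)
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0:
        return 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def _proportion_ci(k: int, n: int, level: float) -> tuple[float, float]:
    if n == 0:
        return (0.0, 100.0)
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return (100.0 * ci.low, 100.0 * ci.high)


def sens_spec_at(scores, events, cutoff: float, level: float = 0.95,
                 model_id: str | None = None) -> DiscriminationResult:
    """Sensitivity/specificity (percent, Clopper-Pearson CIs) and likelihood
    ratios classifying positive iff score >= cutoff."""
    scores, events = _as_arrays(scores, events)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pred = scores >= cutoff
    tp = int(np.sum(pred & events))
    fn = int(np.sum(~pred & events))
    tn = int(np.sum(~pred & ~events))
    fp = int(np.sum(pred & ~events))
    n1, n0 = tp + fn, tn + fp
    se = 100.0 * tp / n1 if n1 else 0.0
    sp = 100.0 * tn / n0 if n0 else 0.0
    lr_pos = (se / (100.0 - sp)) if sp < 100.0 else float("inf")
    lr_neg = ((100.0 - se) / sp) if sp > 0.0 else float("inf")
    return DiscriminationResult(
        cutoff=float(cutoff),
        sensitivity=se, sensitivity_ci=_proportion_ci(tp, n1, level),
        specificity=sp, specificity_ci=_proportion_ci(tn, n0, level),
        lr_pos=lr_pos, lr_neg=lr_neg, model_id=model_id,
        metadata={"classification_rule": ">= cutoff",
                  "ci_method": "Clopper-Pearson"},
    )


def optimal_cutoff(scores, events) -> float:
    """Cut-off among observed score values maximizing Youden J = Se + Sp - 1;
    ties are broken toward the smallest cutoff."""
    scores, events = _as_arrays(scores, events)
    _check_two_classes(events)
    cand = np.unique(scores)
    n1 = events.sum()
    n0 = len(events) - n1
    # classify positive iff score >= c: Se(c) = #(pos >= c)/n1, Sp = #(neg < c)/n0
    pos_sorted = np.sort(scores[events])
    neg_sorted = np.sort(scores[~events])
    se = 1.0 - np.searchsorted(pos_sorted, cand, side="left") / n1
    sp = np.searchsorted(neg_sorted, cand, side="left") / n0
    j = se + sp - 1.0
    best = np.flatnonzero(j == j.max())[0]
    return float(cand[best])
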
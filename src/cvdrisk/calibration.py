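"""Observed-vs-expected calibration against Kaplan-Meier survival.

Workflow: subjects are ranked into deciles of predicted risk, small deciles
are collapsed with their closest neighbours until every group holds a
minimum number of observed events, and the Greenwood-Nam-D'Agostino (GND)
chi-square statistic

    chi2 = sum_g (KM_observed_g - mean_predicted_g)**2 / Var_g(KM)

is referred to a chi-square distribution with G - 1 degrees of freedom
(G = number of groups).  ``Var_g`` is the Greenwood variance of the
group's Kaplan-Meier estimate by default; a binomial variance
p(1-p)/n is available as a declared alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RiskGroup", "GNDResult", "km_estimate", "form_groups",
           "gnd_test", "gnd_pvalue", "calibration_chart_data"]


@dataclass
class RiskGroup:
    """One calibration group, ordered by mean predicted risk."""

    indices: np.ndarray
    n: int
    mean_predicted: float
    km_observed: float       # 1 - KM survival at the horizon
    greenwood_var: float     # Greenwood variance of KM at the horizon
    observed_events: int     # events by the horizon
    expected_events: float   # n * mean_predicted


@dataclass
class GNDResult:
    """Greenwood-Nam-D'Agostino test result (df = groups - 1)."""

    chi2: float
    groups: int
    p_value: float = field(init=False)

    def __post_init__(self):
        if self.chi2 < 0:
            raise ValueError("chi2 must be non-negative")
        if self.groups < 2:
            raise ValueError("at least 2 groups are required")
        self.p_value = gnd_pvalue(self.chi2, self.groups)

    @property
    def df(self) -> int:
        return self.groups - 1


def gnd_pvalue(chi2: float, n_groups: int) -> float:
    """Upper-tail chi-square probability with df = n_groups - 1."""
    return float(stats.chi2.sf(chi2, n_groups - 1))


def km_estimate(times, events, t: float) -> tuple[float, float]:
    """Kaplan-Meier survival and Greenwood variance at time ``t``.

    Product-limit over event times <= t; ``t`` beyond the last observed
    time uses the last value.  Raises on empty input.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    if t < 0:
        raise ValueError("t must be non-negative")
    order = np.argsort(times, kind="stable")
    tt = times[order]
    ee = events[order]
    uniq, counts = np.unique(tt[ee & (tt <= t)], return_counts=True)
    if uniq.size == 0:
        return 1.0, 0.0
    at_risk = len(tt) - np.searchsorted(tt, uniq, side="left")
    frac = counts / at_risk
    surv = float(np.prod(1.0 - frac))
    if np.any(at_risk == counts):  # survival hits zero; variance degenerate
        return 0.0, 0.0
    var = surv ** 2 * float(np.sum(counts / (at_risk * (at_risk - counts))))
    return surv, var


def _initial_groups(predicted: np.ndarray, init_groups: int) -> list[np.ndarray]:
    """Decile-style groups by predicted risk, tied values kept together."""
    if np.unique(predicted).size == 1:
        return [np.arange(len(predicted))]
    ranks = pd.Series(predicted).rank(method="average").to_numpy()
    # quantile bin on midranks so ties land in a single bin
    qs = np.quantile(ranks, np.linspace(0, 1, init_groups + 1))
    qs = np.unique(qs)
    bins = np.clip(np.searchsorted(qs, ranks, side="right") - 1, 0, len(qs) - 2)
    groups = [np.flatnonzero(bins == b) for b in range(len(qs) - 1)]
    return [g for g in groups if g.size]


def _make_group(idx: np.ndarray, predicted, times, events, h) -> RiskGroup:
    surv, var = km_estimate(times[idx], events[idx], h)
    d = int(np.sum(events[idx] & (times[idx] <= h)))
    p = float(np.mean(predicted[idx]))
    return RiskGroup(indices=idx, n=len(idx), mean_predicted=p,
                     km_observed=1.0 - surv, greenwood_var=var,
                     observed_events=d, expected_events=len(idx) * p)


def form_groups(predicted, times, events, h: float, init_groups: int = 10,
                min_events: int = 2) -> list[RiskGroup]:
    """Risk groups for calibration testing, starting from ``init_groups``
    quantile groups and collapsing until every group has at least
    ``min_events`` observed events.

    The lowest-risk group violating the minimum is merged into the adjacent
    neighbour whose mean predicted risk is closer (edge groups merge
    inward); groups stay contiguous in risk order.
    """
    predicted = np.asarray(predicted, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if not (len(predicted) == len(times) == len(events)):
        raise ValueError("predicted, times and events must be aligned")
    total_events = int(np.sum(events & (times <= h)))
    if total_events < min_events:
        raise ValueError(
            f"only {total_events} events by horizon {h}; need >= {min_events}")

    order = np.argsort(predicted, kind="stable")
    inv_groups = _initial_groups(predicted[order], init_groups)
    groups = [order[g] for g in inv_groups]  # contiguous in risk order

    def events_in(idx):
        return int(np.sum(events[idx] & (times[idx] <= h)))

    def mean_pred(idx):
        return float(np.mean(predicted[idx]))

    while len(groups) > 1:
        bad = [i for i, g in enumerate(groups) if events_in(g) < min_events]
        if not bad:
            break
        i = bad[0]  # lowest-risk violating group first
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            p = mean_pred(groups[i])
            j = i - 1 if abs(mean_pred(groups[i - 1]) - p) <= abs(
                mean_pred(groups[i + 1]) - p) else i + 1
        a, b = min(i, j), max(i, j)
        merged = np.concatenate([groups[a], groups[b]])
        groups = groups[:a] + [merged] + groups[b + 1:]

    return [_make_group(g, predicted, times, events, h) for g in groups]


def gnd_test(groups: list[RiskGroup], variance: str = "greenwood") -> GNDResult:
    """Greenwood-Nam-D'Agostino chi-square test over formed risk groups.

    ``variance`` selects the denominator: "greenwood" (default, the
    survival-adapted form) or "binomial" (p(1-p)/n on the KM-observed
    proportion).  Groups with zero variance are excluded with a warning;
    df = (contributing groups) - 1.
    """
    if len(groups) < 2:
        raise ValueError("gnd_test requires at least 2 groups")
    chi2 = 0.0
    used = 0
    for g in groups:
        if variance == "greenwood":
            var = g.greenwood_var
        elif variance == "binomial":
            var = g.km_observed * (1.0 - g.km_observed) / g.n
        else:
            raise ValueError(f"unknown variance flavour {variance!r}")
        if var <= 0:
            warnings.warn(
                f"excluding zero-variance group (n={g.n}, "
                f"mean predicted {g.mean_predicted:.4g}) from the GND statistic")
            continue
        chi2 += (g.km_observed - g.mean_predicted) ** 2 / var
        used += 1
    if used < 2:
        raise ValueError("fewer than 2 groups with positive variance")
    return GNDResult(chi2=float(chi2), groups=used)


def calibration_chart_data(groups: list[RiskGroup]) -> pd.DataFrame:
    """Per-group observed (KM-adjusted) and expected event counts, in risk
    order, for calibration plotting."""
    if not groups:
        raise ValueError("no groups supplied")
    return pd.DataFrame({
        "group": np.arange(1, len(groups) + 1),
        "n": [g.n for g in groups],
        "mean_predicted": [g.mean_predicted for g in groups],
        "km_observed_risk": [g.km_observed for g in groups],
        "observed_events": [g.n * g.km_observed for g in groups],
        "expected_events": [g.n * g.mean_predicted for g in groups],
    })
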
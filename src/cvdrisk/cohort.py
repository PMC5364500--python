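"""Cohort data model, CSV I/O, eligibility filtering and descriptive summaries.

A cohort is a pandas DataFrame with one row per subject:

==================  =========================================================
column              meaning / unit
==================  =========================================================
id                  unique subject identifier
sex                 "male" or "female"
age                 years
total_cholesterol   mmol/L
hdl                 mmol/L
glucose             mmol/L (fasting; descriptive only)
sbp                 mmHg
bmi                 kg/m2
bp_treated          0/1 currently on antihypertensive treatment
current_smoker      0/1
diabetes            0/1
followup_years      positive, time to event or censoring
cvd_death           0/1 death from cardiovascular cause during follow-up
all_cause_death     0/1 death from any cause during follow-up
==================  =========================================================

Optional columns: ``hypertension`` (derived from SBP >= 140 or treatment if
absent) and the eligibility flags ``lost_to_followup``, ``prior_cvd``,
``cancer``, ``ckd``, ``missing_model_inputs`` consumed by
:func:`eligibility_filter`.

Non-CVD deaths censor the CVD-mortality analyses at the death time (simple
Kaplan-Meier treatment, no competing-risks estimator).
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

MANDATORY_COLUMNS = [
    "id", "sex", "age", "total_cholesterol", "hdl", "sbp", "bmi",
    "bp_treated", "current_smoker", "diabetes",
    "followup_years", "cvd_death", "all_cause_death",
]

FLAG_COLUMNS = ["bp_treated", "current_smoker", "diabetes", "cvd_death",
                "all_cause_death"]

ELIGIBILITY_FLAGS = ["lost_to_followup", "prior_cvd", "cancer", "ckd",
                     "missing_model_inputs"]

CONTINUOUS_VARS = ["age", "total_cholesterol", "hdl", "glucose", "sbp", "bmi"]


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema."""


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (display convention for percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def validate_cohort(df: pd.DataFrame, require_outcomes: bool = True) -> pd.DataFrame:
    """Validate schema and invariants; returns the (typed) table.

    Invariants: unique ids, followup_years > 0, cvd_death implies
    all_cause_death, sex in {male, female}.  Violating rows are reported
    with their ids.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns
               and (require_outcomes or c not in ("followup_years", "cvd_death",
                                                  "all_cause_death"))]
    if missing:
        raise CohortValidationError(f"missing mandatory column(s): {missing}")
    df = df.copy()
    for c in FLAG_COLUMNS + ELIGIBILITY_FLAGS:
        if c in df.columns:
            df[c] = df[c].astype(float).fillna(0).astype(int)
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise CohortValidationError(
            f"invalid sex for id(s) {df.loc[bad_sex, 'id'].tolist()[:5]}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()[:5]
        raise CohortValidationError(f"duplicate id(s): {dups}")
    if require_outcomes:
        bad_fu = df["followup_years"] <= 0
        if bad_fu.any():
            raise CohortValidationError(
                f"non-positive followup_years for id(s) {df.loc[bad_fu, 'id'].tolist()[:5]}")
        implied = (df["cvd_death"] == 1) & (df["all_cause_death"] == 0)
        if implied.any():
            raise CohortValidationError(
                "cvd_death=1 with all_cause_death=0 for id(s) "
                f"{df.loc[implied, 'id'].tolist()[:5]}")
    return df


def read_cohort(path: str | Path, require_outcomes: bool = True) -> pd.DataFrame:
    """Read a cohort CSV (``#`` comment lines allowed for unit annotations).

    Rows failing type coercion are reported with their (1-based, post-header)
    line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    numeric = [c for c in df.columns if c not in ("id", "sex")]
    bad_lines = []
    for c in numeric:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        bad_lines.extend((df.index[bad] + 2).tolist())
        df[c] = coerced
    if bad_lines:
        raise CohortValidationError(
            f"{path}: unparsable numeric values at line(s) {sorted(set(bad_lines))[:10]}")
    return validate_cohort(df, require_outcomes=require_outcomes)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV with a unit-annotation comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# units: age years; total_cholesterol/hdl/glucose mmol/L; "
                 "sbp mmHg; bmi kg/m2; followup_years years\n")
        df.to_csv(fh, index=False)


def eligibility_filter(df: pd.DataFrame, age_range: tuple[float, float] = (40, 65)
                       ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the sequential cohort-flow exclusions and record a ledger.

    Order: age below range, age above range, lost to follow-up, prior
    disease (cancer / chronic kidney disease / CVD), missing model inputs.
    Flags absent from the table count as not-excluded.  The ledger satisfies
    ``initial - sum(exclusions) == final``.
    """
    ledger: dict[str, int] = {"initial": len(df)}
    keep = df

    steps = [
        ("age_below_range", keep["age"] < age_range[0] if "age" in keep else None),
        ("age_above_range", keep["age"] > age_range[1] if "age" in keep else None),
    ]
    for name, mask in steps:
        n0 = len(keep)
        keep = keep.loc[~mask] if mask is not None else keep
        ledger[name] = n0 - len(keep)

    def flag(col):
        if col in keep.columns:
            return keep[col].astype(float).fillna(0).astype(bool)
        return pd.Series(False, index=keep.index)

    n0 = len(keep)
    keep = keep.loc[~flag("lost_to_followup")]
    ledger["lost_to_followup"] = n0 - len(keep)

    n0 = len(keep)
    disease = flag("cancer") | flag("ckd") | flag("prior_cvd")
    keep = keep.loc[~disease]
    ledger["prior_disease"] = n0 - len(keep)

    n0 = len(keep)
    keep = keep.loc[~flag("missing_model_inputs")]
    ledger["missing_model_inputs"] = n0 - len(keep)

    ledger["final"] = len(keep)
    return keep.copy(), ledger


def _hypertension(df: pd.DataFrame) -> pd.Series:
    if "hypertension" in df.columns:
        return df["hypertension"].astype(float).fillna(0).astype(bool)
    return (df["sbp"] >= 140) | df["bp_treated"].astype(bool)


def summarize(df: pd.DataFrame) -> dict:
    """Table-1 style descriptive summary, overall and by sex.

    Continuous variables as mean +/- SD; categorical as count (percent);
    antihypertensive treatment as percent of treated among hypertensive.
    Percentages are rounded half-up to 2 decimals.
    """
    if len(df) == 0:
        raise CohortValidationError("cannot summarize an empty cohort")
    groups = {"overall": df,
              "male": df[df["sex"] == "male"],
              "female": df[df["sex"] == "female"]}
    out: dict = {"n": {}, "continuous": {}, "categorical": {},
                 "treated_among_hypertensive": {}}
    n_all = len(df)
    for name, g in groups.items():
        out["n"][name] = {"count": len(g),
                          "percent": round_half_up(100.0 * len(g) / n_all, 2)}
        cont = {}
        for v in CONTINUOUS_VARS:
            if v in g.columns and len(g):
                cont[v] = {"mean": float(g[v].mean()),
                           "sd": float(g[v].std(ddof=1)) if len(g) > 1 else 0.0}
        out["continuous"][name] = cont
        cat = {}
        for v in ["current_smoker", "diabetes"]:
            if v in g.columns:
                cnt = int(g[v].sum())
                cat[v] = {"count": cnt,
                          "percent": round_half_up(100.0 * cnt / len(g), 2) if len(g) else 0.0}
        hyper = _hypertension(g) if len(g) else pd.Series(dtype=bool)
        cat["hypertension"] = {"count": int(hyper.sum()),
                               "percent": round_half_up(100.0 * hyper.sum() / len(g), 2)
                               if len(g) else 0.0}
        out["categorical"][name] = cat
        n_hyper = int(hyper.sum())
        if n_hyper:
            treated = int(g.loc[hyper, "bp_treated"].sum())
            out["treated_among_hypertensive"][name] = {
                "count": treated,
                "percent": round_half_up(100.0 * treated / n_hyper, 2)}
        else:
            out["treated_among_hypertensive"][name] = {"count": 0, "percent": None}
    return out


def person_years(df: pd.DataFrame) -> dict[str, float]:
    """Total and by-sex person-years of follow-up."""
    return {
        "total": float(df["followup_years"].sum()),
        "male": float(df.loc[df["sex"] == "male", "followup_years"].sum()),
        "female": float(df.loc[df["sex"] == "female", "followup_years"].sum()),
    }


def crude_mortality(df: pd.DataFrame, outcome: str = "cvd") -> float:
    """Crude mortality, percent (1 decimal, round half-up): 100 * deaths / N."""
    if len(df) == 0:
        raise CohortValidationError("cannot compute mortality of an empty cohort")
    col = {"cvd": "cvd_death", "all_cause": "all_cause_death"}.get(outcome)
    if col is None:
        raise ValueError(f"outcome must be 'cvd' or 'all_cause', got {outcome!r}")
    return round_half_up(100.0 * df[col].sum() / len(df), 1)
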
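"""End-to-end validation pipeline and machine-readable report.

``run_pipeline`` executes: cohort acquisition (file or synthetic) ->
scoring under every model -> stratification -> discrimination ->
calibration (-> recalibration if requested) -> cross-model comparison, and
writes per-model metric tables, calibration chart data, a cohort summary
and a versioned JSON report.  All methodological choices (CI method,
variance flavour, df convention, category mapping, cut-off rule) are
recorded in the report metadata.  Reports contain no timestamps, so a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import calibration_chart_data, form_groups, gnd_test
from .cohort import (crude_mortality, person_years, read_cohort, summarize,
                     write_cohort)
from .compare import crosstab_agreement, extreme_misclassification, spearman_rho, stratify
from .discrimination import auc_ci, optimal_cutoff, sens_spec_at
from .engine import score_cohort_by_sex
from .recalibration import recalibrate
from .simulate import default_config_table1, generate_cohort
from .specs import builtin_recalibrated_specs, load_model_spec

REPORT_SCHEMA_VERSION = 1

DEFAULT_CONFIG = {
    "cohort": {"source": "synthetic", "n": 10338, "seed": 0},
    "models": "builtin",
    "horizon": 5.0,
    "observed_horizon": 6.0,
    "min_events": 2,
    "init_groups": 10,
    "diabetes_adjust": None,
    "recalibrate": None,  # None | "mean_only" | "full"
}


class PipelineError(RuntimeError):
    pass


def _load_models(models) -> dict[str, dict[str, object]]:
    """Group specs into {model_id: {"male": spec, "female": spec}}."""
    if models in (None, "builtin"):
        flat = builtin_recalibrated_specs().values()
    else:
        flat = [load_model_spec(p) for p in models]
    grouped: dict[str, dict] = {}
    for spec in flat:
        grouped.setdefault(spec.model_id, {})[spec.sex] = spec
    incomplete = [m for m, d in grouped.items() if set(d) != {"male", "female"}]
    if incomplete:
        raise PipelineError(f"models missing a sex-specific spec: {incomplete}")
    return grouped


def _get_cohort(cfg: dict) -> pd.DataFrame:
    src = cfg.get("source", "synthetic")
    if src == "synthetic":
        gen_cfg = default_config_table1(n=int(cfg.get("n", 10338)))
        return generate_cohort(gen_cfg, seed=int(cfg.get("seed", 0)))
    if src == "file":
        return read_cohort(cfg["path"])
    raise PipelineError(f"unknown cohort source {src!r}")


def _round_floats(obj, nd=6):
    if isinstance(obj, float):
        if np.isfinite(obj):
            return round(obj, nd)
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return _round_floats(obj.item(), nd)
    return obj


def _model_metrics(scores: pd.Series, cohort: pd.DataFrame, spec_pair, cfg
                   ) -> dict:
    h = float(cfg["horizon"])
    out = {}
    for sex in ("overall", "male", "female"):
        sub = cohort if sex == "overall" else cohort[cohort["sex"] == sex]
        s = scores.loc[sub.index].to_numpy()
        ev = sub["cvd_death"].to_numpy().astype(bool)
        entry: dict = {"n": int(len(sub)), "events": int(ev.sum())}
        if 0 < ev.sum() < len(sub):
            auc, lo, hi = auc_ci(s, ev)
            entry["auc"] = auc
            entry["auc_ci"] = [lo, hi]
            cut = optimal_cutoff(s, ev)
            entry["youden_cutoff"] = cut
            entry["at_youden_cutoff"] = sens_spec_at(s, ev, cut).to_dict()
            rec = spec_pair["male"].thresholds[-1] if spec_pair else None
            if rec is not None:
                entry["at_recommended_cutoff"] = sens_spec_at(s, ev, rec).to_dict()
            try:
                groups = form_groups(s, sub["followup_years"].to_numpy(),
                                     ev, h, init_groups=int(cfg["init_groups"]),
                                     min_events=int(cfg["min_events"]))
                gnd = gnd_test(groups)
                entry["calibration"] = {
                    "chi2": gnd.chi2, "groups": gnd.groups, "df": gnd.df,
                    "p_value": gnd.p_value,
                    "chart": calibration_chart_data(groups).to_dict("records"),
                }
            except ValueError as exc:
                entry["calibration"] = {"error": str(exc)}
        out[sex] = entry
    return out


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """Execute the full validation pipeline; returns (and optionally writes)
    the report dictionary."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out_path = Path(out_dir) if out_dir else None
    if out_path:
        out_path.mkdir(parents=True, exist_ok=True)

    cohort = _get_cohort(dict(cfg["cohort"]))
    models = _load_models(cfg["models"])

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": _round_floats({k: v for k, v in cfg.items()}),
        "metadata": {
            "auc_ci_method": "DeLong",
            "proportion_ci_method": "Clopper-Pearson",
            "calibration_variance": "greenwood",
            "calibration_df": "groups - 1",
            "population_cutoff_rule": "Youden J",
            "classification_rule": ">= cutoff",
            "four_to_three_mapping": "(<7.5 -> low; 7.5-19.9 -> intermediate; >=20 -> high)",
        },
    }

    report["cohort"] = {
        "summary": summarize(cohort),
        "person_years": person_years(cohort),
        "crude_cvd_mortality_pct": crude_mortality(cohort, "cvd"),
        "crude_all_cause_mortality_pct": crude_mortality(cohort, "all_cause"),
    }
    if out_path:
        write_cohort(cohort, out_path / "cohort.csv")
        (out_path / "cohort_summary.json").write_text(
            json.dumps(_round_floats(report["cohort"]), indent=1, sort_keys=True))

    if cfg.get("recalibrate"):
        recal = {}
        for model_id, pair in models.items():
            if pair["male"].family != "cox_form":
                recal[model_id] = pair  # SCORE family: multiplier only
                continue
            recal[model_id] = {
                sex: recalibrate(cohort[cohort["sex"] == sex], pair[sex],
                                 mode=cfg["recalibrate"], h=float(cfg["horizon"]))
                for sex in ("male", "female")
            }
        models = recal

    scores = {}
    cats = {}
    report["models"] = {}
    for model_id, pair in models.items():
        s = score_cohort_by_sex(cohort, pair["male"], pair["female"],
                                horizon=float(cfg["horizon"]),
                                diabetes_adjust=cfg["diabetes_adjust"],
                                rescale=True)
        scores[model_id] = s
        cats[model_id] = stratify(s.to_numpy(), pair["male"])
        dist = pd.Series(cats[model_id]).value_counts(sort=False)
        report["models"][model_id] = {
            "risk_category_counts": {str(k): int(v) for k, v in dist.items()},
            "metrics": _model_metrics(s, cohort, pair, cfg),
        }

    ids = sorted(scores)
    comparisons = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            table, agree = crosstab_agreement(cats[a], cats[b])
            comparisons[f"{a} vs {b}"] = {
                "percent_agreement": agree,
                "extreme_misclassification": extreme_misclassification(cats[a], cats[b]),
                "spearman_rho": spearman_rho(scores[a].to_numpy(), scores[b].to_numpy()),
                "crosstab": {str(r): {str(c): int(table.loc[r, c]) for c in table.columns}
                             for r in table.index},
            }
    report["comparisons"] = comparisons
    report = _round_floats(report)

    if out_path:
        (out_path / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n")
        rows = []
        for model_id, entry in report["models"].items():
            for sex, m in entry["metrics"].items():
                if "auc" not in m:
                    continue
                cal = m.get("calibration", {})
                rows.append({
                    "model": model_id, "stratum": sex, "n": m["n"],
                    "events": m["events"], "auc": m["auc"],
                    "auc_lo": m["auc_ci"][0], "auc_hi": m["auc_ci"][1],
                    "youden_cutoff": m["youden_cutoff"],
                    "sensitivity": m["at_youden_cutoff"]["sensitivity"],
                    "specificity": m["at_youden_cutoff"]["specificity"],
                    "lr_pos": m["at_youden_cutoff"]["lr_pos"],
                    "lr_neg": m["at_youden_cutoff"]["lr_neg"],
                    "cal_chi2": cal.get("chi2"), "cal_groups": cal.get("groups"),
                    "cal_p": cal.get("p_value"),
                })
        pd.DataFrame(rows).to_csv(out_path / "metrics.csv", index=False)
    return report
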
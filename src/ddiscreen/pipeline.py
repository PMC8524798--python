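"""One-shot analysis driver: screen -> prevalence -> tests -> models.

This is the library behind the ``analyze`` and ``report`` CLI subcommands.
It reproduces the analysis sequence of a longitudinal DDI prevalence study:
point-prevalence at the five assessment times (overall and stratified),
McNemar's test between admission and discharge (overall and per arm), the
chi-squared test for trend over the post-discharge assessments, per-patient
2-month change classification, and logistic models for three outcomes —
any baseline DDI, 2-month increase, 2-month decrease — each preceded by a
univariate screen at P < .15 and a collinearity report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .longitudinal import (
    PatientTimeline,
    classify_change,
    contributors,
    most_common_rules,
    prevalence_table,
    timelines_from_medications,
)
from .rulebase import RuleSet
from .stats import (
    PairedBinary2x2,
    TrendSeries,
    check_collinearity,
    chi2_trend_test,
    fit_multivariable,
    mcnemar_test,
    univariate_screen,
)

__all__ = ["AnalysisResult", "run_analysis", "write_analysis", "MODEL_COVARIATES"]

logger = logging.getLogger(__name__)

#: Baseline covariates offered to the risk-factor models.  drugs_per_day is
#: deliberately absent: hyperpolypharmacy is its threshold and the pair is
#: definitionally collinear (the collinearity report flags it when present).
MODEL_COVARIATES = [
    "age_group", "sex", "site",
    "dementia", "depression", "stroke", "hypertension", "atrial_fibrillation",
    "diabetes", "coronary_artery_disease", "heart_failure",
    "chronic_renal_failure", "chronic_hepatic_failure", "copd", "cancer",
    "bleeding", "thromboembolic_disease",
    "hyperpolypharmacy", "prior_hospitalization", "non_independent_living",
    "adl_score", "admission_type", "admission_reason",
]


@dataclass
class AnalysisResult:
    prevalence: pd.DataFrame
    mcnemar: dict
    trend: dict
    change: pd.DataFrame
    common_rules: pd.DataFrame
    models: dict = field(default_factory=dict)
    collinearity: pd.DataFrame | None = None


def _paired_counts(hits: pd.DataFrame, patients: list[str],
                   a: str = "t0", b: str = "t1") -> PairedBinary2x2:
    pos_a = set(hits.loc[hits["timepoint"] == a, "patient_id"])
    pos_b = set(hits.loc[hits["timepoint"] == b, "patient_id"])
    n11 = n10 = n01 = n00 = 0
    for p in patients:
        ia, ib = p in pos_a, p in pos_b
        n11 += ia and ib
        n10 += ia and not ib
        n01 += ib and not ia
        n00 += not ia and not ib
    return PairedBinary2x2(n11=n11, n10=n10, n01=n01, n00=n00)


def _trend_series(hits: pd.DataFrame, timelines: list[PatientTimeline],
                  patients: set[str] | None = None) -> TrendSeries:
    points = []
    for tp in ("t1", "t2", "t6", "t12"):
        pool = contributors(timelines, tp)
        if patients is not None:
            pool &= patients
        if not pool:
            continue
        pos = set(hits.loc[hits["timepoint"] == tp, "patient_id"]) & pool
        points.append((tp, len(pos), len(pool)))
    return TrendSeries(tuple(points))


def _fit_outcome(name: str, cov: pd.DataFrame, y: np.ndarray, seed: int,
                 c_ci: str | None = "bootstrap") -> dict:
    present = [c for c in MODEL_COVARIATES if c in cov.columns]
    X = cov[present]
    screen = univariate_screen(X, y)
    selected = screen.loc[screen["selected"], "variable"].tolist()
    out = {"outcome": name, "n": int(len(y)), "univariate": screen,
           "selected": selected, "multivariable": None, "summary": None}
    if not selected:
        logger.warning("%s: no covariate passed the univariate screen", name)
        return out
    try:
        res = fit_multivariable(X[selected], y, c_ci=c_ci, seed=seed)
    except Exception as exc:
        logger.warning("%s: multivariable fit failed: %s", name, exc)
        out["summary"] = {"error": str(exc)}
        return out
    out["multivariable"] = res.table
    out["summary"] = {
        "n": res.n, "aic": res.aic, "c_statistic": res.c_statistic,
        "c_ci": res.c_ci, "converged": res.converged,
    }
    return out


def run_analysis(
    hits: pd.DataFrame,
    meds: pd.DataFrame,
    covariates: pd.DataFrame,
    rules: RuleSet | None = None,
    seed: int = 0,
    c_ci: str | None = "bootstrap",
) -> AnalysisResult:
    """Run the full statistical sequence on screened hits."""
    timelines = timelines_from_medications(meds, covariates)
    eligible = {t.patient_id for t in timelines}
    hits = hits[hits["patient_id"].isin(eligible)]
    cov = covariates[covariates["patient_id"].isin(eligible)].reset_index(drop=True)

    prev = prevalence_table(hits, timelines, cov)

    # admission vs discharge, paired (all eligible patients have both)
    mcn: dict = {}
    all_ids = sorted(eligible)
    t = _paired_counts(hits, all_ids)
    stat, p = mcnemar_test(t)
    mcn["overall"] = {"n11": t.n11, "n10": t.n10, "n01": t.n01, "n00": t.n00,
                      "statistic": stat, "p": p}
    trend: dict = {}
    s = _trend_series(hits, timelines)
    stat, p = chi2_trend_test(s)
    trend["overall"] = {"points": list(s.points), "statistic": stat, "p": p}
    if "arm" in cov.columns:
        for arm, grp in cov.groupby("arm"):
            ids = sorted(set(grp["patient_id"]))
            t = _paired_counts(hits, ids)
            stat, p = mcnemar_test(t)
            mcn[str(arm)] = {"n11": t.n11, "n10": t.n10, "n01": t.n01,
                             "n00": t.n00, "statistic": stat, "p": p}
            s = _trend_series(hits, timelines, set(ids))
            stat, p = chi2_trend_test(s)
            trend[str(arm)] = {"points": list(s.points), "statistic": stat, "p": p}

    change_status = classify_change(hits, timelines)
    change = pd.DataFrame(
        [{"patient_id": c.patient_id, "increased": c.increased,
          "decreased": c.decreased} for c in change_status],
        columns=["patient_id", "increased", "decreased"],
    )

    common = most_common_rules(hits, "t0")

    models: dict = {}
    cov_idx = cov.set_index("patient_id")
    pos_t0 = set(hits.loc[hits["timepoint"] == "t0", "patient_id"])
    y_base = np.array([pid in pos_t0 for pid in cov["patient_id"]], dtype=float)
    models["baseline_ddi"] = _fit_outcome("baseline_ddi", cov, y_base, seed, c_ci)

    if not change.empty:
        cov_ch = cov_idx.loc[change["patient_id"]].reset_index()
        for outcome in ("increased", "decreased"):
            y = change[outcome].to_numpy(dtype=float)
            if len(np.unique(y)) < 2:
                logger.warning("%s: degenerate outcome; model skipped", outcome)
                continue
            models[outcome] = _fit_outcome(outcome, cov_ch, y, seed, c_ci)
    else:
        logger.warning("no patient contributes at both t0 and t2; "
                       "change analysis skipped")

    present = [c for c in MODEL_COVARIATES if c in cov.columns]
    extra = [c for c in ("drugs_per_day",) if c in cov.columns]
    coll = check_collinearity(cov[present + extra])

    return AnalysisResult(
        prevalence=prev, mcnemar=mcn, trend=trend, change=change,
        common_rules=common, models=models, collinearity=coll,
    )


def write_analysis(result: AnalysisResult, out_dir: str | Path) -> list[str]:
    """Write every analysis table to *out_dir*; returns the file names."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        written.append(name)

    def _json(obj, name: str) -> None:
        (out / name).write_text(json.dumps(obj, indent=2, default=float) + "\n")
        written.append(name)

    _csv(result.prevalence, "prevalence.csv")
    _csv(result.change, "change.csv")
    _csv(result.common_rules, "most_common_rules.csv")
    _json(result.mcnemar, "mcnemar.json")
    _json(result.trend, "trend.json")
    if result.collinearity is not None:
        _csv(result.collinearity, "collinearity.csv")
    (out / "models").mkdir(exist_ok=True)
    for name, model in result.models.items():
        _csv(model["univariate"], f"models/{name}_univariate.csv")
        if model["multivariable"] is not None:
            _csv(model["multivariable"], f"models/{name}_multivariable.csv")
            _json(model["summary"], f"models/{name}_summary.json")
    return written
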
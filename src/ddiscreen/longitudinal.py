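"""Longitudinal accounting: censoring, point-prevalence, and 2-month change.

Patients enter the analysis only if they have medication data both at
admission (t0) and discharge (t1).  After discharge, a patient with data at
some time t but none at the previous assessment t-1 is censored at t-1: the
first missing follow-up assessment ends the patient's contribution, and any
later snapshots are discarded.  Point-prevalence at a timepoint is the
fraction of still-contributing patients with at least one detected DDI,
overall or within a stratum (mechanism, harm category, trial arm, site, or
single rule).  Change between baseline and the 2-month assessment is
classified on rule-id sets: a rule present at follow-up but not at baseline
means the patient's DDIs increased; a rule present at baseline but absent at
follow-up means they decreased (both can hold at once).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detection import TIMEPOINTS, MedicationSnapshot
from .rulebase import HarmCategory, Mechanism, RuleSet

__all__ = [
    "IneligiblePatientError",
    "UndefinedEstimateError",
    "PatientTimeline",
    "PrevalenceEstimate",
    "ChangeStatus",
    "apply_censoring",
    "contributors",
    "point_prevalence",
    "prevalence_table",
    "most_common_rules",
    "classify_change",
    "timelines_from_medications",
]

logger = logging.getLogger(__name__)

_TP_ORDER = {t: i for i, t in enumerate(TIMEPOINTS)}
_FOLLOW_UP = TIMEPOINTS[2:]  # t2, t6, t12

STRATIFIERS = ("overall", "mechanism", "harm", "arm", "site", "rule")


class IneligiblePatientError(ValueError):
    """Patient lacks the admission or discharge snapshot required for entry."""


class UndefinedEstimateError(ValueError):
    """Prevalence requested at a timepoint with an empty denominator."""


@dataclass(frozen=True)
class PatientTimeline:
    """Covariates plus per-timepoint snapshots plus a censoring point."""

    patient_id: str
    snapshots: dict[str, MedicationSnapshot]
    covariates: dict = field(default_factory=dict)
    censor_at: str | None = None

    def __post_init__(self) -> None:
        for required in ("t0", "t1"):
            if required not in self.snapshots:
                raise IneligiblePatientError(
                    f"patient {self.patient_id}: missing {required} snapshot"
                )
        for tp in self.snapshots:
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r}")

    def contributes_at(self, timepoint: str) -> bool:
        if timepoint not in self.snapshots:
            return False
        if self.censor_at is not None and _TP_ORDER[timepoint] >= _TP_ORDER[self.censor_at]:
            return False
        return True


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Counts and proportion for one timepoint and stratum."""

    timepoint: str
    stratum_type: str
    stratum: str
    n_with: int
    n_total: int

    @property
    def proportion(self) -> float:
        return self.n_with / self.n_total

    def __post_init__(self) -> None:
        if not (0 <= self.n_with <= self.n_total):
            raise ValueError("need 0 <= n_with <= n_total")


@dataclass(frozen=True)
class ChangeStatus:
    patient_id: str
    increased: bool
    decreased: bool


def apply_censoring(timeline: PatientTimeline) -> PatientTimeline:
    """Set censor_at to the first follow-up assessment with no snapshot.

    Snapshots at or after the censoring point are dropped, implementing the
    rule that data at time t without data at t-1 do not count.
    """
    censor_at = None
    for tp in _FOLLOW_UP:
        if tp not in timeline.snapshots:
            censor_at = tp
            break
    if censor_at is None:
        return replace(timeline, censor_at=None)
    kept = {
        tp: snap
        for tp, snap in timeline.snapshots.items()
        if _TP_ORDER[tp] < _TP_ORDER[censor_at]
    }
    n_dropped = len(timeline.snapshots) - len(kept)
    if n_dropped:
        logger.info(
            "patient %s: censored at %s; %d later snapshot(s) discarded",
            timeline.patient_id, censor_at, n_dropped,
        )
    return replace(timeline, snapshots=kept, censor_at=censor_at)


def contributors(timelines: list[PatientTimeline], timepoint: str) -> set[str]:
    """Patients still contributing data at *timepoint* after censoring."""
    return {t.patient_id for t in timelines if t.contributes_at(timepoint)}


def _hits_at(hits: pd.DataFrame, timepoint: str) -> pd.DataFrame:
    return hits[hits["timepoint"] == timepoint]


def point_prevalence(
    hits: pd.DataFrame,
    timelines: list[PatientTimeline],
    timepoint: str,
    stratifier: str = "overall",
    covariates: pd.DataFrame | None = None,
) -> list[PrevalenceEstimate]:
    """Point-prevalence of >=1 qualifying DDI at one timepoint.

    The denominator is the number of non-censored patients at the timepoint
    (within the stratum, for arm/site strata).  For the mechanism stratifier,
    rules with mechanism 'both' count in both the pharmacokinetic and the
    pharmacodynamic stratum.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}; allowed: {STRATIFIERS}")
    pool = contributors(timelines, timepoint)
    if not pool:
        raise UndefinedEstimateError(f"no patients contribute at {timepoint}")
    h = _hits_at(hits, timepoint)
    h = h[h["patient_id"].isin(pool)]

    if stratifier == "overall":
        return [
            PrevalenceEstimate(
                timepoint, "overall", "overall",
                h["patient_id"].nunique(), len(pool),
            )
        ]
    if stratifier == "mechanism":
        out = []
        for label, accepted in (
            ("pharmacokinetic", {Mechanism.PHARMACOKINETIC.value, Mechanism.BOTH.value}),
            ("pharmacodynamic", {Mechanism.PHARMACODYNAMIC.value, Mechanism.BOTH.value}),
        ):
            sub = h[h["mechanism"].isin(accepted)]
            out.append(
                PrevalenceEstimate(timepoint, "mechanism", label,
                                   sub["patient_id"].nunique(), len(pool))
            )
        return out
    if stratifier == "harm":
        return [
            PrevalenceEstimate(
                timepoint, "harm", cat.value,
                h.loc[h["harm"] == cat.value, "patient_id"].nunique(), len(pool),
            )
            for cat in HarmCategory
        ]
    if stratifier == "rule":
        return [
            PrevalenceEstimate(
                timepoint, "rule", str(rid),
                grp["patient_id"].nunique(), len(pool),
            )
            for rid, grp in h.groupby("rule_id")
        ]
    # arm / site: stratum membership comes from the covariate table
    if covariates is None or stratifier not in covariates.columns:
        raise ValueError(f"stratifier {stratifier!r} needs a covariate table "
                         f"with a {stratifier!r} column")
    cov = covariates.set_index("patient_id") if "patient_id" in covariates.columns else covariates
    out = []
    for level in sorted(cov[stratifier].astype(str).unique()):
        members = set(cov.index[cov[stratifier].astype(str) == level]) & pool
        if not members:
            continue
        n_with = h.loc[h["patient_id"].isin(members), "patient_id"].nunique()
        out.append(PrevalenceEstimate(timepoint, stratifier, level, n_with, len(members)))
    return out


def prevalence_table(
    hits: pd.DataFrame,
    timelines: list[PatientTimeline],
    covariates: pd.DataFrame | None = None,
    stratifiers: tuple[str, ...] = STRATIFIERS,
) -> pd.DataFrame:
    """All-timepoint, all-stratifier prevalence in the output CSV schema."""
    rows = []
    for tp in TIMEPOINTS:
        if not contributors(timelines, tp):
            continue
        for strat in stratifiers:
            if strat in ("arm", "site") and (
                covariates is None
                or strat not in getattr(covariates, "columns", [])
            ):
                continue
            for est in point_prevalence(hits, timelines, tp, strat, covariates):
                rows.append(
                    {
                        "timepoint": est.timepoint,
                        "stratum_type": est.stratum_type,
                        "stratum": est.stratum,
                        "n_with": est.n_with,
                        "n_total": est.n_total,
                        "proportion": est.proportion,
                    }
                )
    return pd.DataFrame(rows)


def most_common_rules(
    hits: pd.DataFrame, timepoint: str | None = None
) -> pd.DataFrame:
    """Rank rules by patient-level frequency; flag the most common ones.

    The most common rules are those whose frequency reaches the 3rd quartile
    of the per-rule frequency distribution; ties at the threshold are kept
    together.  Returns a DataFrame (rule_id, n_patients, selected) sorted by
    descending frequency.
    """
    h = hits if timepoint is None else _hits_at(hits, timepoint)
    if h.empty:
        return pd.DataFrame(columns=["rule_id", "n_patients", "selected"])
    freq = (
        h.groupby("rule_id")["patient_id"]
        .nunique()
        .sort_values(ascending=False)
        .rename("n_patients")
        .reset_index()
    )
    threshold = float(np.quantile(freq["n_patients"], 0.75))
    freq["selected"] = freq["n_patients"] >= threshold
    return freq


def classify_change(
    hits: pd.DataFrame,
    timelines: list[PatientTimeline],
    baseline: str = "t0",
    follow: str = "t2",
) -> list[ChangeStatus]:
    """Per-patient DDI increase/decrease between two assessments.

    Computed on rule-id sets: increased iff a rule fires at *follow* that did
    not at *baseline*; decreased iff a baseline rule no longer fires.  Only
    patients contributing at both timepoints are classified; censored
    patients are excluded (logged, not an error).
    """
    eligible = [
        t for t in timelines
        if t.contributes_at(baseline) and t.contributes_at(follow)
    ]
    n_excluded = len(timelines) - len(eligible)
    if n_excluded:
        logger.info(
            "change %s->%s: %d patient(s) excluded (censored before %s)",
            baseline, follow, n_excluded, follow,
        )
    base_sets = (
        _hits_at(hits, baseline).groupby("patient_id")["rule_id"].agg(set).to_dict()
    )
    follow_sets = (
        _hits_at(hits, follow).groupby("patient_id")["rule_id"].agg(set).to_dict()
    )
    out = []
    for t in eligible:
        b = base_sets.get(t.patient_id, set())
        f = follow_sets.get(t.patient_id, set())
        out.append(
            ChangeStatus(
                patient_id=t.patient_id,
                increased=bool(f - b),
                decreased=bool(b - f),
            )
        )
    return out


def timelines_from_medications(
    meds: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    censor: bool = True,
) -> list[PatientTimeline]:
    """Build censored patient timelines from a long medication table.

    A patient's snapshot at a timepoint exists iff the table has at least one
    row for that (patient, timepoint).  Patients without both t0 and t1 are
    dropped with a logged warning (sub-study eligibility).
    """
    cov_map: dict[str, dict] = {}
    if covariates is not None:
        cov = covariates.set_index("patient_id") if "patient_id" in covariates.columns else covariates
        cov_map = cov.to_dict(orient="index")
    timelines = []
    for pid, grp in meds.groupby("patient_id", sort=True):
        snaps = {}
        for tp, sub in grp.groupby("timepoint"):
            snaps[tp] = MedicationSnapshot(
                patient_id=str(pid), timepoint=tp,
                codes=frozenset(sub["atc_code"].astype(str)),
            )
        try:
            t = PatientTimeline(
                patient_id=str(pid), snapshots=snaps,
                covariates=cov_map.get(pid, cov_map.get(str(pid), {})),
            )
        except IneligiblePatientError as exc:
            logger.warning("%s; patient dropped", exc)
            continue
        timelines.append(apply_censoring(t) if censor else t)
    return timelines
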
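"""Synthetic cohort generator with known ground truth.

Emulates a multicentre hospital cohort of older adults (>=70 years, >=3
chronic conditions, >=5 chronic drugs, median ~12 drugs/day) observed at
admission (t0), discharge (t1) and 2/6/12-month telephone follow-up, with
hospitalization-driven medication churn and dropout.  Medication lists are
assembled from two independent parts: *witness* ATC codes that realize the
interaction rules a patient is meant to trigger, and *filler* codes drawn
from a pool verified to match no rule group, so the drug-count distribution
and the DDI prevalence can be controlled independently.

Whether a patient has any DDI at baseline is drawn from a logistic model on
the patient's covariates with configurable log-odds-ratios, so that the
inferential pipeline can be checked for parameter recovery.  Which rules a
positive patient triggers is drawn from a weight table whose default mass is
concentrated on the five interaction rules that dominate such cohorts
(potassium-reducing duplications, centrally-acting polytherapy,
potassium-sparing duplications, anticoagulant+antiplatelet, NSAID+SSRI).

The generator's truth table is produced by running the detection engine on
the emitted codes at build time; a self-check asserts that every intended
rule is detected and that no DDI-negative patient triggers anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator
from scipy.optimize import brentq
from scipy.special import expit, logit

from .detection import TIMEPOINTS, screen_cohort
from .longitudinal import PatientTimeline, timelines_from_medications
from .rulebase import DDIRule, RuleSet, load_default_rules

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "FILLER_POOL",
    "generate_cohort",
    "inject_rule_instance",
    "summarize_truth",
    "witness_codes",
]

#: ATC codes verified (by test and by a generator self-check) to belong to no
#: drug group of any packaged rule: common chronic-disease drugs that are
#: inert with respect to the consensus interaction list.
FILLER_POOL = (
    "A02BC02",  # pantoprazole
    "A02BC03",  # lansoprazole
    "A06AD11",  # lactulose
    "A07DA03",  # loperamide
    "A07EC02",  # mesalazine
    "A10BA02",  # metformin
    "A10BH01",  # sitagliptin
    "A11CC05",  # colecalciferol
    "A11DA01",  # thiamine
    "B03BA01",  # cyanocobalamin
    "B03BB01",  # folic acid
    "C10AX09",  # ezetimibe
    "G04CA02",  # tamsulosin
    "N02BE01",  # paracetamol
    "N02BB02",  # metamizole
    "N07CA01",  # betahistine
    "R03BB04",  # tiotropium
    "R06AE07",  # cetirizine
    "S01ED01",  # timolol (ophthalmic)
)

#: Curated witness codes for the rules the generator injects by default.
#: Chosen to realize each rule with as little leakage into *other* rules as
#: the ATC groups allow (e.g. the potassium-reducing pair uses an inhaled
#: beta2 agonist plus a contact laxative rather than two diuretics, which
#: would also satisfy the diuretic side of several pairwise rules).  Residual
#: cross-rule hits from co-injected rules are legitimate and are captured by
#: the engine-derived truth table.
DEFAULT_WITNESSES: dict[int, list[str]] = {
    6: ["C01AA05", "C03CA01"],    # digoxin + furosemide
    11: ["B01AA03", "M01AE01"],   # warfarin + ibuprofen
    12: ["B01AA03", "B01AC06"],   # warfarin + aspirin
    14: ["B01AF01", "N06AB06"],   # rivaroxaban + sertraline
    20: ["B01AC06", "M01AE01"],   # aspirin + ibuprofen
    21: ["C09AA02", "C03DA01"],   # enalapril + spironolactone
    23: ["C09AA02", "M01AE01"],   # enalapril + ibuprofen
    25: ["C03CA01", "M01AE01"],   # furosemide + ibuprofen
    36: ["N05BA01", "N05CF01", "N06AA09"],  # diazepam + zopiclone + amitriptyline
    37: ["N02AA01", "N05BA01"],   # morphine + diazepam
    38: ["N06AB06", "N02AX02"],   # sertraline + tramadol
    39: ["M01AE01", "N06AB06"],   # ibuprofen + sertraline
    40: ["N05AA01", "N05AH04"],   # chlorpromazine + quetiapine
    65: ["R03AC02", "A06AB06"],   # salbutamol + sennosides
    66: ["N06AB06", "C03CA01"],   # sertraline + furosemide
}

SITES = ("Louvain", "Cork", "Utrecht", "Bern")
ARMS = ("intervention", "control")

COMORBIDITY_FLAGS = (
    "dementia", "depression", "stroke", "hypertension", "atrial_fibrillation",
    "diabetes", "coronary_artery_disease", "heart_failure",
    "chronic_renal_failure", "chronic_hepatic_failure", "copd", "cancer",
    "bleeding", "thromboembolic_disease",
)


class ConfigError(ValueError):
    pass


class SimulationConfig(BaseModel):
    """All knobs of the cohort simulator; the seed is mandatory."""

    n_patients: int = Field(ge=0)
    seed: int

    site_probs: dict[str, float] = {
        "Louvain": 0.20, "Cork": 0.17, "Utrecht": 0.22, "Bern": 0.41,
    }
    arm_probs: dict[str, float] = {"intervention": 0.5, "control": 0.5}

    # age = 70 + Gamma(shape, scale); defaults target median 79, IQR 74-84
    age_gamma_shape: float = 2.0
    age_gamma_scale: float = 4.8

    comorbidity_prevalence: dict[str, float] = {
        "dementia": 0.06, "depression": 0.09, "stroke": 0.21,
        "hypertension": 0.66, "atrial_fibrillation": 0.36, "diabetes": 0.32,
        "coronary_artery_disease": 0.34, "heart_failure": 0.26,
        "chronic_renal_failure": 0.27, "chronic_hepatic_failure": 0.05,
        "copd": 0.19, "cancer": 0.25, "bleeding": 0.13,
        "thromboembolic_disease": 0.12,
    }
    min_comorbidities: int = 3
    prior_hospitalization_prob: float = 0.51
    non_independent_living_prob: float = 0.19
    elective_admission_prob: float = 0.24
    surgical_admission_prob: float = 0.13

    # drugs/day ~ round(LogNormal(ln(median), sigma)), floor at min_drugs
    drugs_median: float = 12.0
    drugs_sigma: float = 0.33
    min_drugs: int = 5

    # baseline >=1-DDI status: logistic on covariates, intercept calibrated
    # so that the mean probability equals baseline_ddi_prevalence
    baseline_ddi_prevalence: float = 0.54
    baseline_coefs: dict[str, float] = {
        "age_80_89": -0.236, "age_90_plus": -0.431, "male": -0.211,
        "depression": 1.058, "coronary_artery_disease": 0.223,
        "heart_failure": 0.470, "atrial_fibrillation": 0.438,
        "chronic_renal_failure": 0.086, "chronic_hepatic_failure": -0.713,
        "copd": 0.647, "prior_hospitalization": 0.157,
        "hyperpolypharmacy": 0.793, "non_independent_living": 0.231,
        "admission_medical": 0.086,
    }

    # how many rules a baseline-positive patient triggers (1-based probs)
    n_rules_probs: list[float] = [0.60, 0.25, 0.10, 0.05]
    rule_weights: dict[int, float] = {
        65: 0.33, 36: 0.24, 21: 0.13, 12: 0.10, 39: 0.08,
        6: 0.015, 11: 0.015, 14: 0.015, 20: 0.01, 23: 0.02,
        25: 0.015, 37: 0.015, 38: 0.015, 40: 0.01, 66: 0.01,
    }

    # discharge churn: in-hospital accumulation of interacting prescriptions
    # is arm-specific; the medication-review arm's additions are balanced by
    # deprescribing so its net discharge change is approximately null
    discharge_add_prob: dict[str, float] = {"control": 0.16, "intervention": 0.03}
    discharge_drop_prob: float = 0.04

    # post-discharge churn; the 2-month step carries covariate effects
    t2_add_prob: float = 0.225
    t2_drop_prob: float = 0.37
    late_add_prob: float = 0.06
    late_drop_prob: float = 0.08
    increase_coefs: dict[str, float] = {
        "hyperpolypharmacy": 0.554, "atrial_fibrillation": 0.698,
        "heart_failure": 0.582, "coronary_artery_disease": 0.255,
    }
    decrease_coefs: dict[str, float] = {
        "hyperpolypharmacy": 0.703, "depression": 0.525,
        "heart_failure": 0.315, "male": -0.274,
    }

    # probability that a follow-up snapshot is missing (censoring downstream)
    dropout_probs: dict[str, float] = {"t2": 0.115, "t6": 0.06, "t12": 0.05}

    follow_up: bool = True  # False: emit t0/t1 only (baseline analyses)

    @field_validator("site_probs", "arm_probs", "comorbidity_prevalence",
                     "discharge_add_prob", "dropout_probs")
    @classmethod
    def _probs_in_unit(cls, v):
        for k, p in v.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {k}={p} outside [0,1]")
        return v

    def validated(self, rules: RuleSet) -> "SimulationConfig":
        for rid in self.rule_weights:
            try:
                rules.by_id(rid)
            except KeyError:
                raise ConfigError(f"rule_weights references unknown rule id {rid}")
        max_witness = max(
            _n_witnesses(rules.by_id(rid)) for rid in self.rule_weights
        )
        budget = max_witness * len(self.n_rules_probs)
        if budget > self.min_drugs + len(FILLER_POOL):
            raise ConfigError(
                f"rule witness budget ({budget}) exceeds the drug budget"
            )
        return self


def _n_witnesses(rule: DDIRule) -> int:
    return 2 if rule.kind == "pairwise" else rule.min_count


def _complete_prefix(prefix: str, variant: int) -> str:
    """Extend an ATC prefix to a full valid 7-character code."""
    dd = f"{(variant % 9) + 1:02d}"
    n = len(prefix)
    if n == 7:
        return prefix
    if n == 5:
        return prefix + dd
    if n == 4:
        return prefix + "A" + dd
    if n == 3:
        return prefix + "AA" + dd
    return prefix + "01AA" + dd


def witness_codes(rule: DDIRule, variant: int = 0) -> list[str]:
    """Minimal distinct ATC codes that make *rule* fire.

    For pairwise rules one code per group; for cardinality rules
    ``min_count`` codes from the group (cycling over the include prefixes).
    """
    out: list[str] = []
    if rule.kind == "pairwise":
        for group in rule.groups:
            prefixes = sorted(group.include)
            for attempt in range(12):
                code = _complete_prefix(
                    prefixes[(variant + attempt) % len(prefixes)],
                    variant + attempt,
                )
                if group.contains(code) and code not in out:
                    out.append(code)
                    break
            else:  # pragma: no cover - packaged groups always complete
                raise RuntimeError(f"cannot build witness for {group.name}")
    else:
        (group,) = rule.groups
        prefixes = sorted(group.include)
        attempt = 0
        while len(out) < rule.min_count and attempt < 12 * rule.min_count:
            p = prefixes[(variant + attempt) % len(prefixes)]
            code = _complete_prefix(p, variant + attempt // len(prefixes))
            if group.contains(code) and code not in out:
                out.append(code)
            attempt += 1
        if len(out) < rule.min_count:  # pragma: no cover
            raise RuntimeError(f"cannot build witnesses for rule {rule.rule_id}")
    return out


def inject_rule_instance(
    timeline: PatientTimeline, rule: DDIRule, timepoint: str, variant: int = 0
) -> PatientTimeline:
    """Return a copy of *timeline* with witness codes for *rule* added."""
    from dataclasses import replace

    from .detection import MedicationSnapshot, evaluate_rule

    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    snaps = dict(timeline.snapshots)
    old = snaps.get(timepoint)
    codes = set(old.codes) if old else set()
    codes.update(witness_codes(rule, variant))
    snap = MedicationSnapshot(timeline.patient_id, timepoint, frozenset(codes))
    if evaluate_rule(snap, rule) is None:  # pragma: no cover - self-check
        raise RuntimeError(f"injection self-check failed for rule {rule.rule_id}")
    snaps[timepoint] = snap
    return replace(timeline, snapshots=snaps)


@dataclass
class SimulatedCohort:
    """Generated cohort: emitted tables plus the generator's ground truth."""

    medications: pd.DataFrame   # patient_id, timepoint, atc_code
    covariates: pd.DataFrame    # one row per patient
    truth: pd.DataFrame         # patient_id, timepoint, rule_id, intended
    config: SimulationConfig

    def timelines(self) -> list[PatientTimeline]:
        return timelines_from_medications(self.medications, self.covariates)


def _calibrate_offset(eta: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(eta + c)) == target."""
    if len(eta) == 0:
        return logit(target)
    return float(brentq(lambda c: expit(eta + c).mean() - target, -25, 25))


def _design_vector(cov: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    """Linear predictor for the generator's internal logistic models."""
    eta = np.zeros(len(cov))
    for key, beta in coefs.items():
        if key == "age_80_89":
            x = ((cov["age"] >= 80) & (cov["age"] <= 89)).astype(float)
        elif key == "age_90_plus":
            x = (cov["age"] >= 90).astype(float)
        elif key == "male":
            x = (cov["sex"] == "male").astype(float)
        elif key == "admission_medical":
            x = (cov["admission_reason"] == "medical").astype(float)
        elif key in cov.columns:
            x = cov[key].astype(float)
        else:
            raise ConfigError(f"coefficient references unknown covariate {key!r}")
        eta += beta * np.asarray(x)
    return eta


def _sample_covariates(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    width = max(4, len(str(max(n, 1))))
    pid = [f"P{i:0{width}d}" for i in range(1, n + 1)]
    site = rng.choice(list(cfg.site_probs), p=_norm(cfg.site_probs), size=n)
    arm = rng.choice(list(cfg.arm_probs), p=_norm(cfg.arm_probs), size=n)
    age = 70 + np.floor(rng.gamma(cfg.age_gamma_shape, cfg.age_gamma_scale, size=n)).astype(int)
    sex = np.where(rng.random(n) < 0.55, "male", "female")

    flags = {
        f: rng.random(n) < p for f, p in cfg.comorbidity_prevalence.items()
    }
    flag_mat = np.column_stack([flags[f] for f in COMORBIDITY_FLAGS]) if n else np.zeros((0, len(COMORBIDITY_FLAGS)), bool)
    # enforce eligibility (>=3 chronic conditions) by topping up short rows
    order = list(COMORBIDITY_FLAGS)
    probs = np.array([cfg.comorbidity_prevalence[f] for f in order])
    for i in np.nonzero(flag_mat.sum(axis=1) < cfg.min_comorbidities)[0]:
        need = cfg.min_comorbidities - int(flag_mat[i].sum())
        off = np.nonzero(~flag_mat[i])[0]
        pick = rng.choice(off, size=need, replace=False,
                          p=probs[off] / probs[off].sum())
        flag_mat[i, pick] = True

    drugs = np.maximum(
        cfg.min_drugs,
        np.round(rng.lognormal(np.log(cfg.drugs_median), cfg.drugs_sigma, size=n)).astype(int),
    )
    adl = np.clip(np.round(rng.normal(5.2, 1.0, size=n) * 2) / 2, 0.0, 6.0)

    cov = pd.DataFrame({"patient_id": pid, "site": site, "arm": arm,
                        "age": age, "sex": sex})
    for j, f in enumerate(order):
        cov[f] = flag_mat[:, j] if n else np.array([], dtype=bool)
    cov["n_comorbidities"] = flag_mat.sum(axis=1) if n else np.array([], dtype=int)
    cov["drugs_per_day"] = drugs
    cov["hyperpolypharmacy"] = drugs >= 10
    cov["prior_hospitalization"] = rng.random(n) < cfg.prior_hospitalization_prob
    cov["non_independent_living"] = rng.random(n) < cfg.non_independent_living_prob
    cov["adl_score"] = adl
    cov["admission_type"] = np.where(
        rng.random(n) < cfg.elective_admission_prob, "elective", "non-elective")
    cov["admission_reason"] = np.where(
        rng.random(n) < cfg.surgical_admission_prob, "surgical", "medical")
    cov["age_group"] = pd.cut(
        cov["age"], bins=[69, 79, 89, 200], labels=["70-79", "80-89", ">=90"]
    ).astype(str)
    return cov


def _norm(d: dict[str, float]) -> np.ndarray:
    v = np.array(list(d.values()), dtype=float)
    if v.sum() <= 0:
        raise ConfigError("probabilities sum to zero")
    return v / v.sum()


def generate_cohort(cfg: SimulationConfig, rules: RuleSet | None = None) -> SimulatedCohort:
    """Generate a reproducible cohort with per-patient rule ground truth."""
    rules = rules if rules is not None else load_default_rules()
    cfg = cfg.validated(rules)
    rng = np.random.default_rng(cfg.seed)
    cov = _sample_covariates(cfg, rng)
    n = cfg.n_patients

    empty_meds = pd.DataFrame(columns=["patient_id", "timepoint", "atc_code"])
    empty_truth = pd.DataFrame(columns=["patient_id", "timepoint", "rule_id", "intended"])
    if n == 0:
        return SimulatedCohort(empty_meds, cov, empty_truth, cfg)

    # baseline >=1-DDI status from the covariate logistic model
    eta = _design_vector(cov, cfg.baseline_coefs)
    eta += _calibrate_offset(eta, cfg.baseline_ddi_prevalence)
    y0 = rng.random(n) < expit(eta)

    rule_ids = np.array(list(cfg.rule_weights), dtype=int)
    rule_p = _norm(cfg.rule_weights)
    kprobs = np.array(cfg.n_rules_probs) / np.sum(cfg.n_rules_probs)

    # 2-month churn probabilities, covariate-modulated, mean-calibrated
    eta_inc = _design_vector(cov, cfg.increase_coefs)
    eta_inc += _calibrate_offset(eta_inc, cfg.t2_add_prob)
    p_inc = expit(eta_inc)
    eta_dec = _design_vector(cov, cfg.decrease_coefs)
    eta_dec += _calibrate_offset(eta_dec, cfg.t2_drop_prob)
    p_dec = expit(eta_dec)

    followups = ["t2", "t6", "t12"] if cfg.follow_up else []
    observed = {
        tp: rng.random(n) >= cfg.dropout_probs.get(tp, 0.0) for tp in followups
    }

    med_rows: list[tuple[str, str, str]] = []
    intended_rows: list[tuple[str, str, int]] = []

    # witness codes per injectable rule: curated low-leakage sets where they
    # apply to this rule set (verified), generic completions otherwise
    from .detection import MedicationSnapshot, evaluate_rule

    witness_map: dict[int, list[str]] = {}
    for rid in map(int, rule_ids):
        rule = rules.by_id(rid)
        cand = DEFAULT_WITNESSES.get(rid)
        if cand is not None and evaluate_rule(
            MedicationSnapshot("_", "t0", frozenset(cand)), rule
        ) is not None:
            witness_map[rid] = list(cand)
        else:
            witness_map[rid] = witness_codes(rule, variant=0)

    def sample_new_rule(active: dict[int, list[str]]) -> int | None:
        avail = [i for i, rid in enumerate(rule_ids) if int(rid) not in active]
        if not avail:
            return None
        w = rule_p[avail] / rule_p[avail].sum()
        return int(rule_ids[rng.choice(avail, p=w)])

    for i in range(n):
        pid = cov.at[i, "patient_id"]
        arm = cov.at[i, "arm"]
        # active: rule_id -> witness codes currently prescribed
        active: dict[int, list[str]] = {}
        if y0[i]:
            k = 1 + rng.choice(len(kprobs), p=kprobs)
            chosen = rng.choice(len(rule_ids), size=min(k, len(rule_ids)),
                                replace=False, p=rule_p)
            for j in chosen:
                rid = int(rule_ids[j])
                active[rid] = witness_map[rid]

        n_target = int(cov.at[i, "drugs_per_day"])
        witness_set = sorted({c for cs in active.values() for c in cs})
        n_fill = min(len(FILLER_POOL), max(0, n_target - len(witness_set)))
        fillers = list(rng.choice(FILLER_POOL, size=n_fill, replace=False))

        def emit(tp: str) -> None:
            codes = sorted({c for cs in active.values() for c in cs} | set(fillers))
            for c in codes:
                med_rows.append((pid, tp, c))
            for rid in active:
                intended_rows.append((pid, tp, rid))

        emit("t0")

        # discharge churn: structured medication review (intervention arm)
        # suppresses the in-hospital accumulation of interacting prescriptions
        if rng.random() < cfg.discharge_add_prob[arm]:
            rid = sample_new_rule(active)
            if rid is not None:
                active[rid] = witness_map[rid]
        if active and rng.random() < cfg.discharge_drop_prob:
            drop = int(rng.choice(sorted(active)))
            del active[drop]
        emit("t1")

        for tp in followups:
            add_p = p_inc[i] if tp == "t2" else cfg.late_add_prob
            drop_p = p_dec[i] if tp == "t2" else cfg.late_drop_prob
            if active and rng.random() < drop_p:
                drop = int(rng.choice(sorted(active)))
                del active[drop]
            if rng.random() < add_p:
                rid = sample_new_rule(active)
                if rid is not None:
                    active[rid] = witness_map[rid]
            if observed[tp][i]:
                emit(tp)

    meds = pd.DataFrame(med_rows, columns=["patient_id", "timepoint", "atc_code"])
    intended = pd.DataFrame(intended_rows, columns=["patient_id", "timepoint", "rule_id"])

    detected = screen_cohort(meds, rules)
    truth = detected[["patient_id", "timepoint", "rule_id"]].copy()
    truth = truth.merge(
        intended.assign(intended=True), how="left",
        on=["patient_id", "timepoint", "rule_id"],
    )
    truth["intended"] = truth["intended"].eq(True)

    _self_check(meds, intended, detected, cov, y0)
    return SimulatedCohort(meds, cov, truth, cfg)


def _self_check(meds, intended, detected, cov, y0) -> None:
    """Generator invariants: intended rules detected; negatives clean."""
    det_keys = set(map(tuple, detected[["patient_id", "timepoint", "rule_id"]].itertuples(index=False)))
    int_keys = set(map(tuple, intended.itertuples(index=False)))
    missing = int_keys - det_keys
    if missing:  # pragma: no cover
        raise RuntimeError(f"self-check: intended rules not detected: {sorted(missing)[:5]}")
    pos_at_t0 = set(detected.loc[detected["timepoint"] == "t0", "patient_id"])
    should_be_pos = set(cov.loc[np.asarray(y0), "patient_id"])
    if pos_at_t0 != should_be_pos:  # pragma: no cover
        raise RuntimeError("self-check: baseline DDI status mismatch")


def summarize_truth(cohort: SimulatedCohort) -> pd.DataFrame:
    """Per-timepoint intended prevalence and per-rule frequencies.

    One row per (timepoint, rule_id) with the number of patients intended to
    trigger the rule, plus one 'any' row per timepoint with the intended
    >=1-DDI prevalence among emitted snapshots.
    """
    if cohort.truth.empty:
        return pd.DataFrame(columns=["timepoint", "rule_id", "n_patients", "prevalence"])
    denom = (
        cohort.medications.groupby("timepoint")["patient_id"].nunique().to_dict()
    )
    rows = []
    for tp, grp in cohort.truth.groupby("timepoint"):
        rows.append({"timepoint": tp, "rule_id": "any",
                     "n_patients": grp["patient_id"].nunique(),
                     "prevalence": grp["patient_id"].nunique() / denom[tp]})
        for rid, sub in grp.groupby("rule_id"):
            rows.append({"timepoint": tp, "rule_id": str(rid),
                         "n_patients": sub["patient_id"].nunique(),
                         "prevalence": sub["patient_id"].nunique() / denom[tp]})
    out = pd.DataFrame(rows)
    tp_order = {t: i for i, t in enumerate(TIMEPOINTS)}
    return out.sort_values(
        ["timepoint", "rule_id"],
        key=lambda s: s.map(tp_order) if s.name == "timepoint" else s,
        kind="mergesort",
    ).reset_index(drop=True)
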
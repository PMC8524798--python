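"""Screening of medication snapshots against the DDI rule set.

A snapshot is the set of ATC codes a patient is taking at one assessment
time.  A pairwise rule fires when the snapshot contains two *distinct* codes,
one from each drug group; a cardinality rule fires when it contains at least
``min_count`` distinct codes from its group.  Multiplicity is counted at rule
level: however many drug combinations satisfy a rule within one snapshot, it
yields a single hit, and all matching codes are retained as the hit's
triggering codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atc import ATCFormatError, canonical_atc
from .rulebase import DDIRule, DrugGroup, HarmCategory, Mechanism, RuleSet

__all__ = [
    "TIMEPOINTS",
    "MedicationSnapshot",
    "DDIHit",
    "evaluate_rule",
    "screen_snapshot",
    "screen_cohort",
    "hits_to_frame",
]

logger = logging.getLogger(__name__)

# Assessment times: hospital admission (t0), discharge (t1), then telephone
# follow-up at 2, 6 and 12 months after baseline.
TIMEPOINTS = ("t0", "t1", "t2", "t6", "t12")

HIT_COLUMNS = ["patient_id", "timepoint", "rule_id", "mechanism", "harm", "triggering_codes"]


@dataclass(frozen=True)
class MedicationSnapshot:
    """The set of ATC codes a patient takes at one assessment time."""

    patient_id: str
    timepoint: str
    codes: frozenset[str]

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"unknown timepoint {self.timepoint!r}; allowed: {list(TIMEPOINTS)}"
            )
        cleaned = set()
        for code in self.codes:
            try:
                cleaned.add(canonical_atc(code))
            except ATCFormatError:
                logger.warning(
                    "patient %s %s: skipping invalid ATC code %r",
                    self.patient_id, self.timepoint, code,
                )
        object.__setattr__(self, "codes", frozenset(cleaned))


@dataclass(frozen=True)
class DDIHit:
    """One rule triggered for one patient at one timepoint."""

    patient_id: str
    timepoint: str
    rule_id: int
    triggering_codes: frozenset[str]
    mechanism: Mechanism
    harm: HarmCategory


def evaluate_rule(snapshot: MedicationSnapshot, rule: DDIRule) -> DDIHit | None:
    """Evaluate one rule against one snapshot; return a hit or None.

    Pairwise: fires iff distinct codes a != b exist with a in group 1 and
    b in group 2 (a single code matching both groups is not an interaction).
    Cardinality: fires iff at least ``min_count`` distinct codes match the
    group.  ``triggering_codes`` carries every matching code.
    """
    if rule.kind == "pairwise":
        g1, g2 = rule.groups
        m1 = {c for c in snapshot.codes if g1.contains(c)}
        m2 = {c for c in snapshot.codes if g2.contains(c)}
        if not m1 or not m2 or len(m1 | m2) < 2:
            return None
        witnesses = m1 | m2
    else:
        (g,) = rule.groups
        matching = {c for c in snapshot.codes if g.contains(c)}
        if len(matching) < rule.min_count:
            return None
        witnesses = matching
    return DDIHit(
        patient_id=snapshot.patient_id,
        timepoint=snapshot.timepoint,
        rule_id=rule.rule_id,
        triggering_codes=frozenset(witnesses),
        mechanism=rule.mechanism,
        harm=rule.harm,
    )


def screen_snapshot(snapshot: MedicationSnapshot, rs: RuleSet) -> list[DDIHit]:
    """Screen one snapshot against every rule; hits ordered by rule_id."""
    hits = []
    for rule in rs:
        hit = evaluate_rule(snapshot, rule)
        if hit is not None:
            hits.append(hit)
    return hits


class _CompiledRules:
    """Membership matrices for bulk screening.

    For the unique codes of a cohort we precompute one boolean column per
    drug group (plus, for pairwise rules, the union of the two groups, which
    makes the distinctness requirement a simple count: a pairwise rule fires
    iff both groups are hit and the union contains >=2 distinct codes).
    """

    def __init__(self, rs: RuleSet, codes: list[str]):
        self.rs = rs
        self.codes = codes
        code_index = {c: i for i, c in enumerate(codes)}
        self.code_index = code_index
        n = len(codes)

        cols: list[np.ndarray] = []

        def col(group: DrugGroup) -> int:
            v = np.zeros(n, dtype=bool)
            for i, c in enumerate(codes):
                v[i] = group.contains(c)
            cols.append(v)
            return len(cols) - 1

        self.rule_cols: list[tuple[DDIRule, tuple[int, ...]]] = []
        self.witness_col: list[int] = []  # per rule: all-matching-codes column
        for rule in rs:
            if rule.kind == "pairwise":
                i1 = col(rule.groups[0])
                i2 = col(rule.groups[1])
                union = cols[i1] | cols[i2]
                cols.append(union)
                self.rule_cols.append((rule, (i1, i2, len(cols) - 1)))
                self.witness_col.append(len(cols) - 1)
            else:
                i1 = col(rule.groups[0])
                self.rule_cols.append((rule, (i1,)))
                self.witness_col.append(i1)
        self.membership = (
            np.stack(cols, axis=1) if cols else np.zeros((n, 0), dtype=bool)
        )

    def hit_matrix(self, indicator: np.ndarray) -> tuple[np.ndarray, list[DDIRule]]:
        """indicator: (n_snapshots, n_codes) boolean -> (n_snapshots, n_rules)."""
        counts = indicator.astype(np.int32) @ self.membership.astype(np.int32)
        out = np.zeros((indicator.shape[0], len(self.rule_cols)), dtype=bool)
        rules = []
        for j, (rule, idx) in enumerate(self.rule_cols):
            if rule.kind == "pairwise":
                i1, i2, iu = idx
                out[:, j] = (counts[:, i1] >= 1) & (counts[:, i2] >= 1) & (counts[:, iu] >= 2)
            else:
                (i1,) = idx
                out[:, j] = counts[:, i1] >= rule.min_count
            rules.append(rule)
        return out, rules


def _clean_cohort_codes(meds: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize codes, dropping (and logging) invalid ones."""
    codes = meds["atc_code"].astype(str)
    cleaned = []
    keep = np.ones(len(meds), dtype=bool)
    for i, raw in enumerate(codes):
        try:
            cleaned.append(canonical_atc(raw))
        except ATCFormatError:
            logger.warning("skipping invalid ATC code %r (row %d)", raw, i)
            cleaned.append("")
            keep[i] = False
    out = meds.copy()
    out["atc_code"] = cleaned
    return out[keep]


def screen_cohort(meds: pd.DataFrame, rs: RuleSet) -> pd.DataFrame:
    """Screen a long-format medication table against the rule set.

    Parameters
    ----------
    meds
        DataFrame with columns ``patient_id``, ``timepoint``, ``atc_code``
        (one row per drug; duplicates collapse).  Every (patient, timepoint)
        present is screened; censoring is the caller's responsibility (see
        :mod:`ddiscreen.longitudinal`).
    rs
        The validated rule set.

    Returns
    -------
    DataFrame with columns patient_id, timepoint, rule_id, mechanism, harm,
    triggering_codes ('|'-joined, sorted), stably sorted by
    (patient_id, timepoint order, rule_id).
    """
    required = {"patient_id", "timepoint", "atc_code"}
    missing = required - set(meds.columns)
    if missing:
        raise ValueError(f"medication table missing column(s): {sorted(missing)}")
    bad_tp = set(meds["timepoint"].unique()) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(
            f"unknown timepoint token(s) {sorted(bad_tp)}; allowed: {list(TIMEPOINTS)}"
        )
    meds = _clean_cohort_codes(meds)
    if meds.empty:
        return pd.DataFrame(columns=HIT_COLUMNS)

    dedup = meds.drop_duplicates(["patient_id", "timepoint", "atc_code"])
    codes = sorted(dedup["atc_code"].unique())
    compiled = _CompiledRules(rs, codes)

    combined = dedup["patient_id"].astype(str) + "\x1f" + dedup["timepoint"]
    row_idx, uniq_keys = pd.factorize(combined)
    keys = pd.DataFrame(
        [k.split("\x1f", 1) for k in uniq_keys], columns=["patient_id", "timepoint"]
    )
    indicator = np.zeros((len(keys), len(codes)), dtype=bool)
    col_idx = dedup["atc_code"].map(compiled.code_index).to_numpy()
    indicator[row_idx, col_idx] = True

    hit_mat, rules = compiled.hit_matrix(indicator)

    # Recover triggering codes only for the (snapshot, rule) pairs that
    # fired, reusing the compiled membership matrix.
    codes_arr = np.array(codes)
    records = []
    snap_rows, rule_cols = np.nonzero(hit_mat)
    for srow, jcol in zip(snap_rows, rule_cols):
        rule = rules[jcol]
        member = compiled.membership[:, compiled.witness_col[jcol]]
        witnesses = codes_arr[indicator[int(srow)] & member]
        records.append(
            {
                "patient_id": keys.loc[int(srow), "patient_id"],
                "timepoint": keys.loc[int(srow), "timepoint"],
                "rule_id": rule.rule_id,
                "mechanism": rule.mechanism.value,
                "harm": rule.harm.value,
                "triggering_codes": "|".join(sorted(witnesses)),
            }
        )
    out = pd.DataFrame(records, columns=HIT_COLUMNS)
    tp_order = {t: i for i, t in enumerate(TIMEPOINTS)}
    out = out.sort_values(
        ["patient_id", "timepoint", "rule_id"],
        key=lambda s: s.map(tp_order) if s.name == "timepoint" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def hits_to_frame(hits: list[DDIHit]) -> pd.DataFrame:
    """Convert DDIHit objects to the hit-table schema."""
    records = [
        {
            "patient_id": h.patient_id,
            "timepoint": h.timepoint,
            "rule_id": h.rule_id,
            "mechanism": h.mechanism.value,
            "harm": h.harm.value,
            "triggering_codes": "|".join(sorted(h.triggering_codes)),
        }
        for h in hits
    ]
    return pd.DataFrame(records, columns=HIT_COLUMNS)
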
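"""Censoring, point-prevalence, most-common rules and change classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ddiscreen as d
from ddiscreen.detection import MedicationSnapshot, screen_snapshot
from ddiscreen.longitudinal import (
    IneligiblePatientError,
    PatientTimeline,
    PrevalenceEstimate,
    UndefinedEstimateError,
    apply_censoring,
    classify_change,
    contributors,
    most_common_rules,
    point_prevalence,
)


def timeline(pid, timepoints, codes=("A10BA02",)):
    snaps = {tp: MedicationSnapshot(pid, tp, frozenset(codes))
             for tp in timepoints}
    return PatientTimeline(patient_id=pid, snapshots=snaps)


def hits_frame(rows):
    """rows: (patient_id, timepoint, rule_id, mechanism, harm)"""
    cols = ["patient_id", "timepoint", "rule_id", "mechanism", "harm",
            "triggering_codes"]
    return pd.DataFrame(
        [dict(zip(cols, (p, t, r, m, h, ""))) for p, t, r, m, h in rows],
        columns=cols,
    )


class TestCensoring:
    def test_gap_at_two_months_censors_and_discards_later_data(self):
        t = apply_censoring(timeline("p1", ["t0", "t1", "t6"]))
        assert t.censor_at == "t2"
        assert "t6" not in t.snapshots
        assert not t.contributes_at("t6")

    def test_complete_follow_up_is_uncensored(self):
        t = apply_censoring(timeline("p1", ["t0", "t1", "t2", "t6", "t12"]))
        assert t.censor_at is None
        assert all(t.contributes_at(tp) for tp in d.TIMEPOINTS)

    def test_hospital_only_data_censors_at_first_follow_up(self):
        t = apply_censoring(timeline("p1", ["t0", "t1"]))
        assert t.censor_at == "t2"
        assert t.contributes_at("t0") and t.contributes_at("t1")

    @pytest.mark.parametrize("present", [["t1", "t2"], ["t0"], ["t2", "t6"]])
    def test_missing_hospital_snapshot_is_ineligible(self, present):
        with pytest.raises(IneligiblePatientError):
            timeline("p1", present)


class TestPointPrevalence:
    def test_printed_numerator_denominator_rounds_to_54_percent(self):
        est = PrevalenceEstimate("t0", "overall", "overall",
                                 n_with=1045, n_total=1950)
        assert est.proportion == pytest.approx(0.5359, abs=1e-4)
        assert round(100 * est.proportion) == 54

    def test_no_hits_gives_zero_prevalence(self):
        tls = [apply_censoring(timeline(f"p{i}", ["t0", "t1"])) for i in range(4)]
        (est,) = point_prevalence(hits_frame([]), tls, "t0")
        assert est.n_with == 0 and est.n_total == 4

    def test_empty_denominator_is_an_error(self):
        tls = [apply_censoring(timeline("p1", ["t0", "t1"]))]
        with pytest.raises(UndefinedEstimateError):
            point_prevalence(hits_frame([]), tls, "t6")

    def test_mechanism_both_counts_in_pk_and_pd_strata(self):
        tls = [apply_censoring(timeline("p1", ["t0", "t1"]))]
        hits = hits_frame([("p1", "t0", 4, "both", "cardiovascular")])
        ests = {e.stratum: e for e in point_prevalence(hits, tls, "t0", "mechanism")}
        assert ests["pharmacokinetic"].n_with == 1
        assert ests["pharmacodynamic"].n_with == 1

    def test_overall_at_least_any_stratum(self, small_cohort, small_cohort_screen):
        tls = small_cohort.timelines()
        for tp in ("t0", "t1", "t2"):
            (overall,) = point_prevalence(small_cohort_screen, tls, tp)
            for strat in ("mechanism", "harm", "rule"):
                for e in point_prevalence(small_cohort_screen, tls, tp, strat):
                    assert e.n_with <= overall.n_with

    def test_denominators_non_increasing_after_discharge(self, small_cohort):
        tls = small_cohort.timelines()
        sizes = [len(contributors(tls, tp)) for tp in ("t2", "t6", "t12")]
        assert sizes == sorted(sizes, reverse=True)

    def test_per_rule_numerators_match_bruteforce_recount(
        self, small_cohort, small_cohort_screen
    ):
        """Stratified numerators re-derived patient-by-patient from raw hits."""
        tls = small_cohort.timelines()
        pool = contributors(tls, "t0")
        h = small_cohort_screen
        h = h[(h.timepoint == "t0") & h.patient_id.isin(pool)]
        recount = h.groupby("rule_id")["patient_id"].nunique().to_dict()
        for e in point_prevalence(small_cohort_screen, tls, "t0", "rule"):
            assert e.n_with == recount[int(e.stratum)]
            assert e.n_total == len(pool)


class TestMostCommonRules:
    def test_single_rule_cohort(self):
        hits = hits_frame([("p1", "t0", 65, "pharmacodynamic", "cardiovascular")])
        out = most_common_rules(hits, "t0")
        assert out["rule_id"].tolist() == [65]
        assert out["selected"].all()

    def test_uniform_frequencies_keep_all_ties(self):
        rows = [(f"p{i}", "t0", r, "pharmacodynamic", "other")
                for r in (1, 2, 3, 4) for i in range(3)]
        out = most_common_rules(hits_frame(rows), "t0")
        assert out["selected"].all()

    def test_no_hits_is_empty(self):
        assert most_common_rules(hits_frame([]), "t0").empty

    def test_generator_dominant_rules_rank_first(
        self, small_cohort, small_cohort_screen
    ):
        out = most_common_rules(small_cohort_screen, "t0")
        assert set(out.head(5)["rule_id"]) == {65, 36, 21, 12, 39}


class TestClassifyChange:
    def _tls(self, pids):
        return [apply_censoring(timeline(p, ["t0", "t1", "t2"])) for p in pids]

    def test_new_rule_is_increase_only(self):
        hits = hits_frame([("p1", "t0", 65, "pharmacodynamic", "cardiovascular"),
                           ("p1", "t2", 65, "pharmacodynamic", "cardiovascular"),
                           ("p1", "t2", 36, "pharmacodynamic", "neurological")])
        (c,) = classify_change(hits, self._tls(["p1"]))
        assert c.increased and not c.decreased

    def test_swap_is_both(self):
        hits = hits_frame([("p1", "t0", 36, "pharmacodynamic", "neurological"),
                           ("p1", "t2", 65, "pharmacodynamic", "cardiovascular")])
        (c,) = classify_change(hits, self._tls(["p1"]))
        assert c.increased and c.decreased

    def test_identical_rule_sets_are_no_change(self):
        hits = hits_frame([("p1", "t0", 12, "pharmacodynamic", "bleeding"),
                           ("p1", "t2", 12, "pharmacodynamic", "bleeding")])
        (c,) = classify_change(hits, self._tls(["p1"]))
        assert not c.increased and not c.decreased

    def test_censored_patients_excluded(self):
        tls = [apply_censoring(timeline("p1", ["t0", "t1", "t2"])),
               apply_censoring(timeline("p2", ["t0", "t1"]))]
        out = classify_change(hits_frame([]), tls)
        assert [c.patient_id for c in out] == ["p1"]

    def test_matches_bruteforce_recomputation_from_snapshots(
        self, rules, small_cohort, small_cohort_screen
    ):
        """Re-screen raw snapshots one at a time and re-derive the change
        flags by set difference, independently of the hit table."""
        tls = small_cohort.timelines()
        got = {c.patient_id: c for c in classify_change(small_cohort_screen, tls)}
        n_checked = 0
        for t in tls:
            if not (t.contributes_at("t0") and t.contributes_at("t2")):
                assert t.patient_id not in got
                continue
            r0 = {h.rule_id for h in screen_snapshot(t.snapshots["t0"], rules)}
            r2 = {h.rule_id for h in screen_snapshot(t.snapshots["t2"], rules)}
            assert got[t.patient_id].increased == bool(r2 - r0)
            assert got[t.patient_id].decreased == bool(r0 - r2)
            n_checked += 1
        assert n_checked == len(got) > 100
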
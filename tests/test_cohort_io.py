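"""Domain types, CSV round-trips, life tables and interval construction."""

import io
import math

import numpy as np
import pytest

from ptfr import (
    NEVER_EVENT,
    IntervalDatum,
    LifeTable,
    PtfrError,
    RowValidationError,
    SchemaError,
    Status,
    SubjectRecord,
    VisitHistory,
    build_life_table,
    eligible_subset,
    histories_to_intervals,
    life_table_observed_pt,
    read_life_table,
    read_subjects,
    read_visit_histories,
    subjects_to_intervals,
    truncate_at_horizon,
    write_life_table,
    write_subjects,
)
from ptfr.datasets import toy_cohort

from .conftest import random_oracle_cohort


class TestReadSubjects:
    def test_parses_all_three_statuses(self):
        csv = io.StringIO(
            "subject_id,exit_time,status\na,1.0,event\nb,2.0,DROPOUT\nc,3.0,admin_censored\n"
        )
        recs = read_subjects(csv)
        assert [r.status for r in recs] == [
            Status.EVENT,
            Status.DROPOUT,
            Status.ADMIN_CENSORED,
        ]
        assert [r.subject_id for r in recs] == ["a", "b", "c"]

    def test_integer_status_codes(self):
        csv = io.StringIO("subject_id,exit_time,status\na,1.0,1\nb,2.0,2\nc,3.0,0\n")
        recs = read_subjects(csv)
        assert [r.status for r in recs] == [
            Status.EVENT,
            Status.DROPOUT,
            Status.ADMIN_CENSORED,
        ]

    def test_header_only_gives_empty_list(self):
        assert read_subjects(io.StringIO("subject_id,exit_time,status\n")) == []

    def test_negative_exit_time_names_the_row(self):
        csv = io.StringIO("subject_id,exit_time,status\na,1.0,event\nb,-1,dropout\n")
        with pytest.raises(RowValidationError, match="row 1"):
            read_subjects(csv)

    def test_missing_column_names_it(self):
        with pytest.raises(SchemaError, match="status"):
            read_subjects(io.StringIO("subject_id,exit_time\na,1.0\n"))

    def test_never_event_marker_and_schema_mapping(self):
        csv = io.StringIO("id,t,state,oracle\na,1.0,dropout,never\nb,0.5,event,0.5\n")
        recs = read_subjects(
            csv,
            schema={
                "subject_id": "id",
                "exit_time": "t",
                "status": "state",
                "true_event_time": "oracle",
            },
        )
        assert recs[0].true_event_time == NEVER_EVENT
        assert recs[1].true_event_time == 0.5

    def test_roundtrip_preserves_records(self, tmp_path, toy_a_events):
        path = tmp_path / "cohort.csv"
        write_subjects(toy_a_events, path)
        assert read_subjects(path) == toy_a_events


class TestLifeTable:
    def test_toy_scenario_a_counts(self, toy_a):
        lt = build_life_table(toy_a, [0, 1, 2, 3])
        assert lt.n_at_risk == (100, 50, 45)
        assert lt.n_events == (10, 5, 5)
        assert lt.n_dropouts == (40, 0, 0)

    def test_toy_scenario_b_counts(self, toy_b):
        lt = build_life_table(toy_b, [0, 1, 2, 3])
        assert lt.n_at_risk == (100, 90, 85)
        assert lt.n_events == (10, 5, 5)
        assert lt.n_dropouts == (0, 0, 40)

    def test_admin_censored_survivors_exit_nowhere(self):
        recs = [
            SubjectRecord(str(i), 3.0, Status.ADMIN_CENSORED) for i in range(5)
        ]
        lt = build_life_table(recs, [0, 1, 2, 3])
        assert lt.n_events == (0, 0, 0) and lt.n_dropouts == (0, 0, 0)
        assert lt.n_final == 5

    def test_observed_person_time_midpoint_convention(self, toy_a, toy_b):
        assert life_table_observed_pt(build_life_table(toy_a, [0, 1, 2, 3])) == 165.0
        assert life_table_observed_pt(build_life_table(toy_b, [0, 1, 2, 3])) == 245.0

    def test_full_follow_up_person_time(self):
        lt = LifeTable([0, 1, 2, 3], [10, 10, 10], [0, 0, 0], [0, 0, 0])
        assert life_table_observed_pt(lt) == 30.0

    def test_non_unit_intervals_scale_person_time(self):
        lt = LifeTable([0, 2], [10], [2], [0])
        assert life_table_observed_pt(lt) == 2 * (10 - 1)

    def test_bookkeeping_identity_enforced(self):
        with pytest.raises(PtfrError, match="N_k"):
            LifeTable([0, 1, 2], [10, 9], [2, 0], [0, 0])

    def test_exit_beyond_last_boundary_rejected(self):
        recs = [SubjectRecord("a", 4.0, Status.EVENT)]
        with pytest.raises(PtfrError, match="exceeds"):
            build_life_table(recs, [0, 1, 2, 3])

    def test_exit_conservation(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            cohort = truncate_at_horizon(random_oracle_cohort(rng, tau=5.0), 5.0)
            lt = build_life_table(cohort, [0, 1, 2, 3, 4, 5])
            n_ev = sum(r.status is Status.EVENT for r in cohort)
            n_dr = sum(r.status is Status.DROPOUT for r in cohort)
            assert sum(lt.n_events) == n_ev
            assert sum(lt.n_dropouts) == n_dr

    def test_csv_roundtrip(self, tmp_path, toy_a):
        lt = build_life_table(toy_a, [0, 1, 2, 3])
        path = tmp_path / "lt.csv"
        write_life_table(lt, path)
        assert read_life_table(path) == lt


class TestIntervals:
    def test_toy_scenario_a_intervals(self, toy_a):
        data = subjects_to_intervals(toy_a, [0, 1, 2, 3], sentinel_e=100.0)
        got = {(d.left, d.right): d.weight for d in data}
        assert got == {
            (0.0, 1.0): 10,
            (1.0, 2.0): 5,
            (2.0, 3.0): 5,
            (0.0, 100.0): 40,
            (3.0, 100.0): 40,
        }

    def test_weights_sum_to_cohort_size(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            cohort = truncate_at_horizon(random_oracle_cohort(rng, tau=5.0), 5.0)
            data = subjects_to_intervals(cohort, [0, 1, 2, 3, 4, 5])
            assert sum(d.weight for d in data) == len(cohort)

    def test_irregular_event_uses_previous_visit(self):
        h = VisitHistory("a", (0.0, 0.8, 2.1), event_at_last_visit=True)
        (d,) = histories_to_intervals([h])
        assert (d.left, d.right) == (0.8, 2.1)

    def test_irregular_survivor_is_right_open(self):
        h = VisitHistory("a", (0.0, 1.2), event_at_last_visit=False)
        (d,) = histories_to_intervals([h], sentinel_e=100.0)
        assert (d.left, d.right) == (1.2, 100.0)

    def test_event_at_first_visit_starts_at_entry(self):
        h = VisitHistory("a", (0.7,), event_at_last_visit=True)
        (d,) = histories_to_intervals([h])
        assert (d.left, d.right) == (0.0, 0.7)

    def test_sentinel_must_exceed_last_boundary(self, toy_a):
        with pytest.raises(PtfrError, match="sentinel"):
            subjects_to_intervals(toy_a, [0, 1, 2, 3], sentinel_e=2.0)

    def test_empty_interval_rejected(self):
        with pytest.raises(PtfrError, match="empty"):
            IntervalDatum(1.0, 1.0)


class TestHorizonHandling:
    def _staggered(self):
        return [
            SubjectRecord("early", 5.0, Status.ADMIN_CENSORED, entry_offset=0.0),
            SubjectRecord("mid", 2.0, Status.DROPOUT, entry_offset=3.0),
            SubjectRecord("late", 1.0, Status.EVENT, 1.0, entry_offset=6.0),
        ]

    def test_eligibility_by_potential_follow_up(self):
        subjects = self._staggered()
        # 7.2-year study: a subject entering at 3.0 years has 4.2 potential
        assert {r.subject_id for r in eligible_subset(subjects, 5.0, 7.2)} == {"early"}
        assert {r.subject_id for r in eligible_subset(subjects, 3.0, 7.2)} == {
            "early",
            "mid",
        }

    def test_horizon_beyond_study_span_empty(self):
        assert eligible_subset(self._staggered(), 8.0, 7.2) == []

    def test_all_common_entry_all_retained(self):
        subjects = [
            SubjectRecord(str(i), 1.0, Status.EVENT, 1.0, entry_offset=0.0)
            for i in range(4)
        ]
        assert len(eligible_subset(subjects, 3.0, 3.0)) == 4

    def test_truncation_converts_late_exits_to_admin(self):
        subjects = [
            SubjectRecord("a", 4.0, Status.EVENT, 4.0, entry_offset=0.0),
            SubjectRecord("b", 2.0, Status.DROPOUT, entry_offset=0.0),
        ]
        out = eligible_subset(subjects, 3.0, 10.0)
        assert out[0].status is Status.ADMIN_CENSORED and out[0].exit_time == 3.0
        assert out[1].status is Status.DROPOUT and out[1].exit_time == 2.0

    def test_dropout_exactly_at_horizon_is_administrative(self):
        (rec,) = truncate_at_horizon(
            [SubjectRecord("a", 3.0, Status.DROPOUT)], 3.0
        )
        assert rec.status is Status.ADMIN_CENSORED

    def test_idempotent_and_monotone_in_horizon(self):
        subjects = self._staggered()
        e3 = eligible_subset(subjects, 3.0, 7.2)
        assert eligible_subset(e3, 3.0, 7.2) == e3
        ids5 = {r.subject_id for r in eligible_subset(subjects, 5.0, 7.2)}
        ids3 = {r.subject_id for r in eligible_subset(subjects, 3.0, 7.2)}
        assert ids5 <= ids3

    def test_missing_entry_offset_rejected(self):
        with pytest.raises(PtfrError, match="entry_offset"):
            eligible_subset([SubjectRecord("a", 1.0, Status.EVENT, 1.0)], 1.0, 5.0)


class TestVisitHistoryReader:
    def test_long_format_grouping(self):
        csv = io.StringIO(
            "subject_id,visit_time,event_flag\n"
            "a,0.0,0\na,1.1,0\na,2.0,1\nb,0.0,0\nb,0.9,0\n"
        )
        h = read_visit_histories(csv)
        assert h[0] == VisitHistory("a", (0.0, 1.1, 2.0), True)
        assert h[1] == VisitHistory("b", (0.0, 0.9), False)

    def test_non_increasing_visits_rejected(self):
        with pytest.raises(PtfrError, match="increasing"):
            VisitHistory("a", (0.0, 1.0, 1.0))
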
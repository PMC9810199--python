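"""Event-log extraction: cohort selection, per-type customization, repair,
serialization round trips, and the event-conservation invariant."""

import pandas as pd
import pytest

from omopflow.extraction import (Cohort, Event, EventLog, LogSpec, Trace,
                                 compute_los, extract_er_log,
                                 extract_inpatient_log, extract_log,
                                 extract_outpatient_log,
                                 extract_patient_journey_log,
                                 repair_dateonly_timestamps, select_cohort)
from omopflow.log_io import logs_equal, read_log, write_log
from omopflow.synthetic import DatasetBuilder

SURGERY = 4336464
T = pd.Timestamp


def _inpatient_toy():
    """Five inpatient visits; surgery concept present in three of them."""
    builder = DatasetBuilder()
    for i in range(1, 6):
        builder.add_person(i, 8532 if i % 2 else 8507, 1981)
        vid = builder.add_visit(i, 9201, T(f"2021-08-0{i} 09:03:00"),
                                T(f"2021-08-0{i + 3} 10:00:00"),
                                provider_id=1)
        if i <= 3:
            builder.add_event("procedure_occurrence", i, vid, SURGERY,
                              T(f"2021-08-0{i + 1} 08:30:00"), provider_id=1)
        builder.add_event("drug_exposure", i, vid, 1154186,
                          T(f"2021-08-0{i} 09:03:00"), provider_id=1)
    return builder.finalize()


def test_cohort_selection_filters_on_contained_concept():
    dataset = _inpatient_toy()
    spec = LogSpec(process_type="inpatient",
                   cohort=Cohort(concept_ids=[SURGERY]))
    assert select_cohort(dataset, spec) == [1, 2, 3]


def test_cohort_period_excluding_all_visits_is_empty():
    dataset = _inpatient_toy()
    spec = LogSpec(process_type="inpatient", period_start=T("1999-01-01"),
                   period_end=T("2000-01-01"),
                   cohort=Cohort(concept_ids=[SURGERY]))
    assert select_cohort(dataset, spec) == []


def test_descendant_expansion_selects_visit_with_child_concept_only():
    builder = DatasetBuilder()
    builder.config.extra_ancestor_pairs.append((500, 501))
    builder.use_concept(500)
    builder.add_person(1, 8532, 1980)
    vid = builder.add_visit(1, 9201, T("2021-08-01 09:00:00"),
                            T("2021-08-04 10:00:00"))
    builder.add_event("procedure_occurrence", 1, vid, 501,
                      T("2021-08-02 09:00:00"))
    dataset = builder.finalize()
    without = LogSpec(process_type="inpatient",
                      cohort=Cohort(concept_ids=[500]))
    with_desc = LogSpec(process_type="inpatient",
                        cohort=Cohort(concept_ids=[500],
                                      use_descendants=True))
    assert select_cohort(dataset, without) == []
    assert select_cohort(dataset, with_desc) == [vid]


@pytest.mark.parametrize("start, end, unit, expected", [
    ("2021-08-01 09:03:00", "2021-08-04 10:00:00", "days", 3),
    ("2021-08-01 09:03:00", "2021-08-01 09:03:00", "days", 0),
    ("2021-08-01 19:04:00", "2021-08-01 20:04:00", "hours", 1.00),
    ("2021-08-01 23:50:00", "2021-08-02 00:10:00", "days", 1),
])
def test_los_computation(start, end, unit, expected):
    assert compute_los(T(start), T(end), unit) == expected


def test_los_rejects_reversed_visit():
    with pytest.raises(ValueError):
        compute_los(T("2021-08-02"), T("2021-08-01"), "days")


def test_inpatient_scope_filters_event_tables():
    builder = DatasetBuilder()
    builder.add_person(1, 8532, 1981)
    vid = builder.add_visit(1, 9201, T("2021-08-01 09:00:00"),
                            T("2021-08-04 10:00:00"), provider_id=1)
    for k in range(4):
        builder.add_event("drug_exposure", 1, vid, 1154186,
                          T(f"2021-08-01 1{k}:00:00"), provider_id=1)
    for k in range(2):
        builder.add_event("measurement", 1, vid, 3012608,
                          T(f"2021-08-02 1{k}:00:00"), provider_id=1)
    dataset = builder.finalize()
    spec = LogSpec(process_type="inpatient", scope=["drug_exposure"])
    log = extract_inpatient_log(dataset, spec)
    assert len(log) == 1 and log.n_events == 4


def test_inpatient_case_attributes_match_demographics():
    dataset = _inpatient_toy()
    spec = LogSpec(process_type="inpatient", scope=["drug_exposure"],
                   cohort=Cohort(concept_ids=[SURGERY]))
    log = extract_inpatient_log(dataset, spec)
    trace = log.case("1")
    assert trace.attributes["los_days"] == 3
    assert trace.attributes["sex"] == "8532 (Female)"
    assert trace.attributes["age"] == 40
    assert trace.events[0].activity == "1154186 (fentanyl 0.1 MG)"
    assert trace.events[0].originator == "O00001"


def _outpatient_toy(date_only=("cost",)):
    builder = DatasetBuilder()
    builder.add_person(1, 8532, 1991)
    vid = builder.add_visit(1, 9202, T("2021-08-01 09:00:00"),
                            T("2021-08-01 17:00:00"), care_site_id=1)
    rows = [("condition_occurrence", 3100001, "10:10:00"),
            ("drug_exposure", 1154186, "10:25:00"),
            ("cost", 3400001, "10:40:00"),
            ("observation", 3200001, "10:05:00")]
    for table, concept, time in rows:
        builder.add_event(table, 1, vid, concept, T(f"2021-08-01 {time}"),
                          date_only=table in date_only)
    return builder.finalize()


def test_outpatient_activities_use_table_level_labels():
    dataset = _outpatient_toy(date_only=())
    spec = LogSpec(process_type="outpatient", features=["department"])
    log = extract_outpatient_log(dataset, spec)
    activities = [e.activity for e in log.traces[0].events]
    assert activities == ["Survey", "Consultation", "Drug", "Payment"]
    assert all(e.attributes["department"] == "Care site 1"
               for e in log.traces[0].events)


def test_repair_orders_condition_before_drug_before_cost():
    dataset = _outpatient_toy(
        date_only=("condition_occurrence", "drug_exposure", "cost"))
    spec = LogSpec(process_type="outpatient")
    log = extract_outpatient_log(dataset, spec)
    repaired = repair_dateonly_timestamps(log)
    events = repaired.traces[0].events
    # the one timed event (observation 10:05) stays put and anchors the rest
    assert events[0].activity == "Survey"
    assert events[0].timestamp == T("2021-08-01 10:05:00")
    assert [e.activity for e in events[1:]] == ["Consultation", "Drug",
                                                "Payment"]
    # K=3 repaired events -> successive gaps 5, 17.5, 30 minutes
    gaps = [(b.timestamp - a.timestamp).total_seconds() / 60
            for a, b in zip(events, events[1:])]
    assert gaps == [5.0, 17.5, 30.0]


def test_repair_single_event_gets_minimum_gap():
    dataset = _outpatient_toy(date_only=("cost",))
    log = extract_outpatient_log(dataset, LogSpec(process_type="outpatient"))
    repaired = repair_dateonly_timestamps(log)
    events = repaired.traces[0].events
    last_timed = T("2021-08-01 10:25:00")  # drug row
    payment = [e for e in events if e.activity == "Payment"][0]
    assert payment.timestamp == last_timed + pd.Timedelta(minutes=5)
    for e in events:
        if e.activity != "Payment":
            assert not e.attributes.get("repaired")


def test_repair_rejects_uncovered_table():
    dataset = _outpatient_toy(date_only=("observation",))
    log = extract_outpatient_log(dataset, LogSpec(process_type="outpatient"))
    with pytest.raises(ValueError, match="observation"):
        repair_dateonly_timestamps(log)


def test_repair_without_dateonly_events_is_identity():
    dataset = _outpatient_toy(date_only=())
    log = extract_outpatient_log(dataset, LogSpec(process_type="outpatient"))
    assert logs_equal(repair_dateonly_timestamps(log), log)


def _er_toy():
    builder = DatasetBuilder()
    builder.add_person(1, 8532, 2011)
    builder.add_person(2, 8507, 1971)
    builder.add_visit(1, 9203, T("2021-08-01 19:04:00"),
                      T("2021-08-01 20:04:00"), provider_id=1,
                      admitting=8536, discharge=8536)
    vid2 = builder.add_visit(2, 9203, T("2021-08-01 20:01:00"),
                             T("2021-08-02 01:00:00"), provider_id=2,
                             admitting=44790567, discharge=8536)
    builder.add_event("measurement", 2, vid2, 3012608,
                      T("2021-08-01 21:00:00"), provider_id=2)
    return builder.finalize()


def test_er_boundary_activities_and_los():
    log = extract_er_log(_er_toy(), LogSpec(process_type="er"))
    one, two = log.traces
    assert one.events[0].activity == "8536 (Visit from home)"
    assert one.events[-1].activity == "8536 (Discharge to home)"
    assert one.events[-1].timestamp == T("2021-08-01 20:04:00")
    assert one.attributes["los_hours"] == 1.00
    assert two.events[0].activity == \
        "44790567 (Patient transfer from hospital to hospital)"
    assert [e.activity for e in two.events][1] == "Measurement"


def test_er_missing_boundary_concepts_get_placeholder_labels():
    builder = DatasetBuilder()
    builder.add_person(1, 8532, 1980)
    builder.add_visit(1, 9203, T("2021-08-01 10:00:00"),
                      T("2021-08-01 12:00:00"))
    log = extract_er_log(builder.finalize(), LogSpec(process_type="er"))
    assert log.traces[0].events[0].activity == "unknown source"
    assert log.traces[0].events[-1].activity == "unknown destination"


def _journey_toy():
    """A four-visit patient mirroring the visit-type sequence Out, Lab, ER,
    In, plus duplicate same-day drug rows in the first outpatient visit."""
    builder = DatasetBuilder()
    builder.add_person(1, 8532, 2011)
    v1 = builder.add_visit(1, 9202, T("2021-08-01 09:04:00"),
                           T("2021-08-01 11:00:00"))
    builder.add_visit(1, 32036, T("2021-08-01 12:04:00"),
                      T("2021-08-01 13:00:00"))
    v3 = builder.add_visit(1, 9203, T("2021-09-11 12:04:00"),
                           T("2021-09-11 18:00:00"), admitting=8536,
                           discharge=8536)
    v4 = builder.add_visit(1, 9201, T("2021-09-14 14:04:00"),
                           T("2021-09-20 10:00:00"))
    builder.add_event("drug_exposure", 1, v1, 1154186,
                      T("2021-08-01 09:30:00"))
    builder.add_event("drug_exposure", 1, v1, 19086213,
                      T("2021-08-01 10:15:00"))
    builder.add_event("measurement", 1, v3, 3012608, T("2021-09-11 13:00:00"))
    builder.add_event("procedure_occurrence", 1, v4, SURGERY,
                      T("2021-09-15 09:00:00"))
    return builder.finalize()


def test_visit_level_journey_trace():
    spec = LogSpec(process_type="patient_journey")
    log = extract_patient_journey_log(_journey_toy(), spec)
    assert [e.activity for e in log.traces[0].events] == [
        "Outpatient visit", "Laboratory visit", "Emergency room visit",
        "Inpatient visit"]


def test_descendant_journey_dedups_same_day_activity_types():
    spec = LogSpec(process_type="patient_journey", journey_level="descendant")
    log = extract_patient_journey_log(_journey_toy(), spec)
    activities = [e.activity for e in log.traces[0].events]
    # two same-date drug rows collapse into a single Out_1_Drug event
    assert activities.count("Out_1_Drug") == 1
    assert "ER_1_Measurement" in activities
    assert "In_1_Procedure" in activities


def test_descendant_journey_markers_wrap_each_visit():
    spec = LogSpec(process_type="patient_journey", journey_level="descendant",
                   journey_markers=True)
    log = extract_patient_journey_log(_journey_toy(), spec)
    activities = [e.activity for e in log.traces[0].events]
    assert activities[0] == "Out_1_Start"
    assert "Out_1_End" in activities and "In_1_End" in activities


def test_per_type_visit_indices_strictly_increase():
    builder = DatasetBuilder()
    builder.add_person(1, 8532, 1980)
    for day in (1, 5, 9):
        builder.add_visit(1, 9202, T(f"2021-08-0{day} 09:00:00"),
                          T(f"2021-08-0{day} 10:00:00"))
    spec = LogSpec(process_type="patient_journey", journey_level="descendant",
                   journey_markers=True)
    log = extract_patient_journey_log(builder.finalize(), spec)
    starts = [e.activity for e in log.traces[0].events
              if e.activity.endswith("Start")]
    assert starts == ["Out_1_Start", "Out_2_Start", "Out_3_Start"]


def test_equal_timestamp_ties_break_by_source_table_rank():
    builder = DatasetBuilder()
    builder.add_person(1, 8532, 1980)
    vid = builder.add_visit(1, 9201, T("2021-08-01 09:00:00"),
                            T("2021-08-04 10:00:00"))
    builder.add_event("drug_exposure", 1, vid, 1154186,
                      T("2021-08-01 10:00:00"))
    builder.add_event("condition_occurrence", 1, vid, 3100001,
                      T("2021-08-01 10:00:00"))
    spec = LogSpec(process_type="inpatient",
                   scope=["condition_occurrence", "drug_exposure"])
    log = extract_inpatient_log(builder.finalize(), spec)
    tables = [e.source_table for e in log.traces[0].events]
    assert tables == ["condition_occurrence", "drug_exposure"]


def test_event_conservation_against_cdm_rows(inpatient_small):
    cfg, dataset, _ = inpatient_small
    scope = ["procedure_occurrence", "drug_exposure", "measurement",
             "observation"]
    spec = LogSpec(process_type="inpatient", scope=scope,
                   cohort=Cohort(concept_ids=[cfg.surgery_concept_id]))
    log = extract_inpatient_log(dataset, spec)
    visit_ids = {int(t.case_id) for t in log.traces}
    expected = sum(
        int(dataset.events(t)["visit_occurrence_id"].isin(visit_ids).sum())
        for t in scope)
    assert log.n_events == expected
    # every event carries the provenance of exactly one CDM row
    keys = [(e.source_table, e.event_row_id)
            for t in log.traces for e in t.events]
    assert len(keys) == len(set(keys))


def test_er_conservation_adds_two_boundary_events(er_dataset):
    _, dataset, _ = er_dataset
    scope = ["measurement", "drug_exposure", "observation", "note"]
    log = extract_er_log(dataset, LogSpec(process_type="er", scope=scope))
    visit_ids = {int(t.case_id) for t in log.traces}
    scoped = sum(
        int(dataset.events(t)["visit_occurrence_id"].isin(visit_ids).sum())
        for t in scope)
    assert log.n_events == scoped + 2 * len(log)


def test_within_case_events_are_time_ordered_after_repair(outpatient_dataset):
    _, dataset, _ = outpatient_dataset
    log = repair_dateonly_timestamps(
        extract_outpatient_log(dataset, LogSpec(process_type="outpatient")))
    for trace in log.traces:
        stamps = [e.timestamp for e in trace.events]
        assert stamps == sorted(stamps)


@pytest.mark.parametrize("fmt", ["csv", "xes"])
def test_log_serialization_round_trip(er_dataset, tmp_path, fmt):
    _, dataset, _ = er_dataset
    log = extract_er_log(dataset, LogSpec(process_type="er"))
    path = tmp_path / f"log.{fmt}"
    write_log(log, path, fmt)
    assert logs_equal(read_log(path, fmt), log)


def test_round_trip_preserves_zero_event_cases(tmp_path):
    log = EventLog(traces=[
        Trace(case_id="empty", attributes={"los_days": 2}),
        Trace(case_id="full", attributes={"los_days": 1}, events=[
            Event(event_id="e1", activity="a",
                  timestamp=T("2021-08-01 10:00:00"))])])
    for fmt in ("csv", "xes"):
        path = tmp_path / f"log.{fmt}"
        write_log(log, path, fmt)
        back = read_log(path, fmt)
        assert logs_equal(back, log), fmt


def test_unknown_format_is_rejected(tmp_path):
    with pytest.raises(ValueError, match="format"):
        write_log(EventLog(), tmp_path / "x.bin", "parquet")


def test_extract_dispatch_covers_all_process_types(journey_dataset):
    _, dataset, _ = journey_dataset
    log = extract_log(dataset, LogSpec(process_type="patient_journey"))
    assert len(log) > 0
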
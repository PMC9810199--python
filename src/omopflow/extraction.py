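"""Event-log construction from a CDM dataset for four healthcare process types.

A log specification names the process type (inpatient, outpatient, ER,
patient journey), an extraction period, a scope of clinical source tables,
an optional cohort criterion (e.g. "visits containing surgery concept X",
optionally expanded through concept_ancestor), and optional features.  Each
extractor turns qualifying visits (or patients, for journeys) into traces:

* inpatient — case per visit, activities are concept-coded clinical orders
  rendered ``"<id> (<name>)"``, LOS in calendar days as a case attribute;
* outpatient — activities are coarse table-level labels (Consultation, Drug,
  Payment, ...), since CDMs carry no fine-grained administrative events;
* ER — admitting source and discharge destination become synthetic start/end
  activities, LOS in hours;
* patient journey — case per person; either one event per visit (visit-type
  labels) or indexed within-visit activities like ``Out_1_Drug`` with
  same-day duplicates collapsed.

Date-only timestamps can be repaired deterministically into the order
condition > drug > cost with gaps spread across a 5-30 minute band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cdm import CLINICAL_TABLES, SOURCE_TABLE_RANK, CdmDataset

logger = logging.getLogger(__name__)

PROCESS_TYPES = ("inpatient", "outpatient", "er", "patient_journey")

#: visit_concept_ids per process type; 262 covers "ER and inpatient" dual use
VISIT_CONCEPTS = {"inpatient": {9201}, "outpatient": {9202}, "er": {9203}}
DUAL_USE_VISIT_CONCEPT = 262

OUTPATIENT_ACTIVITY = {
    "condition_occurrence": "Consultation",
    "visit_occurrence": "Consultation",
    "measurement": "Physical examination & Lab test",
    "drug_exposure": "Drug",
    "procedure_occurrence": "Surgery & Radiology test",
    "cost": "Payment",
    "observation": "Survey",
    "device_exposure": "Device",
    "note": "Note",
}

JOURNEY_VISIT_LABELS = {9201: "Inpatient visit", 9202: "Outpatient visit",
                        9203: "Emergency room visit", 32036: "Laboratory visit"}
JOURNEY_TYPE_ABBREV = {9201: "In", 9202: "Out", 9203: "ER", 32036: "Lab"}
JOURNEY_TABLE_LABELS = {
    "condition_occurrence": "Condition", "procedure_occurrence": "Procedure",
    "drug_exposure": "Drug", "measurement": "Measurement",
    "device_exposure": "Device", "observation": "Observation",
    "cost": "Payment", "note": "Note",
}

DEFAULT_REPAIR_ORDER = ("condition_occurrence", "drug_exposure", "cost")


class Cohort(BaseModel):
    """Cohort criterion: visits containing >=1 event of these concepts."""

    table: str = "procedure_occurrence"
    concept_ids: list[int]
    use_descendants: bool = False


class LogSpec(BaseModel):
    """Declarative description of one event-log extraction."""

    process_type: str
    period_start: pd.Timestamp = pd.Timestamp("1900-01-01")
    period_end: pd.Timestamp = pd.Timestamp("2100-01-01")
    scope: list[str] = Field(default_factory=lambda: list(CLINICAL_TABLES))
    cohort: Optional[Cohort] = None
    features: list[str] = Field(default_factory=list)
    include_dual_use_visits: bool = True
    journey_level: str = "visit"  # visit | descendant
    journey_window_start: Optional[pd.Timestamp] = None
    journey_window_end: Optional[pd.Timestamp] = None
    journey_markers: bool = False
    visit_type_labels: dict[int, str] = Field(
        default_factory=lambda: dict(JOURNEY_VISIT_LABELS))
    visit_type_abbrev: dict[int, str] = Field(
        default_factory=lambda: dict(JOURNEY_TYPE_ABBREV))

    model_config = {"arbitrary_types_allowed": True}

    @model_validator(mode="after")
    def _check(self) -> "LogSpec":
        if self.process_type not in PROCESS_TYPES:
            raise ValueError(f"unknown process type {self.process_type!r}")
        if self.period_start >= self.period_end:
            raise ValueError("period start must precede end")
        if not self.scope:
            raise ValueError("scope must name at least one source table")
        for t in self.scope:
            if t not in CLINICAL_TABLES:
                raise ValueError(f"unknown scope table {t!r}")
        if self.journey_level not in ("visit", "descendant"):
            raise ValueError(f"unknown journey level {self.journey_level!r}")
        ws, we = self.journey_window_start, self.journey_window_end
        if (ws is None) != (we is None):
            raise ValueError("journey window needs both start and end")
        if ws is not None and (ws > self.period_start or we < self.period_end):
            raise ValueError("journey window must contain the period")
        return self


@dataclass
class Event:
    event_id: str
    activity: str
    timestamp: pd.Timestamp
    originator: str = ""
    source_table: str = ""
    concept_id: Optional[int] = None
    event_row_id: Optional[int] = None
    attributes: dict = field(default_factory=dict)


@dataclass
class Trace:
    case_id: str
    attributes: dict = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)


@dataclass
class EventLog:
    """A set of traces plus provenance of the extraction that produced it."""

    traces: list[Trace] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def n_events(self) -> int:
        return sum(len(t.events) for t in self.traces)

    def case(self, case_id: str) -> Trace:
        for t in self.traces:
            if t.case_id == case_id:
                return t
        raise KeyError(case_id)


def _event_sort_key(e: Event):
    return (e.timestamp, SOURCE_TABLE_RANK.get(e.source_table, 99),
            e.event_row_id if e.event_row_id is not None else 0)


def _visit_concepts_for(spec: LogSpec) -> set[int]:
    concepts = set(VISIT_CONCEPTS.get(spec.process_type, set()))
    if spec.include_dual_use_visits and spec.process_type in ("inpatient", "er"):
        concepts.add(DUAL_USE_VISIT_CONCEPT)
    return concepts


def _cohort_concepts(dataset: CdmDataset, cohort: Cohort) -> set[int]:
    concepts: set[int] = set()
    for cid in cohort.concept_ids:
        if cohort.use_descendants:
            concepts |= dataset.concept_descendants(cid)
        else:
            concepts.add(int(cid))
    return concepts


def select_cohort(dataset: CdmDataset, spec: LogSpec) -> list[int]:
    """Visit ids (person ids for journeys) qualifying under the spec.

    A visit qualifies when its visit_concept_id matches the process type, its
    start falls in the half-open period, and — if a cohort criterion is given
    — it contains at least one event of the cohort concepts (OR-ed, optionally
    expanded to vocabulary descendants).
    """
    visits = dataset.table("visit_occurrence")
    if spec.process_type == "patient_journey":
        in_period = visits[
            (visits["visit_start_datetime"] >= spec.period_start)
            & (visits["visit_start_datetime"] < spec.period_end)]
        if spec.cohort is None:
            persons = sorted(set(in_period["person_id"].dropna().astype(int)))
        else:
            concepts = _cohort_concepts(dataset, spec.cohort)
            ev = dataset.events(spec.cohort.table)
            hit_visits = set(ev.loc[ev["concept_id"].isin(concepts),
                                    "visit_occurrence_id"].dropna().astype(int))
            qualifying = in_period[
                in_period["visit_occurrence_id"].astype(int).isin(hit_visits)]
            persons = sorted(set(qualifying["person_id"].dropna().astype(int)))
        if not persons:
            logger.warning("cohort selection returned no patients")
        return persons

    concepts_ok = visits["visit_concept_id"].isin(_visit_concepts_for(spec))
    in_period = ((visits["visit_start_datetime"] >= spec.period_start)
                 & (visits["visit_start_datetime"] < spec.period_end))
    selected = visits[concepts_ok & in_period]
    if spec.cohort is not None:
        concepts = _cohort_concepts(dataset, spec.cohort)
        ev = dataset.events(spec.cohort.table)
        hit_visits = set(ev.loc[ev["concept_id"].isin(concepts),
                                "visit_occurrence_id"].dropna().astype(int))
        selected = selected[
            selected["visit_occurrence_id"].astype(int).isin(hit_visits)]
    ids = sorted(selected["visit_occurrence_id"].astype(int))
    if not ids:
        logger.warning("cohort selection returned no visits")
    return ids


def compute_los(visit_start: pd.Timestamp, visit_end: pd.Timestamp,
                unit: str = "days") -> float:
    """LOS as calendar-day difference (``days``) or exact hours (``hours``)."""
    if visit_end < visit_start:
        raise ValueError(f"visit end {visit_end} precedes start {visit_start}")
    if unit == "days":
        return int((visit_end.normalize() - visit_start.normalize()).days)
    if unit == "hours":
        return round((visit_end - visit_start).total_seconds() / 3600.0, 2)
    raise ValueError(f"unknown LOS unit {unit!r}")


def _person_index(dataset: CdmDataset) -> dict[int, tuple[int, int]]:
    persons = dataset.table("person")
    return {int(p): (int(g) if pd.notna(g) else 0,
                     int(y) if pd.notna(y) else 0)
            for p, g, y in zip(persons["person_id"],
                               persons["gender_concept_id"],
                               persons["year_of_birth"])}


def _demographics(dataset: CdmDataset, person_id: int,
                  visit_start: pd.Timestamp,
                  index: dict[int, tuple[int, int]]) -> dict:
    gender, birth_year = index.get(int(person_id), (0, 0))
    attrs = {"sex": dataset.resolve_concept(gender) if gender else "",
             "age": int(visit_start.year - birth_year) if birth_year else -1}
    return attrs


def _care_site_names(dataset: CdmDataset) -> dict[int, str]:
    cs = dataset.table("care_site")
    return dict(zip(cs["care_site_id"].astype(int), cs["care_site_name"]))


def _scoped_events(dataset: CdmDataset, scope, visit_ids: set[int]
                   ) -> pd.DataFrame:
    ev = dataset.all_events(scope)
    if ev.empty:
        return ev
    return ev[ev["visit_occurrence_id"].isin(visit_ids)]


def _originator(provider_id) -> str:
    return f"O{int(provider_id):05d}" if pd.notna(provider_id) else ""


def _rows_to_events(dataset: CdmDataset, rows: pd.DataFrame,
                    activity_of) -> list[Event]:
    events = []
    for row in rows.itertuples(index=False):
        events.append(Event(
            event_id=f"{row.source_table}:{int(row.event_row_id)}",
            activity=activity_of(row),
            timestamp=row.event_datetime,
            originator=_originator(row.provider_id),
            source_table=row.source_table,
            concept_id=int(row.concept_id) if pd.notna(row.concept_id) else None,
            event_row_id=int(row.event_row_id),
            attributes={"date_only": bool(row.date_only)}))
    events.sort(key=_event_sort_key)
    return events


def _visit_frame(dataset: CdmDataset, visit_ids: list[int]) -> pd.DataFrame:
    visits = dataset.table("visit_occurrence")
    sel = visits[visits["visit_occurrence_id"].isin(visit_ids)].copy()
    sel["visit_occurrence_id"] = sel["visit_occurrence_id"].astype(int)
    return sel.set_index("visit_occurrence_id").loc[visit_ids]


def extract_inpatient_log(dataset: CdmDataset, spec: LogSpec) -> EventLog:
    """One case per inpatient visit; activities are concept-coded orders."""
    assert spec.process_type == "inpatient"
    visit_ids = select_cohort(dataset, spec)
    sel = _visit_frame(dataset, visit_ids)
    events = _scoped_events(dataset, spec.scope, set(visit_ids))
    pidx = _person_index(dataset)
    log = EventLog(provenance={"process_type": "inpatient"})
    grouped = dict(tuple(events.groupby("visit_occurrence_id"))) if not events.empty else {}
    for vid in visit_ids:
        row = sel.loc[vid]
        rows = grouped.get(vid)
        if rows is None:
            logger.warning("visit %s has no scoped events", vid)
            rows = events.iloc[0:0]
        trace = Trace(case_id=str(vid))
        trace.attributes = {
            "los_days": compute_los(row["visit_start_datetime"],
                                    row["visit_end_datetime"], "days"),
            **_demographics(dataset, row["person_id"],
                            row["visit_start_datetime"], pidx)}
        trace.events = _rows_to_events(
            dataset, rows,
            lambda r: dataset.resolve_concept(int(r.concept_id)))
        log.traces.append(trace)
    return log


def extract_outpatient_log(dataset: CdmDataset, spec: LogSpec) -> EventLog:
    """One case per outpatient visit; activities are table-level labels."""
    assert spec.process_type == "outpatient"
    visit_ids = select_cohort(dataset, spec)
    sel = _visit_frame(dataset, visit_ids)
    events = _scoped_events(dataset, spec.scope, set(visit_ids))
    pidx = _person_index(dataset)
    care_sites = _care_site_names(dataset)
    log = EventLog(provenance={"process_type": "outpatient"})
    grouped = dict(tuple(events.groupby("visit_occurrence_id"))) if not events.empty else {}
    want_department = "department" in spec.features
    for vid in visit_ids:
        row = sel.loc[vid]
        rows = grouped.get(vid, events.iloc[0:0])
        trace = Trace(case_id=str(vid))
        trace.attributes = _demographics(
            dataset, row["person_id"], row["visit_start_datetime"], pidx)
        trace.events = _rows_to_events(
            dataset, rows, lambda r: OUTPATIENT_ACTIVITY[r.source_table])
        if want_department:
            cs = row["care_site_id"]
            department = (care_sites.get(int(cs), "") if pd.notna(cs) else "")
            for e in trace.events:
                e.attributes["department"] = department
        log.traces.append(trace)
    return log


def repair_dateonly_timestamps(
        log: EventLog, order=DEFAULT_REPAIR_ORDER,
        gap_minutes: tuple[float, float] = (5.0, 30.0)) -> EventLog:
    """Assign deterministic times to date-only events.

    Within each case and calendar day, date-only events are re-timestamped
    after the day's last timed event (09:00 if none), sequenced by the given
    source-table order; the k-th repaired event of a K-event day follows its
    predecessor by ``min + (max-min)*(k-1)/max(1, K-1)`` minutes, spreading
    the gaps across the 5-30 minute band.  Timed events are untouched.
    """
    lo, hi = gap_minutes
    if not (0 < lo <= hi):
        raise ValueError("gap range must satisfy 0 < min <= max")
    rank = {t: i for i, t in enumerate(order)}
    out = EventLog(provenance={**log.provenance, "repaired": True})
    for trace in log.traces:
        new_trace = Trace(case_id=trace.case_id,
                          attributes=dict(trace.attributes))
        by_day: dict = {}
        for e in trace.events:
            by_day.setdefault(e.timestamp.normalize(), []).append(e)
        new_events: list[Event] = []
        for day, day_events in by_day.items():
            dated = [e for e in day_events if e.attributes.get("date_only")]
            timed = [e for e in day_events
                     if not e.attributes.get("date_only")]
            new_events.extend(
                Event(**{**vars(t), "attributes": dict(t.attributes)})
                for t in timed)
            if not dated:
                continue
            missing = {e.source_table for e in dated} - set(order)
            if missing:
                raise ValueError(
                    f"date-only events from tables {sorted(missing)} not "
                    f"covered by repair order {list(order)}")
            dated.sort(key=lambda e: (rank[e.source_table],
                                      e.event_row_id or 0))
            base = max((t.timestamp for t in timed),
                       default=day + pd.Timedelta(hours=9))
            k_total = len(dated)
            cursor = base
            for k, e in enumerate(dated, start=1):
                gap = lo + (hi - lo) * (k - 1) / max(1, k_total - 1)
                cursor = cursor + pd.Timedelta(minutes=gap)
                fixed = Event(**vars(e))
                fixed.timestamp = cursor
                fixed.attributes = {**e.attributes, "date_only": False,
                                    "repaired": True}
                new_events.append(fixed)
        new_events.sort(key=_event_sort_key)
        new_trace.events = new_events
        out.traces.append(new_trace)
    return out


def _discharge_label(dataset: CdmDataset, concept_id) -> str:
    if pd.isna(concept_id):
        logger.warning("visit lacks discharge_to_concept_id")
        return "unknown destination"
    name = dataset.concept_name(int(concept_id)) or "unknown"
    dest = name[len("Visit from "):] if name.startswith("Visit from ") else name
    return f"{int(concept_id)} (Discharge to {dest})"


def _admitting_label(dataset: CdmDataset, concept_id) -> str:
    if pd.isna(concept_id):
        logger.warning("visit lacks admitting_source_concept_id")
        return "unknown source"
    return dataset.resolve_concept(int(concept_id))


def extract_er_log(dataset: CdmDataset, spec: LogSpec) -> EventLog:
    """ER cases bounded by admitting-source and discharge activities.

    The first event of every case is the admitting-source concept rendering
    at visit start; the last is ``"<id> (Discharge to <dest>)"`` at visit
    end.  Interior activities default to table-level labels (the feature
    ``concept_activities`` switches to concept renderings).  LOS is recorded
    in hours.
    """
    assert spec.process_type == "er"
    visit_ids = select_cohort(dataset, spec)
    sel = _visit_frame(dataset, visit_ids)
    events = _scoped_events(dataset, spec.scope, set(visit_ids))
    pidx = _person_index(dataset)
    concept_level = "concept_activities" in spec.features
    log = EventLog(provenance={"process_type": "er"})
    grouped = dict(tuple(events.groupby("visit_occurrence_id"))) if not events.empty else {}

    def interior_activity(r):
        if concept_level:
            return dataset.resolve_concept(int(r.concept_id))
        return r.source_table.capitalize()

    for vid in visit_ids:
        row = sel.loc[vid]
        start, end = row["visit_start_datetime"], row["visit_end_datetime"]
        trace = Trace(case_id=str(vid))
        trace.attributes = {
            "los_hours": compute_los(start, end, "hours"),
            "admitting_source": _admitting_label(
                dataset, row["admitting_source_concept_id"]),
            "discharge_to": _discharge_label(
                dataset, row["discharge_to_concept_id"]),
            **_demographics(dataset, row["person_id"], start, pidx)}
        rows = grouped.get(vid, events.iloc[0:0])
        interior = _rows_to_events(dataset, rows, interior_activity)
        first = Event(event_id=f"{vid}_admit",
                      activity=trace.attributes["admitting_source"],
                      timestamp=start, source_table="visit_occurrence",
                      originator=_originator(row["provider_id"]))
        last = Event(event_id=f"{vid}_discharge",
                     activity=trace.attributes["discharge_to"],
                     timestamp=end, source_table="visit_occurrence",
                     originator=_originator(row["provider_id"]))
        trace.events = [first] + interior + [last]
        log.traces.append(trace)
    return log


def extract_patient_journey_log(dataset: CdmDataset, spec: LogSpec) -> EventLog:
    """Person-level journeys across all visit types.

    ``journey_level="visit"``: one event per visit with its visit-type label.
    ``journey_level="descendant"``: within-visit events labelled
    ``<Abbrev>_<k>_<TableLabel>`` where k is the per-type 1-based visit index;
    duplicate (label, calendar date) events collapse to the first occurrence;
    optional per-visit Start/End marker events.
    """
    assert spec.process_type == "patient_journey"
    person_ids = select_cohort(dataset, spec)
    visits = dataset.table("visit_occurrence")
    ws = spec.journey_window_start or spec.period_start
    we = spec.journey_window_end or spec.period_end
    windowed = visits[(visits["visit_start_datetime"] >= ws)
                      & (visits["visit_start_datetime"] < we)]
    pidx = _person_index(dataset)
    descendant = spec.journey_level == "descendant"
    events = (dataset.all_events(spec.scope) if descendant
              else dataset.events("condition_occurrence").iloc[0:0])
    grouped = (dict(tuple(events.groupby("visit_occurrence_id")))
               if descendant and not events.empty else {})
    log = EventLog(provenance={"process_type": "patient_journey",
                               "level": spec.journey_level})
    for person_id in person_ids:
        pv = windowed[windowed["person_id"] == person_id].sort_values(
            ["visit_start_datetime", "visit_occurrence_id"])
        if pv.empty:
            logger.warning("person %s has no visits in journey window",
                           person_id)
            continue
        trace = Trace(case_id=str(int(person_id)))
        first_start = pv["visit_start_datetime"].iloc[0]
        trace.attributes = {
            "n_visits": int(len(pv)),
            **_demographics(dataset, person_id, first_start, pidx)}
        type_counter: dict[str, int] = {}
        trace_events: list[Event] = []
        for row in pv.itertuples(index=False):
            vc = int(row.visit_concept_id)
            vid = int(row.visit_occurrence_id)
            label = spec.visit_type_labels.get(
                vc, dataset.resolve_concept(vc, "name"))
            abbrev = spec.visit_type_abbrev.get(vc, f"V{vc}")
            type_counter[abbrev] = type_counter.get(abbrev, 0) + 1
            k = type_counter[abbrev]
            if not descendant:
                trace_events.append(Event(
                    event_id=f"visit:{vid}", activity=label,
                    timestamp=row.visit_start_datetime,
                    originator=_originator(row.provider_id),
                    source_table="visit_occurrence", concept_id=vc,
                    attributes={"process_type": vc, "visit_index": k}))
                continue
            if spec.journey_markers:
                trace_events.append(Event(
                    event_id=f"visit:{vid}:start",
                    activity=f"{abbrev}_{k}_Start",
                    timestamp=row.visit_start_datetime,
                    source_table="visit_occurrence", concept_id=vc,
                    attributes={"marker": True, "visit_index": k}))
            rows = grouped.get(vid)
            if rows is not None:
                inner = _rows_to_events(
                    dataset, rows,
                    lambda r: f"{abbrev}_{k}_"
                              f"{JOURNEY_TABLE_LABELS[r.source_table]}")
                seen: set[tuple[str, object]] = set()
                for e in inner:
                    key = (e.activity, e.timestamp.normalize())
                    if key in seen:
                        continue  # same activity type on the same date
                    seen.add(key)
                    e.attributes["visit_index"] = k
                    trace_events.append(e)
            if spec.journey_markers:
                trace_events.append(Event(
                    event_id=f"visit:{vid}:end",
                    activity=f"{abbrev}_{k}_End",
                    timestamp=row.visit_end_datetime,
                    source_table="visit_occurrence", concept_id=vc,
                    attributes={"marker": True, "visit_index": k}))
        trace.events = trace_events
        log.traces.append(trace)
    return log


def extract_log(dataset: CdmDataset, spec: LogSpec) -> EventLog:
    """Dispatch to the per-process-type extractor."""
    extractor = {
        "inpatient": extract_inpatient_log,
        "outpatient": extract_outpatient_log,
        "er": extract_er_log,
        "patient_journey": extract_patient_journey_log,
    }[spec.process_type]
    return extractor(dataset, spec)
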
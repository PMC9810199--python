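"""Minimal OMOP CDM data model: table schemas, CSV I/O, validation, vocabulary.

The package works on a deliberately small slice of the CDM (v5.3+): the
tables needed to build process-mining event logs.  Visits live in
``visit_occurrence``; clinical activities come from eight event-bearing
tables (condition_occurrence, procedure_occurrence, drug_exposure,
measurement, device_exposure, observation, cost, note); demographics from
``person``; resources from ``provider`` / ``care_site``; and the vocabulary
from ``concept`` / ``concept_ancestor``.  Only the columns the extractors
need are mandatory — extra columns in a CDM dump pass through untouched.

Timestamps are timezone-naive at second resolution.  A row whose datetime
field carries only a calendar date (``2021-08-01``) is parsed to midnight
with ``date_only=True``; the flag is inferred from the source text, never
from a midnight time, and survives a write/load round trip.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: clinical event tables -> (row id column, concept column, datetime column)
CLINICAL_TABLES: dict[str, tuple[str, str, str]] = {
    "condition_occurrence": (
        "condition_occurrence_id", "condition_concept_id", "condition_start_datetime"),
    "procedure_occurrence": (
        "procedure_occurrence_id", "procedure_concept_id", "procedure_datetime"),
    "drug_exposure": (
        "drug_exposure_id", "drug_concept_id", "drug_exposure_start_datetime"),
    "measurement": ("measurement_id", "measurement_concept_id", "measurement_datetime"),
    "device_exposure": (
        "device_exposure_id", "device_concept_id", "device_exposure_start_datetime"),
    "observation": ("observation_id", "observation_concept_id", "observation_datetime"),
    # OMOP's cost table carries no datetime; a pragmatic cost_datetime column is
    # used so payment rows can act as events, mirroring the other tables.
    "cost": ("cost_id", "cost_concept_id", "cost_datetime"),
    "note": ("note_id", "note_class_concept_id", "note_datetime"),
}

#: deterministic tie-break rank for events sharing a timestamp
SOURCE_TABLE_RANK: dict[str, int] = {
    "condition_occurrence": 0,
    "procedure_occurrence": 1,
    "measurement": 2,
    "drug_exposure": 3,
    "device_exposure": 4,
    "observation": 5,
    "cost": 6,
    "note": 7,
}

MANDATORY_TABLES = ("person", "visit_occurrence", "concept")

#: per-table mandatory columns (extra columns are preserved verbatim)
TABLE_COLUMNS: dict[str, list[str]] = {
    "person": ["person_id", "gender_concept_id", "year_of_birth"],
    "visit_occurrence": [
        "visit_occurrence_id", "person_id", "visit_concept_id",
        "visit_start_datetime", "visit_end_datetime", "provider_id",
        "care_site_id", "admitting_source_concept_id", "discharge_to_concept_id"],
    "provider": ["provider_id", "provider_name"],
    "care_site": ["care_site_id", "care_site_name"],
    "concept": ["concept_id", "concept_name", "domain_id"],
    "concept_ancestor": ["ancestor_concept_id", "descendant_concept_id"],
}
for _t, (_id, _concept, _dt) in CLINICAL_TABLES.items():
    TABLE_COLUMNS[_t] = [_id, "person_id", "visit_occurrence_id", _concept, _dt,
                         "provider_id"]

ALL_TABLES = tuple(TABLE_COLUMNS)

_INT_COLUMNS = re.compile(r"(?<!domain)(_id|year_of_birth)$")
_DATE_ONLY = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_DT_COLUMNS = re.compile(r"(_datetime)$")


def _empty_table(name: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]})
    return _coerce_table(name, df)[0]


def _coerce_table(name: str, df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Coerce raw string columns to typed ones; return (frame, error messages).

    Rows with an unparseable datetime cell are dropped and reported.
    """
    errors: list[str] = []
    bad_rows: set[int] = set()
    df = df.copy()
    for col in df.columns:
        if _DT_COLUMNS.search(col):
            raw = df[col].astype("string").fillna("")
            date_only = raw.str.match(_DATE_ONLY).fillna(False)
            parsed = pd.to_datetime(raw.replace("", pd.NA), format="mixed",
                                    errors="coerce")
            bad = parsed.isna() & (raw != "")
            for idx in df.index[bad]:
                errors.append(f"{name}: unparseable {col} {raw[idx]!r} (row {idx})")
                bad_rows.add(idx)
            df[col] = parsed
            if name in CLINICAL_TABLES and col == CLINICAL_TABLES[name][2]:
                df["date_only"] = date_only.astype(bool)
        elif col == "date_only":
            df[col] = (df[col].astype("string").str.lower()
                       .isin(["true", "1"]) if df[col].dtype == object
                       else df[col].astype(bool))
        elif _INT_COLUMNS.search(col):
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        else:
            df[col] = df[col].astype("string").fillna("")
    if name in CLINICAL_TABLES and "date_only" not in df.columns:
        df["date_only"] = False
    if bad_rows:
        df = df.drop(index=sorted(bad_rows))
    return df.reset_index(drop=True), errors


@dataclass
class Violation:
    rule: str
    table: str
    row_id: object
    message: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_cdm`: empty iff the dataset is consistent."""

    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.violations:
            out[v.rule] = out.get(v.rule, 0) + 1
        return out

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.violations)


@dataclass
class CdmDataset:
    """In-memory OMOP CDM slice: one DataFrame per table plus the vocabulary."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    load_errors: list[str] = field(default_factory=list)

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLE_COLUMNS:
            raise KeyError(f"unknown CDM table {name!r}")
        if name not in self.tables:
            self.tables[name] = _empty_table(name)
        return self.tables[name]

    # -- vocabulary ---------------------------------------------------------
    def concept_name(self, concept_id: int) -> str | None:
        names = self._concept_index()
        return names.get(int(concept_id))

    def _concept_index(self) -> dict[int, str]:
        cached = getattr(self, "_concept_cache", None)
        concept = self.table("concept")
        if cached is None or cached[0] is not concept:
            index = dict(zip(concept["concept_id"].astype(int),
                             concept["concept_name"]))
            self._concept_cache = (concept, index)
        return self._concept_cache[1]

    def resolve_concept(self, concept_id: int, style: str = "id_name") -> str:
        """Render a concept id as ``name`` or ``"<id> (<name>)"``."""
        if style not in ("name", "id_name"):
            raise ValueError(f"unknown style {style!r}")
        name = self.concept_name(concept_id)
        if name is None:
            logger.warning("concept %s not in vocabulary", concept_id)
            name = "unknown"
        return name if style == "name" else f"{int(concept_id)} ({name})"

    def concept_descendants(self, ancestor_id: int) -> set[int]:
        """All descendant concept ids of ``ancestor_id`` (itself included)."""
        anc = self.table("concept_ancestor")
        hits = anc.loc[anc["ancestor_concept_id"] == int(ancestor_id),
                       "descendant_concept_id"]
        if hits.empty:
            logger.warning("concept %s absent from concept_ancestor", ancestor_id)
        return {int(ancestor_id)} | {int(d) for d in hits}

    # -- normalized event view ----------------------------------------------
    def events(self, source_table: str) -> pd.DataFrame:
        """Clinical rows of one table under canonical column names.

        Columns: source_table, event_row_id, person_id, visit_occurrence_id,
        concept_id, event_datetime, date_only, provider_id.
        """
        if source_table not in CLINICAL_TABLES:
            raise KeyError(f"{source_table!r} is not a clinical event table")
        id_col, concept_col, dt_col = CLINICAL_TABLES[source_table]
        df = self.table(source_table)
        out = pd.DataFrame({
            "source_table": source_table,
            "event_row_id": df[id_col],
            "person_id": df["person_id"],
            "visit_occurrence_id": df["visit_occurrence_id"],
            "concept_id": df[concept_col],
            "event_datetime": df[dt_col],
            "date_only": df["date_only"],
            "provider_id": df.get("provider_id", pd.Series(dtype="Int64")),
        })
        return out

    def all_events(self, source_tables=None) -> pd.DataFrame:
        tables = list(source_tables) if source_tables else list(CLINICAL_TABLES)
        frames = [self.events(t) for t in tables]
        frames = [f for f in frames if not f.empty]
        if not frames:
            return self.events("condition_occurrence").iloc[0:0]
        return pd.concat(frames, ignore_index=True)


def load_cdm(source: str | Path, table_names=None) -> CdmDataset:
    """Read per-table CSV files from a directory into a :class:`CdmDataset`.

    Missing optional tables become empty relations; a missing mandatory table
    (person, visit_occurrence, concept) raises ``FileNotFoundError``.
    Unparseable rows are skipped and recorded in ``dataset.load_errors``.
    """
    source = Path(source)
    names = list(table_names) if table_names else list(ALL_TABLES)
    tables: dict[str, pd.DataFrame] = {}
    errors: list[str] = []
    for name in names:
        path = source / f"{name}.csv"
        if not path.exists():
            if name in MANDATORY_TABLES:
                raise FileNotFoundError(f"mandatory CDM table missing: {path}")
            tables[name] = _empty_table(name)
            continue
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in TABLE_COLUMNS[name] if c not in raw.columns]
        if missing:
            raise ValueError(f"{path}: missing CDM columns {missing}")
        coerced, errs = _coerce_table(name, raw)
        tables[name] = coerced
        errors.extend(errs)
    return CdmDataset(tables=tables, load_errors=errors)


def _format_cell(value, date_only: bool = False) -> str:
    if value is None or value is pd.NaT or (isinstance(value, float) and np.isnan(value)):
        return ""
    if isinstance(value, pd.Timestamp):
        return value.strftime("%Y-%m-%d") if date_only else value.strftime(
            "%Y-%m-%d %H:%M:%S")
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if pd.isna(value):
        return ""
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return str(value)


def write_cdm(dataset: CdmDataset, target: str | Path) -> list[Path]:
    """Write one CSV per table; ``load_cdm(write_cdm(d)) == d``."""
    target = Path(target)
    target.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in ALL_TABLES:
        df = dataset.table(name)
        out = pd.DataFrame(index=df.index)
        dt_main = CLINICAL_TABLES[name][2] if name in CLINICAL_TABLES else None
        for col in df.columns:
            if _DT_COLUMNS.search(col):
                if col == dt_main:
                    flags = df["date_only"]
                    out[col] = [_format_cell(v, bool(f))
                                for v, f in zip(df[col], flags)]
                else:
                    out[col] = [_format_cell(v) for v in df[col]]
            elif col == "date_only":
                continue  # re-derived from the datetime text on load
            else:
                out[col] = [_format_cell(v) for v in df[col]]
        path = target / f"{name}.csv"
        out.to_csv(path, index=False)
        written.append(path)
    return written


def datasets_equal(a: CdmDataset, b: CdmDataset) -> bool:
    """Field-by-field equality over every table (used by round-trip tests)."""
    for name in ALL_TABLES:
        ta, tb = a.table(name), b.table(name)
        if list(ta.columns) != list(tb.columns) or len(ta) != len(tb):
            return False
        try:
            pd.testing.assert_frame_equal(ta, tb, check_dtype=False)
        except AssertionError:
            return False
    return True


def validate_cdm(dataset: CdmDataset) -> ValidationReport:
    """Check referential integrity and the visit/event window invariants.

    Rules reported: ``dangling_fk``, ``end_before_start``,
    ``event_within_visit``, ``unknown_visit_concept``, ``duplicate_id``.
    Findings are report entries, never exceptions.
    """
    rep = ValidationReport()
    visits = dataset.table("visit_occurrence")
    persons = set(dataset.table("person")["person_id"].dropna().astype(int))
    visit_ids = set(visits["visit_occurrence_id"].dropna().astype(int))
    concepts = set(dataset.table("concept")["concept_id"].dropna().astype(int))

    for name in ("person", "visit_occurrence") + tuple(CLINICAL_TABLES):
        df = dataset.table(name)
        id_col = TABLE_COLUMNS[name][0]
        dup = df[id_col][df[id_col].duplicated()]
        for rid in dup:
            rep.violations.append(Violation(
                "duplicate_id", name, rid, f"{id_col}={rid} occurs more than once"))

    bad_order = visits[visits["visit_end_datetime"] < visits["visit_start_datetime"]]
    for rid in bad_order["visit_occurrence_id"]:
        rep.violations.append(Violation(
            "end_before_start", "visit_occurrence", rid,
            f"visit {rid}: end precedes start"))
    for rid, pid in zip(visits["visit_occurrence_id"], visits["person_id"]):
        if pd.notna(pid) and int(pid) not in persons:
            rep.violations.append(Violation(
                "dangling_fk", "visit_occurrence", rid,
                f"visit {rid}: person_id {pid} not in person"))
    for rid, vc in zip(visits["visit_occurrence_id"], visits["visit_concept_id"]):
        if pd.notna(vc) and int(vc) not in concepts:
            rep.violations.append(Violation(
                "unknown_visit_concept", "visit_occurrence", rid,
                f"visit {rid}: visit_concept_id {vc} not in vocabulary"))

    vstart = dict(zip(visits["visit_occurrence_id"].astype(int),
                      visits["visit_start_datetime"]))
    vend = dict(zip(visits["visit_occurrence_id"].astype(int),
                    visits["visit_end_datetime"]))
    for name in CLINICAL_TABLES:
        ev = dataset.events(name)
        for rid, vid, pid, when in zip(ev["event_row_id"], ev["visit_occurrence_id"],
                                       ev["person_id"], ev["event_datetime"]):
            if pd.notna(pid) and int(pid) not in persons:
                rep.violations.append(Violation(
                    "dangling_fk", name, rid, f"person_id {pid} not in person"))
            if pd.isna(vid) or int(vid) not in visit_ids:
                rep.violations.append(Violation(
                    "dangling_fk", name, rid,
                    f"visit_occurrence_id {vid} not in visit_occurrence"))
                continue
            lo, hi = vstart[int(vid)], vend[int(vid)]
            if pd.notna(when) and not (
                    lo.normalize() <= when.normalize() <= hi.normalize()):
                rep.violations.append(Violation(
                    "event_within_visit", name, rid,
                    f"event date {when.date()} outside visit window "
                    f"[{lo.date()}, {hi.date()}]"))
    return rep


def resolve_concept(dataset: CdmDataset, concept_id: int,
                    style: str = "id_name") -> str:
    return dataset.resolve_concept(concept_id, style)


def concept_descendants(dataset: CdmDataset, ancestor_id: int) -> set[int]:
    return dataset.concept_descendants(ancestor_id)
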
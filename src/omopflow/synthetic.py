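"""Synthetic OMOP CDM generator with planted ground truth.

Real hospital CDM extracts are private; this module fabricates datasets whose
statistical structure is known exactly, so every downstream stage (extraction,
clinical-pathway mining, discovery) can be tested for recovery of the planted
signal:

* inpatient cohorts anchored on a surgery procedure, with a planted clinical
  pathway — (relative day, concept) entries applied per case with a stated
  occurrence probability — plus day-independent Bernoulli noise orders;
* outpatient visits whose events come from six source tables, with a
  configurable fraction of date-only timestamps on condition/drug/cost rows;
* emergency-room visits with admitting-source and discharge-destination
  concepts drawn from stated distributions and an hour-scale length of stay;
* multi-year patient journeys: each patient's visit sequence is a realization
  of a visit-type Markov chain over {Outpatient, Inpatient, ER, Checkup}.

Every generator is deterministic given the config seed; per-patient
sub-streams are derived from (seed, stream id, patient index) so a patient's
data does not depend on how many patients are generated after it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .cdm import CLINICAL_TABLES, TABLE_COLUMNS, CdmDataset

# Concept ids with fixed names: OMOP visit/gender/ER-source concepts the
# extractors special-case, plus a handful of real drug/lab concepts so
# synthetic pathways read like clinical order sheets.
KNOWN_CONCEPT_NAMES: dict[int, tuple[str, str]] = {
    9201: ("Inpatient visit", "Visit"),
    9202: ("Outpatient visit", "Visit"),
    9203: ("Emergency Room visit", "Visit"),
    262: ("Emergency Room and Inpatient Visit", "Visit"),
    32036: ("Laboratory visit", "Visit"),
    8532: ("Female", "Gender"),
    8507: ("Male", "Gender"),
    8536: ("Visit from home", "Visit"),
    44790567: ("Patient transfer from hospital to hospital", "Visit"),
    8716: ("Visit from independent clinic", "Visit"),
    8717: ("Visit from inpatient facility", "Visit"),
    8756: ("Visit from outpatient clinic", "Visit"),
    40318361: ("Patient registration", "Observation"),
    1154186: ("fentanyl 0.1 MG", "Drug"),
    19086213: ("midazolam 5 MG/ML", "Drug"),
    35605373: ("remifentanil 1 MG", "Drug"),
    925043: ("bisacodyl 5 MG", "Drug"),
    939871: ("sodium phosphate", "Drug"),
    35605994: ("cefotetan 1000 MG", "Drug"),
    42918203: ("lactated Ringer solution 1000 ML", "Drug"),
    717165: ("neostigmine methylsulfate 0.5 MG/ML Injectable Solution", "Drug"),
    963353: ("glycopyrrolate", "Drug"),
    19077241: ("famotidine 20 MG Oral Tablet", "Drug"),
    35603429: ("fentanyl 0.05 MG/ML Injection", "Drug"),
    42921670: ("3 ML Midazolam 1 MG/ML Injectable Solution", "Drug"),
    36249738: ("1000 ML glucose 50 MG/ML Injection", "Drug"),
    42922137: ("2 ML Acetylcysteine 150 MG/ML Injectable Solution", "Drug"),
    19086516: ("aceclofenac 100 MG", "Drug"),
    3000666: ("Metamyelocytes/100 leukocytes in Blood by Manual count",
              "Measurement"),
    3007591: ("Band form neutrophils/100 leukocytes in Blood by Manual count",
              "Measurement"),
    3009261: ("Glucose [Presence] in Urine by Test strip", "Measurement"),
    3011587: ("Promyelocytes/100 leukocytes in Blood by Manual count",
              "Measurement"),
    3018229: ("Myelocytes/100 leukocytes in Blood by Manual count",
              "Measurement"),
    3012608: ("segmented neutrophils/100 leukocytes in blood by automated count",
              "Measurement"),
    3013869: ("basophils/100 leukocytes in blood by automated count",
              "Measurement"),
}

JOURNEY_STATES = ("Outpatient", "Inpatient", "ER", "Checkup")
STATE_VISIT_CONCEPT = {"Outpatient": 9202, "Inpatient": 9201, "ER": 9203,
                       "Checkup": 32036}

_WORK_START_H, _WORK_END_H = 8, 18


class PlantedEntry(BaseModel):
    """One clinical-pathway entry: an order planted on a fixed relative day."""

    relative_day: int
    concept_id: int
    source_table: str
    probability: float = Field(ge=0.0, le=1.0)

    @field_validator("source_table")
    @classmethod
    def _known_table(cls, v: str) -> str:
        if v not in CLINICAL_TABLES:
            raise ValueError(f"unknown clinical table {v!r}")
        return v


class NoiseOrder(BaseModel):
    """A day-independent Bernoulli noise order (per hospitalization day)."""

    concept_id: int
    source_table: str
    probability: float = Field(ge=0.0, le=1.0)

    @field_validator("source_table")
    @classmethod
    def _known_table(cls, v: str) -> str:
        if v not in CLINICAL_TABLES:
            raise ValueError(f"unknown clinical table {v!r}")
        return v


def default_planted_cp() -> list[PlantedEntry]:
    """A 20-entry pathway over days −1…+2, occurrence probabilities 0.85–1.0."""
    plan = [
        (-1, [925043, 939871, 35605994, 42918203], "drug_exposure"),
        (0, [717165, 963353, 19077241, 35603429, 35605373, 42921670],
         "drug_exposure"),
        (1, [19077241, 36249738, 42922137, 35605994], "drug_exposure"),
        (1, [3000666, 3007591, 3009261, 3011587, 3018229], "measurement"),
        (2, [19086516], "drug_exposure"),
    ]
    probs = np.linspace(1.0, 0.85, 20)
    out, k = [], 0
    for day, concepts, table in plan:
        for c in concepts:
            out.append(PlantedEntry(relative_day=day, concept_id=c,
                                    source_table=table,
                                    probability=round(float(probs[k]), 4)))
            k += 1
    return out


def default_noise_orders(n: int = 200) -> list[NoiseOrder]:
    """``n`` noise orders, per-day probabilities spread over 0.01–0.15."""
    tables = ["drug_exposure", "measurement", "observation"]
    probs = np.linspace(0.01, 0.15, n)
    return [NoiseOrder(concept_id=2_000_001 + i, source_table=tables[i % 3],
                       probability=round(float(probs[i]), 4))
            for i in range(n)]


class MarkovChain(BaseModel):
    """Initial distribution and row-stochastic transition matrix over
    visit-type states; every row may also transition to the absorbing "End"."""

    initial: dict[str, float] = Field(
        default_factory=lambda: {"Outpatient": 0.8, "ER": 0.15, "Checkup": 0.05})
    transitions: dict[str, dict[str, float]] = Field(default_factory=lambda: {
        "Outpatient": {"Outpatient": 0.45, "Inpatient": 0.25, "ER": 0.05,
                       "Checkup": 0.05, "End": 0.20},
        "Inpatient": {"Outpatient": 0.70, "ER": 0.05, "Checkup": 0.05,
                      "Inpatient": 0.05, "End": 0.15},
        "ER": {"Outpatient": 0.40, "Inpatient": 0.30, "End": 0.30},
        "Checkup": {"Outpatient": 0.50, "Checkup": 0.10, "End": 0.40},
    })

    @model_validator(mode="after")
    def _stochastic(self) -> "MarkovChain":
        for label, dist in [("initial", self.initial),
                            *self.transitions.items()]:
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"distribution {label!r} sums to {total}, not 1")
            for state in dist:
                if state not in JOURNEY_STATES + ("End",):
                    raise ValueError(f"unknown journey state {state!r}")
        return self


class SyntheticConfig(BaseModel):
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 0
    n_patients: int = Field(default=100, ge=1)
    study_start: dt.date = dt.date(2018, 1, 1)
    study_end: dt.date = dt.date(2021, 12, 31)
    surgery_concept_id: int = 4336464
    planted_cp: list[PlantedEntry] = Field(default_factory=default_planted_cp)
    noise_orders: list[NoiseOrder] = Field(default_factory=default_noise_orders)
    #: LOS in calendar days -> probability (inpatient)
    los_distribution: dict[int, float] = Field(
        default_factory=lambda: {4: 0.25, 5: 0.40, 6: 0.25, 7: 0.10})
    visit_type_chain: MarkovChain = Field(default_factory=MarkovChain)
    visits_per_patient_cap: int = Field(default=30, ge=1)
    er_source_distribution: dict[int, float] = Field(default_factory=lambda: {
        8536: 0.70, 44790567: 0.10, 8716: 0.05, 8717: 0.05, 8756: 0.10})
    er_discharge_distribution: dict[int, float] = Field(default_factory=lambda: {
        8536: 0.85, 44790567: 0.10, 8717: 0.05})
    er_los_mean_hours: float = 5.94
    er_los_sd_hours: float = 7.6
    er_event_means: dict[str, float] = Field(default_factory=lambda: {
        "measurement": 3.0, "drug_exposure": 1.5, "observation": 1.0,
        "note": 0.5})
    outpatient_event_means: dict[str, float] = Field(default_factory=lambda: {
        "condition_occurrence": 1.2, "observation": 0.4, "drug_exposure": 1.5,
        "procedure_occurrence": 1.8, "measurement": 0.7, "cost": 1.0})
    outpatient_visits_per_patient: int = Field(default=3, ge=1)
    date_only_fraction: dict[str, float] = Field(default_factory=lambda: {
        "condition_occurrence": 0.3, "drug_exposure": 0.3, "cost": 0.5})
    extra_ancestor_pairs: list[tuple[int, int]] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if self.study_start >= self.study_end:
            raise ValueError("study_period start must precede end")
        if abs(sum(self.los_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("los_distribution must sum to 1")
        if min(self.los_distribution) < 1:
            raise ValueError("LOS support must be >= 1 day")
        for name in ("er_source_distribution", "er_discharge_distribution"):
            dist = getattr(self, name)
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for frac in self.date_only_fraction.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("date_only_fraction values must be in [0,1]")
        if self.planted_cp:
            pre = max(1, -min(e.relative_day for e in self.planted_cp))
            post = max(1, max(e.relative_day for e in self.planted_cp))
            if min(self.los_distribution) < pre + post:
                raise ValueError(
                    f"planted days need {pre} pre-op and {post} post-op days "
                    f"but the minimum LOS is {min(self.los_distribution)}")
        return self


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the dataset for recovery tests."""

    planted_cp: list[PlantedEntry] = field(default_factory=list)
    noise_orders: list[NoiseOrder] = field(default_factory=list)
    anchors: dict[int, dt.date] = field(default_factory=dict)  # visit -> op day
    visit_sequences: dict[int, list[str]] = field(default_factory=dict)
    transition_matrix: dict[str, dict[str, float]] | None = None
    initial_distribution: dict[str, float] | None = None

    def to_json(self) -> dict:
        return {
            "planted_cp": [e.model_dump() for e in self.planted_cp],
            "noise_orders": [e.model_dump() for e in self.noise_orders],
            "anchors": {str(k): v.isoformat() for k, v in self.anchors.items()},
            "visit_sequences": {str(k): v
                                for k, v in self.visit_sequences.items()},
            "transition_matrix": self.transition_matrix,
            "initial_distribution": self.initial_distribution,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruth":
        return cls(
            planted_cp=[PlantedEntry(**e) for e in obj.get("planted_cp", [])],
            noise_orders=[NoiseOrder(**e) for e in obj.get("noise_orders", [])],
            anchors={int(k): dt.date.fromisoformat(v)
                     for k, v in obj.get("anchors", {}).items()},
            visit_sequences={int(k): v
                             for k, v in obj.get("visit_sequences", {}).items()},
            transition_matrix=obj.get("transition_matrix"),
            initial_distribution=obj.get("initial_distribution"),
        )


# ---------------------------------------------------------------------------
# assembly helpers

class DatasetBuilder:
    """Accumulates typed rows per CDM table and finalizes a CdmDataset."""

    def __init__(self, config: SyntheticConfig | None = None):
        config = config or SyntheticConfig()
        self.config = config
        self.rows: dict[str, list[dict]] = {t: [] for t in TABLE_COLUMNS}
        self.counters: dict[str, int] = {t: 0 for t in CLINICAL_TABLES}
        self.counters["visit_occurrence"] = 0
        self._concepts: set[int] = set()

    def next_id(self, table: str) -> int:
        self.counters[table] += 1
        return self.counters[table]

    def use_concept(self, concept_id: int) -> int:
        self._concepts.add(int(concept_id))
        return int(concept_id)

    def add_person(self, person_id: int, gender: int, year_of_birth: int):
        self.rows["person"].append({
            "person_id": person_id,
            "gender_concept_id": self.use_concept(gender),
            "year_of_birth": year_of_birth})

    def add_visit(self, person_id: int, visit_concept: int,
                  start: dt.datetime, end: dt.datetime,
                  provider_id=None, care_site_id=None,
                  admitting=None, discharge=None) -> int:
        vid = self.next_id("visit_occurrence")
        self.rows["visit_occurrence"].append({
            "visit_occurrence_id": vid, "person_id": person_id,
            "visit_concept_id": self.use_concept(visit_concept),
            "visit_start_datetime": pd.Timestamp(start).floor("s"),
            "visit_end_datetime": pd.Timestamp(end).floor("s"),
            "provider_id": provider_id, "care_site_id": care_site_id,
            "admitting_source_concept_id":
                self.use_concept(admitting) if admitting else None,
            "discharge_to_concept_id":
                self.use_concept(discharge) if discharge else None})
        return vid

    def add_event(self, table: str, person_id: int, visit_id: int,
                  concept_id: int, when: dt.datetime, provider_id=None,
                  date_only: bool = False) -> int:
        id_col, concept_col, dt_col = CLINICAL_TABLES[table]
        rid = self.next_id(table)
        when = pd.Timestamp(when).floor("s")
        if date_only:
            when = when.normalize()
        self.rows[table].append({
            id_col: rid, "person_id": person_id, "visit_occurrence_id": visit_id,
            concept_col: self.use_concept(concept_id), dt_col: when,
            "provider_id": provider_id, "date_only": bool(date_only)})
        return rid

    def finalize(self) -> CdmDataset:
        for pid in range(1, 11):
            self.rows["provider"].append(
                {"provider_id": pid, "provider_name": f"Provider {pid:02d}"})
        for cid in range(1, 4):
            self.rows["care_site"].append(
                {"care_site_id": cid, "care_site_name": f"Care site {cid}"})
        for concept_id in sorted(self._concepts):
            name, domain = KNOWN_CONCEPT_NAMES.get(
                concept_id, (f"synthetic order {concept_id}", "Other"))
            self.rows["concept"].append({"concept_id": concept_id,
                                         "concept_name": name,
                                         "domain_id": domain})
            self.rows["concept_ancestor"].append(
                {"ancestor_concept_id": concept_id,
                 "descendant_concept_id": concept_id})
        for anc, desc in self.config.extra_ancestor_pairs:
            self.rows["concept_ancestor"].append(
                {"ancestor_concept_id": int(anc),
                 "descendant_concept_id": int(desc)})
        tables = {}
        for name, rows in self.rows.items():
            cols = list(TABLE_COLUMNS[name])
            if name in CLINICAL_TABLES:
                cols.append("date_only")
            df = pd.DataFrame(rows, columns=cols)
            for col in cols:
                if col == "date_only":
                    df[col] = df[col].fillna(False).astype(bool)
                elif col != "domain_id" and col.endswith(("_id",
                                                          "year_of_birth")):
                    df[col] = pd.array(df[col], dtype="Int64")
                elif col.endswith("_datetime"):
                    df[col] = pd.to_datetime(df[col])
                else:
                    df[col] = df[col].astype("string").fillna("")
            tables[name] = df
        return CdmDataset(tables=tables)


def _rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, index]))


def _sample_discrete(rng: np.random.Generator, dist: dict) -> object:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _work_time(rng: np.random.Generator, day: dt.date) -> dt.datetime:
    """A second-resolution time uniform over working hours 08:00-18:00."""
    sec = int(rng.integers(0, (_WORK_END_H - _WORK_START_H) * 3600))
    return dt.datetime.combine(day, dt.time(_WORK_START_H)) + dt.timedelta(
        seconds=sec)


def _birth_and_gender(rng: np.random.Generator) -> tuple[int, int]:
    gender = 8532 if rng.random() < 0.6 else 8507
    return int(rng.integers(1940, 1996)), gender


# ---------------------------------------------------------------------------
# generators

def generate_inpatient_cohort(
        config: SyntheticConfig) -> tuple[CdmDataset, GroundTruth]:
    """One inpatient (9201) visit per patient with a planted pathway.

    Each visit contains exactly one surgery event whose date anchors relative
    day 0.  The anchor is placed so every planted relative day fits inside the
    visit window; each planted (day, concept) entry is then applied with its
    stated probability, and noise orders are sprinkled as independent per-day
    Bernoulli draws.
    """
    builder = DatasetBuilder(config)
    truth = GroundTruth(planted_cp=list(config.planted_cp),
                        noise_orders=list(config.noise_orders))
    pre = max(1, -min((e.relative_day for e in config.planted_cp), default=-1))
    post = max(1, max((e.relative_day for e in config.planted_cp), default=1))
    span_days = (config.study_end - config.study_start).days
    max_los = max(config.los_distribution)
    noise_p = np.array([n.probability for n in config.noise_orders])

    for i in range(config.n_patients):
        rng = _rng(config.seed, 1, i)
        person_id = i + 1
        year_of_birth, gender = _birth_and_gender(rng)
        builder.add_person(person_id, gender, year_of_birth)

        los = int(_sample_discrete(rng, config.los_distribution))
        start_day = config.study_start + dt.timedelta(
            days=int(rng.integers(0, max(1, span_days - max_los))))
        start = _work_time(rng, start_day)
        end = _work_time(rng, start_day + dt.timedelta(days=los))
        provider = int(rng.integers(1, 11))
        vid = builder.add_visit(person_id, 9201, start, end,
                                provider_id=provider,
                                care_site_id=int(rng.integers(1, 4)),
                                admitting=8536, discharge=8536)

        anchor_offset = int(rng.integers(pre, los - post + 1))
        anchor_day = start_day + dt.timedelta(days=anchor_offset)
        truth.anchors[vid] = anchor_day
        builder.add_event("procedure_occurrence", person_id, vid,
                          config.surgery_concept_id,
                          _work_time(rng, anchor_day), provider_id=provider)

        for entry in config.planted_cp:
            if rng.random() < entry.probability:
                day = anchor_day + dt.timedelta(days=entry.relative_day)
                builder.add_event(entry.source_table, person_id, vid,
                                  entry.concept_id, _work_time(rng, day),
                                  provider_id=int(rng.integers(1, 11)))
        if len(noise_p):
            hits = rng.random((los + 1, len(noise_p))) < noise_p
            for day_off, order_idx in zip(*np.nonzero(hits)):
                order = config.noise_orders[int(order_idx)]
                day = start_day + dt.timedelta(days=int(day_off))
                builder.add_event(order.source_table, person_id, vid,
                                  order.concept_id, _work_time(rng, day),
                                  provider_id=int(rng.integers(1, 11)))
    return builder.finalize(), truth


def generate_outpatient_visits(
        config: SyntheticConfig) -> tuple[CdmDataset, GroundTruth]:
    """Outpatient (9202) single-day visits with events from six source tables.

    Per-table event counts are Poisson with the configured means (every visit
    gets at least one condition row so no case is empty); a configured
    fraction of condition/drug/cost rows carries date-only timestamps.
    """
    builder = DatasetBuilder(config)
    truth = GroundTruth()
    span_days = (config.study_end - config.study_start).days
    tables = sorted(config.outpatient_event_means)
    concept_pool = {
        "condition_occurrence": [3_100_001, 3_100_002, 3_100_003],
        "observation": [40318361, 3_200_001],
        "drug_exposure": [1154186, 19086213, 19077241],
        "procedure_occurrence": [3_300_001, 3_300_002],
        "measurement": [3012608, 3013869],
        "cost": [3_400_001],
    }
    for i in range(config.n_patients):
        rng = _rng(config.seed, 2, i)
        person_id = i + 1
        year_of_birth, gender = _birth_and_gender(rng)
        builder.add_person(person_id, gender, year_of_birth)
        n_visits = config.outpatient_visits_per_patient
        day_offsets = np.sort(rng.choice(span_days, size=n_visits,
                                         replace=False))
        for day_off in day_offsets:
            day = config.study_start + dt.timedelta(days=int(day_off))
            start = dt.datetime.combine(day, dt.time(9, 0))
            end = dt.datetime.combine(day, dt.time(17, 0))
            vid = builder.add_visit(person_id, 9202, start, end,
                                    provider_id=int(rng.integers(1, 11)),
                                    care_site_id=int(rng.integers(1, 4)))
            cursor = start + dt.timedelta(minutes=int(rng.integers(5, 60)))
            for table in tables:
                count = int(rng.poisson(config.outpatient_event_means[table]))
                if table == "condition_occurrence":
                    count = max(1, count)
                for _ in range(count):
                    concepts = concept_pool[table]
                    concept = concepts[int(rng.integers(0, len(concepts)))]
                    date_only = (rng.random()
                                 < config.date_only_fraction.get(table, 0.0))
                    builder.add_event(table, person_id, vid, concept, cursor,
                                      provider_id=int(rng.integers(1, 11)),
                                      date_only=date_only)
                    cursor += dt.timedelta(minutes=int(rng.integers(3, 25)))
    return builder.finalize(), truth


def generate_er_visits(
        config: SyntheticConfig) -> tuple[CdmDataset, GroundTruth]:
    """ER (9203) visits with admitting-source / discharge-destination mixes.

    LOS in hours follows a gamma distribution matched to the configured
    mean/SD (floored at 15 minutes); in-visit events come from measurement,
    drug_exposure, observation and note tables.
    """
    for dist in (config.er_source_distribution,
                 config.er_discharge_distribution):
        unknown = set(dist) - set(KNOWN_CONCEPT_NAMES)
        if unknown:
            raise ValueError(f"ER distribution over unknown concept ids "
                             f"{sorted(unknown)}")
    builder = DatasetBuilder(config)
    truth = GroundTruth()
    span_days = (config.study_end - config.study_start).days
    mean, sd = config.er_los_mean_hours, config.er_los_sd_hours
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    pool = {"measurement": [3012608, 3013869], "drug_exposure": [1154186],
            "observation": [3_200_001], "note": [3_500_001]}
    for i in range(config.n_patients):
        rng = _rng(config.seed, 3, i)
        person_id = i + 1
        year_of_birth, gender = _birth_and_gender(rng)
        builder.add_person(person_id, gender, year_of_birth)
        day = config.study_start + dt.timedelta(
            days=int(rng.integers(0, span_days)))
        start = dt.datetime.combine(day, dt.time(0)) + dt.timedelta(
            seconds=int(rng.integers(0, 86400)))
        los_h = max(0.25, float(rng.gamma(shape, scale)))
        end = start + dt.timedelta(hours=los_h)
        source = int(_sample_discrete(rng, config.er_source_distribution))
        discharge = int(_sample_discrete(rng, config.er_discharge_distribution))
        vid = builder.add_visit(person_id, 9203, start, end,
                                provider_id=int(rng.integers(1, 11)),
                                care_site_id=int(rng.integers(1, 4)),
                                admitting=source, discharge=discharge)
        span_s = max(1, int((end - start).total_seconds()) - 1)
        for table in sorted(config.er_event_means):
            for _ in range(int(rng.poisson(config.er_event_means[table]))):
                when = start + dt.timedelta(seconds=int(rng.integers(1, span_s + 1)))
                concepts = pool[table]
                builder.add_event(table, person_id, vid,
                                  concepts[int(rng.integers(0, len(concepts)))],
                                  when, provider_id=int(rng.integers(1, 11)))
    return builder.finalize(), truth


def generate_patient_journeys(
        config: SyntheticConfig) -> tuple[CdmDataset, GroundTruth]:
    """Per-patient visit sequences realized from the visit-type Markov chain.

    Visits are materialized with type-appropriate events and strictly
    increasing, non-overlapping windows; the true state sequence and the
    chain parameters are returned as ground truth.
    """
    if config.visits_per_patient_cap < 1:
        raise ValueError("visits_per_patient_cap must be >= 1")
    chain = config.visit_type_chain
    builder = DatasetBuilder(config)
    truth = GroundTruth(
        transition_matrix={s: dict(d) for s, d in chain.transitions.items()},
        initial_distribution=dict(chain.initial))
    event_plan = {
        "Outpatient": [("condition_occurrence", 3_100_001),
                       ("drug_exposure", 19077241), ("cost", 3_400_001)],
        "Inpatient": [("procedure_occurrence", None),  # surgery anchor
                      ("drug_exposure", 35605373), ("measurement", 3012608)],
        "ER": [("measurement", 3013869), ("observation", 3_200_001)],
        "Checkup": [("measurement", 3012608),
                    ("procedure_occurrence", 3_300_001)],
    }
    for i in range(config.n_patients):
        rng = _rng(config.seed, 4, i)
        person_id = i + 1
        year_of_birth, gender = _birth_and_gender(rng)
        builder.add_person(person_id, gender, year_of_birth)
        seq: list[str] = []
        state = str(_sample_discrete(rng, chain.initial))
        cursor = dt.datetime.combine(
            config.study_start + dt.timedelta(days=int(rng.integers(0, 90))),
            dt.time(9, 0))
        while state != "End" and len(seq) < config.visits_per_patient_cap:
            seq.append(state)
            visit_concept = STATE_VISIT_CONCEPT[state]
            if state == "Inpatient":
                los = int(rng.integers(3, 8))
                start = cursor
                end = start + dt.timedelta(days=los, hours=2)
                anchor_day = (start + dt.timedelta(days=1)).date()
            else:
                start = cursor
                end = start + dt.timedelta(hours=float(rng.uniform(1, 8)))
                anchor_day = start.date()
            admitting = 8536 if state == "ER" else None
            discharge = 8536 if state == "ER" else None
            vid = builder.add_visit(person_id, visit_concept, start, end,
                                    provider_id=int(rng.integers(1, 11)),
                                    care_site_id=int(rng.integers(1, 4)),
                                    admitting=admitting, discharge=discharge)
            if state == "Inpatient":
                truth.anchors[vid] = anchor_day
            for table, concept in event_plan[state]:
                if concept is None:
                    concept = config.surgery_concept_id
                when = min(end, max(start, dt.datetime.combine(
                    anchor_day, dt.time(10, 0))) + dt.timedelta(
                        minutes=int(rng.integers(0, 240))))
                builder.add_event(table, person_id, vid, concept, when,
                                  provider_id=int(rng.integers(1, 11)))
            cursor = end + dt.timedelta(days=int(rng.integers(3, 61)),
                                        hours=1)
            state = str(_sample_discrete(rng, chain.transitions[state]))
        truth.visit_sequences[person_id] = seq
    return builder.finalize(), truth
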
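# Methods

## Scope and data model

`omopflow` works on a minimal slice of the OMOP CDM (v5.3+): the tables
needed to build process-mining event logs. Visits live in
`visit_occurrence`; clinical activities come from eight event-bearing
tables (condition_occurrence, procedure_occurrence, drug_exposure,
measurement, device_exposure, observation, cost, note); demographics from
`person`; resources from `provider`/`care_site`; the vocabulary from
`concept`/`concept_ancestor`. Only the columns the extractors need are
mandatory; extra columns in a real CDM dump pass through untouched. Full
OMOP DDL fidelity, vocabulary downloads and EHR→CDM ETL are out of scope.

Two pragmatic schema choices: the OMOP cost table carries no datetime
column, but payment rows are used as timestamped events, so the package
adopts a `cost_datetime` column mirroring the other clinical tables; the
note table uses `note_class_concept_id` as its concept column. Both are
documented here rather than hidden.

Timestamps are timezone-naive at second resolution. A row whose datetime
field carries only a calendar date parses to midnight with
`date_only=True`; the flag is inferred from the source text, never from a
midnight time (midnight can be a real time), and survives write/load round
trips because date-only rows are re-serialized as bare dates.

## Event-log extraction

A `LogSpec` names the process type, a half-open extraction period (visit
membership by `visit_start_datetime`), a scope of source tables, an
optional cohort criterion (visits containing at least one event of the
given concepts, OR-ed, optionally expanded through `concept_ancestor`),
and optional features. Visit type codes: inpatient 9201, outpatient 9202,
ER 9203; code 262 ("ER and inpatient") is included in both inpatient and
ER extraction by default and can be toggled off per spec.

Events tied on timestamp are ordered by a fixed source-table rank
(condition < procedure < measurement < drug < device < observation < cost
< note), then row id — a deterministic stand-in for an ordering the data
does not record.

Per process type:

* **Inpatient** — case per visit, activity = `"<concept_id> (<name>)"`,
  originator = provider id; case attributes LOS in calendar days
  (`end date − start date`), sex (concept rendering), age = visit start
  year − birth year (the minimal person type has no birth month, matching
  the integer ages such logs usually print).
* **Outpatient** — activities are table-level labels
  (condition/visit → Consultation, measurement → Physical examination &
  Lab test, drug → Drug, procedure → Surgery & Radiology test,
  cost → Payment, observation → Survey), since CDMs rarely carry
  fine-grained administrative events; the department feature is taken from
  the visit's care site.
* **ER** — the admitting source concept becomes the first activity at
  visit start and the discharge destination the last at visit end. The
  vocabulary names admission sources "Visit from X"; the discharge label is
  derived by rewriting that prefix, so concept 8536 renders as
  `8536 (Visit from home)` at admission and `8536 (Discharge to home)` at
  discharge. Missing concepts produce "unknown source"/"unknown
  destination" placeholders with warnings. LOS is exact hours rounded to
  two decimals.
* **Patient journey** — case per person; at visit level one event per
  visit labelled by visit type (9201 Inpatient visit, 9202 Outpatient
  visit, 9203 Emergency room visit, 32036 Laboratory visit; extra ids
  configurable). At descendant level, within-visit events are labelled
  `<Abbrev>_<k>_<TableLabel>` with k the 1-based per-type visit index;
  duplicates of the same label on the same calendar date collapse to the
  first occurrence, and optional `<Abbrev>_<k>_Start/_End` markers wrap
  each visit. A hospitalization is a single visit record and so counts
  once.

### Date-only timestamp repair

Within each case and calendar day, date-only events are re-timestamped
after the day's last timed event (09:00 if none), sequenced in the table
order condition > drug > cost; with K events to repair, the k-th follows
its predecessor by `5 + 25·(k−1)/max(1, K−1)` minutes, spreading successive
gaps deterministically across the 5–30 minute band. A random draw from that
band would also be defensible; the linear spread is chosen so repaired logs
are reproducible byte for byte. Timed events are never moved. A date-only
event from a table missing from the order is an error, not a guess.

## Clinical-pathway mining

Case profiles hold the *distinct* entries `(relative day, concept, source
table)` within a day window (default −1…+2) around the anchor — the
earliest occurrence of the anchor (operation) concept in the case; the
anchor event itself is excluded, and multiplicities are kept only for
reporting, so repeated same-day administrations do not inflate the
metrics. Matching is day-aware: an order matches only on its pathway day.

Metrics (all computed on presence):

* application rate: mean over pathway entries of per-entry case coverage;
* matched ratio: mean over cases of `|profile ∩ CP| / |profile|`
  (empty profiles are excluded with a warning);
* matching rate: their sum. The additive identity is exercised by a
  property test over random instances; an empty pathway scores 0.

Greedy selection appends the candidate with the highest application rate
(ties: smaller concept id, then smaller relative day — determinism where
the method itself is silent); an alternative `matching_gain` criterion that
re-evaluates the marginal matching-rate gain each step is exposed for
sensitivity analysis. The curve is computed to `k_max` (default: all
candidates, capped at 500) and the optimum is the smallest k attaining the
maximal matching rate. Along the default greedy sequence the application
rate is non-increasing and the matched ratio non-decreasing — also property
tested. `exhaustive_cp_search` enumerates all size-k subsets (guarded by a
combination cap, default 10⁶) as an independent oracle; no support
pre-filter is applied before selection.

## Synthetic data generator

The generator emulates the statistical skeleton of surgical-cohort CDM
extracts, not medical plausibility: order co-occurrence, billing semantics
and multi-hospital structure are deliberately absent, so passing recovery
tests demonstrates correctness of the machinery, not fitness of any
clinical conclusion.

* **Inpatient** — one 9201 visit per patient; LOS drawn from a discrete
  distribution (default {4: 0.25, 5: 0.40, 6: 0.25, 7: 0.10} days); the
  single surgery event is placed uniformly among the days that leave room
  for every planted relative day (at least one pre-op and one post-op
  day), so planted occurrence probabilities are exact per case; a config
  whose minimum LOS cannot host the planted window is rejected. The
  default planted pathway has 20 entries over days −1…+2 with
  probabilities evenly spread over 0.85–1.0; the default noise set has 200
  day-independent Bernoulli orders with per-day probabilities 0.01–0.15.
  These defaults are the regime where pathway structure exists but is
  buried in noise — the condition the recovery tests probe.
* **Outpatient** — single-day 9202 visits (3 per patient by default);
  per-table Poisson event counts (condition floored at one so no case is
  empty); a per-table fraction of condition/drug/cost rows degraded to
  date-only (defaults 0.3/0.3/0.5).
* **ER** — 9203 visits; admission sources over the concept set
  {8536, 44790567, 8716, 8717, 8756} (default 70% from home); LOS in
  hours from a gamma distribution matched to mean 5.94 h and SD 7.6 h —
  the scale of a busy ER — floored at 15 minutes.
* **Journeys** — per-patient visit-type sequences from a Markov chain
  over {Outpatient, Inpatient, ER, Checkup} with an absorbing End state
  and a visit cap (default 30); visits are materialized with
  type-appropriate events and strictly increasing, non-overlapping
  windows. The checkup-like state maps to visit concept 32036
  ("Laboratory visit"); sites using a bespoke checkup concept can remap
  it.

Determinism: every generator call derives per-patient sub-streams from
(seed, stream id, patient index), so patient i's data is independent of
how many patients follow. Event times within a day are uniform over
working hours 08:00–18:00 unless date-only. Ground truth (planted entries
and probabilities, per-visit anchor dates, chain parameters, true state
sequences) is emitted alongside the dataset.

## Discovery analytics

The DFG counts consecutive event pairs per trace; self-loops are retained
(repeated same-day orders are real). Edge durations carry both mean and
median seconds (median is the more robust view for heavy-tailed gaps;
mean is the default annotation). Flow conservation — start count +
incoming = node frequency = end count + outgoing — holds by construction
and is asserted on every discovered model in the tests.

Mainstream filtering keeps the most frequent activities until their
cumulative event share reaches the requested fraction (ties kept
together), rebuilds traces on survivors, then prunes edges below the
`1 − path_fraction` frequency quantile; fractions of 1.0 are exact
identities, and node sets are never reduced by path pruning. Interactive
mining tools implement "mainstream behaviour" views with proprietary
semantics; this rule is an explicit, documented stand-in, not a claim of
equivalence.

Variants are exact activity-sequence tallies ranked by count; dotted
charts emit one `(case index, time, activity)` point per event with case
ordering by start time (ascending) or duration (descending); LOS summaries
use the n−1 standard deviation, reporting sd 0 with a flag for a single
case.

## Numerical and interface choices

* CDM files are RFC-4180 CSV, UTF-8, exact CDM column names; reading
  accepts both `…_datetime` and date-only text in datetime columns,
  preferring what is present.
* Event logs serialize to flat CSV or IEEE XES 2.0 (concept:name,
  time:timestamp, org:resource; lifecycle omitted); both round-trip
  field-for-field up to attribute ordering.
* Pipeline outputs carry provenance (config hash, seed, version) in a
  `provenance.json` sidecar per run directory — CSV/DOT artifacts stay
  standard-format rather than carrying comment headers.
* CLI exit codes: 0 success, 2 config error, 3 data error, 4 internal.

## Problem sizes

The bundled tests and examples run cohorts of 15–400 patients (2,000 for
binomial-rate checks and 1,000–1,500 for chain/LOS frequency checks) with
the default 20-entry pathway and 200 noise orders; the pathway-recovery
check uses 300 cases. These sizes put sampling error comfortably inside
the 3-standard-error tolerances used throughout while keeping any single
test in the seconds range. All components are linear in events per case
and scale to realistic extracts (tens of thousands of events) in memory.

## Known limitations

* The exhaustive search is an oracle, not a mining tool; it is
  combinatorial by design.
* Administrative activities absent from CDM (registration, scheduling,
  certificate issuance) and nursing/diet information are not inferred —
  outpatient and ER logs are as coarse as their source.
* The greedy matching-rate optimum is not guaranteed globally optimal on
  adversarial instances; the tests bound it by the exhaustive optimum and
  verify equality on well-separated ones.
* The synthetic generator's distributions are chosen for testability;
  matching a particular site's case mix requires configuring them.
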
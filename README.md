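# omopflow

Healthcare process mining on the OMOP Common Data Model.

As hospitals convert their EHR systems to the OMOP CDM — a standardized
relational schema with shared vocabularies for observational research — the
same tables become an attractive, portable source for *process mining*:
deriving process models, clinical pathways, and patient journeys from event
logs. `omopflow` is a Python library (with a thin CLI) for clinical
informaticians and process-mining researchers that

* reads, writes and validates the CDM slice relevant to event-log
  construction (visit_occurrence, the eight event-bearing clinical tables,
  person, provider, care_site, concept, concept_ancestor);
* extracts event logs for four healthcare process types — **inpatient**
  (concept-coded clinical orders per hospitalization), **outpatient**
  (coarse table-level activities: Consultation, Drug, Payment, …),
  **emergency room** (cases bounded by admitting-source and discharge
  activities), and **patient journey** (per-person multi-year visit
  sequences, optionally with indexed within-visit activities like
  `Out_1_Drug`);
* mines **clinical pathways** by the matching-rate criterion;
* provides discovery analytics: directly-follows graphs with frequency and
  performance annotations, mainstream filtering, trace variants,
  dotted-chart coordinates, and length-of-stay summaries;
* generates **synthetic CDM datasets with planted ground truth** (a known
  pathway, a visit-type Markov chain, ER admission/discharge mixes) so the
  whole chain is testable without access to hospital data.

## The clinical-pathway model

For a surgery cohort, each case is profiled by its distinct order entries
`(relative day d, concept c, source table)` where day 0 is the operation
date. A candidate pathway `CP` (a set of such entries) is scored by

* **application rate** `AR(CP) = mean over e ∈ CP of |{cases containing e}| / N`
  — how routinely each selected order is applied;
* **matched ratio** `MR(CP) = mean over cases i of |P_i ∩ CP| / |P_i|`
  — how much of each case's actual care the pathway explains;
* **matching rate** `AR + MR ∈ [0, 2]` — the mining objective.

The greedy miner appends the remaining entry with the highest application
rate, records the metric triple after every append, and selects the prefix
length maximizing the matching rate — the optimal number of clinical
orders. An exhaustive subset search over small instances serves as an
oracle in the test suite.

## Worked example

```bash
python examples/02_clinical_pathway_mining.py
```

generates a 300-patient synthetic surgery cohort (20 planted pathway
entries with occurrence probabilities 0.85–1.0, 200 noise orders at
0.01–0.15 per day), extracts the inpatient log and mines the pathway:

```
log: 300 cases, 35586 events

optimal number of orders: 20
k    application  matched  matching
18   0.9335       0.2052   1.1387
19   0.9298       0.2157   1.1456
20   0.9238       0.2257   1.1495 <- optimum
21   0.8884       0.2279   1.1163
...
recovery vs planted pathway: precision 1.00, recall 1.00

derived pathway by order day:
1 day before
  Drug: 925043(bisacodyl 5 MG), 939871(sodium phosphate), ...
OP day
  Drug: 717165(neostigmine methylsulfate 0.5 MG/ML Injectable Solution), ...
```

The curve shows the matching rate rising while high-probability routine
orders are added and falling once noise orders start diluting the
application rate; the optimum lands exactly on the 20 planted entries.
The other examples (`examples/01…05`) cover dataset generation and
validation, ER/outpatient extraction with timestamp repair, patient
journeys, and DFG/dotted-chart discovery.

The same workflows are available from the shell:

```bash
omopflow simulate --generator inpatient --seed 1 --out run/
omopflow extract --type inpatient --cdm run/cdm --out run/log.csv
omopflow mine-cp --log run/log.csv --anchor-concept 4336464 \
    --window -1:2 --cdm run/cdm --out run/cp
```

## Layout

```
src/omopflow/        cdm.py         CDM tables, CSV I/O, validation, vocabulary
                     synthetic.py   generators with planted ground truth
                     extraction.py  log specs and the four extractors
                     log_io.py      CSV / XES serialization
                     cpmining.py    pathway metrics, greedy + exhaustive mining
                     discovery.py   DFG, variants, dotted charts, LOS stats
                     config.py      run configuration and staged pipeline
                     cli.py         thin command-line shims
examples/            one narrative script per capability
tests/               pytest suite (unit, property, acceptance)
docs/methods.md      models, parameters, and design notes
```
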
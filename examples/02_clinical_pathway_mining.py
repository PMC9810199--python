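"""Mine a clinical pathway from a synthetic surgery cohort.

Extracts the inpatient event log, profiles each case relative to its
operation day, runs the greedy matching-rate miner, and prints the metric
curve around the optimal order count plus the day-grouped pathway report.
"""

from omopflow import (Cohort, LogSpec, build_case_profiles, cp_report,
                      extract_inpatient_log, greedy_cp_mine)
from omopflow.cpmining import render_cp_report
from omopflow.synthetic import SyntheticConfig, generate_inpatient_cohort

config = SyntheticConfig(seed=1, n_patients=300)
dataset, truth = generate_inpatient_cohort(config)

spec = LogSpec(process_type="inpatient",
               scope=["procedure_occurrence", "drug_exposure", "measurement",
                      "observation"],
               cohort=Cohort(concept_ids=[config.surgery_concept_id]))
log = extract_inpatient_log(dataset, spec)
print(f"log: {len(log)} cases, {log.n_events} events")

profiles = build_case_profiles(log, config.surgery_concept_id,
                               day_window=(-1, 2))
pathway = greedy_cp_mine(profiles)

print(f"\noptimal number of orders: {pathway.optimal_k}")
print("k    application  matched  matching")
for k in range(max(0, pathway.optimal_k - 3),
               min(len(pathway.curve), pathway.optimal_k + 3)):
    m = pathway.curve[k]
    marker = " <- optimum" if k + 1 == pathway.optimal_k else ""
    print(f"{k + 1:<5}{m.application_rate:.4f}       {m.matched_ratio:.4f}"
          f"   {m.matching_rate:.4f}{marker}")

planted = {(e.relative_day, e.concept_id, e.source_table)
           for e in truth.planted_cp}
mined = {tuple(e) for e in pathway.optimal_entries}
tp = len(planted & mined)
print(f"\nrecovery vs planted pathway: precision "
      f"{tp / len(mined):.2f}, recall {tp / len(planted):.2f}")

print("\nderived pathway by order day:")
print(render_cp_report(cp_report(pathway.optimal_entries,
                                 dataset.concept_name)))

# The matching rate (application rate + matched ratio) peaks where adding
# further orders would dilute routine coverage faster than it explains care;
# on this cohort the optimum recovers the planted 20-order pathway.
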
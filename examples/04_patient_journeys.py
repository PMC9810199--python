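"""Patient-journey logs at visit level and descendant level.

Each patient's multi-year visit sequence is a realization of a visit-type
Markov chain.  At visit level every visit is one event; at descendant level
within-visit activities are labelled Out_1_Drug-style with per-type visit
indices and same-day duplicates collapsed.
"""

from omopflow import LogSpec, compute_variants, extract_patient_journey_log
from omopflow.synthetic import SyntheticConfig, generate_patient_journeys

config = SyntheticConfig(seed=3, n_patients=400)
dataset, truth = generate_patient_journeys(config)

log = extract_patient_journey_log(
    dataset, LogSpec(process_type="patient_journey"))
variants = compute_variants(log)
print(f"{len(log)} patients, {log.n_events} visits, "
      f"{len(variants.variants)} distinct journeys")
print("most frequent journeys:")
for seq, count, support in variants.top(5):
    print(f"  {count:4d} ({support:6.2%})  {' > '.join(seq)}")

descendant = extract_patient_journey_log(
    dataset, LogSpec(process_type="patient_journey",
                     journey_level="descendant", journey_markers=True))
trace = descendant.traces[0]
print(f"\ndescendant-level journey of patient {trace.case_id}:")
print("  " + " > ".join(e.activity for e in trace.events[:12]))
print(f"true visit-type sequence: "
      f"{truth.visit_sequences[int(trace.case_id)]}")

# Variant supports sum to one over patients; the descendant view exposes
# intervention patterns inside each indexed visit.
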
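"""Extract ER and outpatient event logs; repair date-only timestamps.

ER cases are bounded by admitting-source and discharge activities and carry
LOS in hours; outpatient events use coarse table-level activity labels, and
rows recorded with only a calendar date get deterministic times in the
order condition > drug > cost.
"""

from omopflow import (LogSpec, extract_er_log, extract_outpatient_log,
                      los_summary, repair_dateonly_timestamps)
from omopflow.synthetic import (SyntheticConfig, generate_er_visits,
                                generate_outpatient_visits)

config = SyntheticConfig(seed=2, n_patients=200)

er_dataset, _ = generate_er_visits(config)
er_log = extract_er_log(er_dataset, LogSpec(process_type="er"))
trace = er_log.traces[0]
print("ER case", trace.case_id)
for e in trace.events:
    print(f"  {e.timestamp}  {e.activity}")
stats = los_summary(er_log, "los_hours")
print(f"ER LOS: mean {stats['mean']:.2f} h, sd {stats['sd']:.2f} h, "
      f"median {stats['median']:.2f} h over {stats['n_cases']} cases")

out_dataset, _ = generate_outpatient_visits(config)
out_log = extract_outpatient_log(out_dataset,
                                 LogSpec(process_type="outpatient"))
n_dated = sum(e.attributes.get("date_only", False)
              for t in out_log.traces for e in t.events)
repaired = repair_dateonly_timestamps(out_log)
print(f"\noutpatient log: {len(out_log)} cases, {out_log.n_events} events, "
      f"{n_dated} date-only rows repaired")
case = repaired.traces[0]
for e in case.events:
    tag = " (repaired)" if e.attributes.get("repaired") else ""
    print(f"  {e.timestamp}  {e.activity}{tag}")

# Each first/last ER activity names the admission source and discharge
# destination; repaired outpatient events keep the stated table order with
# gaps spread across 5-30 minutes.
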
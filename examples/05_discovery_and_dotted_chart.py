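"""Directly-follows discovery, mainstream filtering, and dotted charts.

Discovers the annotated DFG of a journey log, filters it to mainstream
behaviour, and emits dotted-chart coordinates sorted by case duration.
"""

from omopflow import (LogSpec, discover_dfg, dotted_chart,
                      extract_patient_journey_log, filter_mainstream)
from omopflow.synthetic import SyntheticConfig, generate_patient_journeys

config = SyntheticConfig(seed=5, n_patients=300)
dataset, _ = generate_patient_journeys(config)
log = extract_patient_journey_log(
    dataset, LogSpec(process_type="patient_journey"))

dfg = discover_dfg(log)
print(f"full model: {len(dfg.activity_freq)} activities, "
      f"{len(dfg.edges)} edges")
for (a, b), e in sorted(dfg.edges.items(),
                        key=lambda kv: -kv[1].frequency)[:5]:
    print(f"  {a} -> {b}: {e.frequency}x, median "
          f"{e.median_s / 86400:.1f} days")

filtered, main_dfg = filter_mainstream(log, activity_fraction=0.8,
                                       path_fraction=0.5)
print(f"mainstream (80% activities, 50% paths): "
      f"{len(main_dfg.activity_freq)} activities, "
      f"{len(main_dfg.edges)} edges")

chart = dotted_chart(log, sort="duration", time_axis="relative")
idx, t, act = chart.points[0]
print(f"\ndotted chart: {len(chart.points)} points; first point is case "
      f"index {idx} at +{t:.0f} s ({act})")
print(f"longest journey: case {chart.case_order[0]}")

# Edge medians show typical gaps between consecutive visits; duration
# sorting puts the longest patient journeys at the top of the chart.
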
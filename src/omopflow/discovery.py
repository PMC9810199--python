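"""Process discovery on event logs: directly-follows graphs, mainstream
filtering, trace variants, dotted-chart coordinates, and LOS summaries.

The directly-follows graph (DFG) counts consecutive event pairs within each
case's time-ordered trace, annotates edges with inter-event duration
statistics (mean and median seconds), and records start/end activity
frequencies.  Flow conservation holds by construction: for every activity,
start count + incoming edge traversals = event count = end count + outgoing
edge traversals.

Mainstream filtering mimics the "keep the mainstream behaviour" views of
interactive process-mining tools: the most frequent activities are kept
until their cumulative event share reaches the requested fraction (ties kept
together), traces are rebuilt on the survivors, and low-frequency edges are
pruned by a frequency quantile.  The exact semantics of commercial miners
are proprietary; this cumulative-coverage rule is an explicit stand-in.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .extraction import EventLog, Trace


@dataclass
class DfgEdge:
    frequency: int = 0
    durations_s: list[float] = field(default_factory=list)

    @property
    def mean_s(self) -> float:
        return float(np.mean(self.durations_s)) if self.durations_s else 0.0

    @property
    def median_s(self) -> float:
        return float(np.median(self.durations_s)) if self.durations_s else 0.0


@dataclass
class Dfg:
    activity_freq: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[str, str], DfgEdge] = field(default_factory=dict)
    start_freq: dict[str, int] = field(default_factory=dict)
    end_freq: dict[str, int] = field(default_factory=dict)

    def edge(self, a: str, b: str) -> DfgEdge:
        return self.edges[(a, b)]

    def to_json(self, stat: str = "mean") -> dict:
        return {
            "activities": dict(sorted(self.activity_freq.items())),
            "start_activities": dict(sorted(self.start_freq.items())),
            "end_activities": dict(sorted(self.end_freq.items())),
            "edges": [
                {"from": a, "to": b, "frequency": e.frequency,
                 "duration_s": e.mean_s if stat == "mean" else e.median_s}
                for (a, b), e in sorted(self.edges.items())],
        }

    def to_dot(self, stat: str = "mean") -> str:
        """Graphviz DOT rendering (frequency + duration annotations)."""
        lines = ["digraph dfg {", "  rankdir=TB;"]
        ids = {a: f"n{i}" for i, a in enumerate(sorted(self.activity_freq))}
        for a, node in ids.items():
            lines.append(f'  {node} [label="{a}\\n{self.activity_freq[a]}"];')
        for (a, b), e in sorted(self.edges.items()):
            dur = e.mean_s if stat == "mean" else e.median_s
            lines.append(f'  {ids[a]} -> {ids[b]} '
                         f'[label="{e.frequency} ({dur:.0f}s)"];')
        lines.append("}")
        return "\n".join(lines)


def discover_dfg(log: EventLog) -> Dfg:
    """Build the annotated directly-follows graph of a log."""
    dfg = Dfg()
    for trace in log.traces:
        if not trace.events:
            continue
        acts = [e.activity for e in trace.events]
        for a in acts:
            dfg.activity_freq[a] = dfg.activity_freq.get(a, 0) + 1
        dfg.start_freq[acts[0]] = dfg.start_freq.get(acts[0], 0) + 1
        dfg.end_freq[acts[-1]] = dfg.end_freq.get(acts[-1], 0) + 1
        for prev, cur in zip(trace.events, trace.events[1:]):
            key = (prev.activity, cur.activity)
            edge = dfg.edges.setdefault(key, DfgEdge())
            edge.frequency += 1
            edge.durations_s.append(
                (cur.timestamp - prev.timestamp).total_seconds())
    return dfg


def filter_mainstream(log: EventLog, activity_fraction: float = 1.0,
                      path_fraction: float = 1.0) -> tuple[EventLog, Dfg]:
    """Keep mainstream activities and major paths only.

    Activities are ranked by event count; the smallest prefix whose
    cumulative count reaches ``activity_fraction`` of all events survives
    (activities tied with the last kept one survive too).  Traces are rebuilt
    on surviving events, then DFG edges with frequency below the
    ``1 - path_fraction`` quantile are pruned (nodes are never removed).
    """
    if not (0 < activity_fraction <= 1) or not (0 < path_fraction <= 1):
        raise ValueError("fractions must be in (0, 1]")
    counts: dict[str, int] = {}
    for trace in log.traces:
        for e in trace.events:
            counts[e.activity] = counts.get(e.activity, 0) + 1
    total = sum(counts.values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept: set[str] = set()
    cum = 0
    threshold_count = None
    for act, cnt in ranked:
        if cum >= activity_fraction * total and cnt != threshold_count:
            break
        kept.add(act)
        cum += cnt
        threshold_count = cnt
    filtered = EventLog(provenance={**log.provenance,
                                    "activity_fraction": activity_fraction,
                                    "path_fraction": path_fraction})
    for trace in log.traces:
        surv = [e for e in trace.events if e.activity in kept]
        if surv:
            filtered.traces.append(Trace(case_id=trace.case_id,
                                         attributes=dict(trace.attributes),
                                         events=surv))
    if not filtered.traces:
        raise ValueError("filtering emptied every case; "
                         "increase the fractions")
    dfg = discover_dfg(filtered)
    if dfg.edges and path_fraction < 1.0:
        freqs = np.array([e.frequency for e in dfg.edges.values()])
        cut = float(np.quantile(freqs, 1.0 - path_fraction))
        dfg.edges = {k: e for k, e in dfg.edges.items() if e.frequency >= cut}
    return filtered, dfg


@dataclass
class VariantTable:
    """Ranked distinct activity sequences with counts and supports."""

    variants: list[tuple[tuple[str, ...], int, float]] = field(
        default_factory=list)
    n_cases: int = 0

    def top(self, n: int = 10):
        return self.variants[:n]


def compute_variants(log: EventLog) -> VariantTable:
    if not log.traces:
        raise ValueError("log is empty")
    tally: dict[tuple[str, ...], int] = {}
    for trace in log.traces:
        key = tuple(e.activity for e in trace.events)
        tally[key] = tally.get(key, 0) + 1
    n = len(log.traces)
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return VariantTable(
        variants=[(seq, cnt, cnt / n) for seq, cnt in ranked], n_cases=n)


@dataclass
class DottedChart:
    """Per-event plotting coordinates: (case index, time, activity)."""

    points: list[tuple[int, float, str]] = field(default_factory=list)
    case_order: list[str] = field(default_factory=list)
    sort: str = "start_time"
    time_axis: str = "absolute"


def dotted_chart(log: EventLog, sort: str = "start_time",
                 time_axis: str = "absolute") -> DottedChart:
    """Dotted-chart coordinates: one point per event.

    ``sort="start_time"`` orders cases by ascending first-event time;
    ``sort="duration"`` by descending case duration.  ``time_axis`` is
    either absolute epoch seconds or the offset from each case's start.
    """
    if sort not in ("start_time", "duration"):
        raise ValueError(f"unknown sort mode {sort!r}")
    if time_axis not in ("absolute", "relative"):
        raise ValueError(f"unknown time axis {time_axis!r}")
    cases = [t for t in log.traces if t.events]
    if sort == "start_time":
        cases.sort(key=lambda t: (t.events[0].timestamp, t.case_id))
    else:
        cases.sort(key=lambda t: (-(t.events[-1].timestamp
                                    - t.events[0].timestamp).total_seconds(),
                                  t.case_id))
    chart = DottedChart(sort=sort, time_axis=time_axis)
    for idx, trace in enumerate(cases):
        chart.case_order.append(trace.case_id)
        start = trace.events[0].timestamp
        for e in trace.events:
            t = (e.timestamp.timestamp() if time_axis == "absolute"
                 else (e.timestamp - start).total_seconds())
            chart.points.append((idx, t, e.activity))
    return chart


def los_summary(log: EventLog, attribute: str = "los_days") -> dict:
    """Sample statistics of the LOS case attribute (sd uses n−1).

    With a single case the sd is undefined; it is reported as 0 with
    ``sd_defined=False``.
    """
    missing = [t.case_id for t in log.traces if attribute not in t.attributes]
    if missing:
        raise ValueError(f"cases missing {attribute!r}: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    values = [float(t.attributes[attribute]) for t in log.traces]
    if not values:
        raise ValueError("log is empty")
    n = len(values)
    return {
        "n_cases": n,
        "mean": float(np.mean(values)),
        "sd": float(statistics.stdev(values)) if n > 1 else 0.0,
        "sd_defined": n > 1,
        "median": float(np.median(values)),
    }


def write_dfg(dfg: Dfg, out_dir: str | Path, stat: str = "mean") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dot = out_dir / "dfg.dot"
    dot.write_text(dfg.to_dot(stat))
    js = out_dir / "dfg.json"
    js.write_text(json.dumps(dfg.to_json(stat), indent=2))
    return [dot, js]
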
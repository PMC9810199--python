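"""Matching-rate-based clinical-pathway (CP) mining.

A clinical pathway here is a day-structured set of clinical orders around an
anchoring operation: entries ``(relative day, concept, source table)`` where
day 0 is the operation date.  Given per-case profiles (the distinct entries
each case exhibits inside a day window), three metrics score a candidate CP:

* application rate — mean over CP entries of the fraction of cases whose
  profile contains the entry (how routinely each selected order is applied);
* matched ratio — mean over cases of the fraction of the case's distinct
  entries covered by the CP (how much of actual care the CP explains);
* matching rate — their sum, the selection objective, in [0, 2].

Greedy mining repeatedly appends the candidate entry with the highest
application rate (or highest matching-rate gain), records the metric triple
after every append, and reports the prefix length maximizing the matching
rate — the optimal number of clinical orders.  An exhaustive search over
entry subsets serves as an oracle on small instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import NamedTuple, Optional, Sequence

import pandas as pd

from .extraction import EventLog

logger = logging.getLogger(__name__)


class CpEntry(NamedTuple):
    """Hashable identity of a pathway entry."""

    relative_day: int
    concept_id: int
    source_table: str


@dataclass
class CaseProfile:
    """Distinct (relative day, concept, table) entries of one case.

    ``counts`` keeps occurrence multiplicity for reporting; the metrics use
    presence only, so repeated same-day administrations do not inflate them.
    """

    case_id: str
    anchor_date: pd.Timestamp
    entries: frozenset[CpEntry]
    counts: dict[CpEntry, int] = field(default_factory=dict)


class CpMetrics(NamedTuple):
    application_rate: float
    matched_ratio: float
    matching_rate: float


@dataclass
class ClinicalPathway:
    """Greedy selection order, per-prefix metric curve, and the optimum."""

    entries: list[CpEntry] = field(default_factory=list)
    curve: list[CpMetrics] = field(default_factory=list)
    optimal_k: int = 0

    @property
    def optimal_entries(self) -> list[CpEntry]:
        return self.entries[: self.optimal_k]

    @property
    def optimal_metrics(self) -> Optional[CpMetrics]:
        return self.curve[self.optimal_k - 1] if self.optimal_k else None


def build_case_profiles(log: EventLog, anchor_concept_id: int,
                        day_window: tuple[int, int] = (-1, 2),
                        anchor_concept_ids: Optional[set[int]] = None,
                        ) -> list[CaseProfile]:
    """Profile every case relative to its earliest anchor (operation) event.

    Events become entries ``(event date − anchor date, concept, table)``
    restricted to ``day_window``; the anchor event itself is excluded.
    Cases lacking an anchor event are dropped with a warning.
    """
    d_min, d_max = day_window
    if d_min > d_max:
        raise ValueError("day_window minimum exceeds maximum")
    anchors = anchor_concept_ids or {int(anchor_concept_id)}
    profiles: list[CaseProfile] = []
    dropped = 0
    for trace in log.traces:
        anchor_ts = None
        for e in sorted(trace.events, key=lambda e: e.timestamp):
            if e.concept_id is not None and int(e.concept_id) in anchors:
                anchor_ts = e.timestamp
                anchor_event = e
                break
        if anchor_ts is None:
            dropped += 1
            logger.warning("case %s lacks anchor concept %s; dropped",
                           trace.case_id, sorted(anchors))
            continue
        anchor_date = anchor_ts.normalize()
        counts: dict[CpEntry, int] = {}
        for e in trace.events:
            if e is anchor_event or e.concept_id is None:
                continue
            rel = int((e.timestamp.normalize() - anchor_date).days)
            if not d_min <= rel <= d_max:
                continue
            entry = CpEntry(rel, int(e.concept_id), e.source_table)
            counts[entry] = counts.get(entry, 0) + 1
        profiles.append(CaseProfile(case_id=trace.case_id,
                                    anchor_date=anchor_date,
                                    entries=frozenset(counts),
                                    counts=counts))
    if dropped:
        logger.warning("%d cases dropped for missing anchor", dropped)
    return profiles


def entry_application_rate(entry: CpEntry,
                           profiles: Sequence[CaseProfile]) -> float:
    """Fraction of cases whose profile contains ``entry``."""
    if not profiles:
        raise ValueError("profiles must be non-empty")
    return sum(entry in p.entries for p in profiles) / len(profiles)


def cp_application_rate(cp: Sequence[CpEntry],
                        profiles: Sequence[CaseProfile]) -> float:
    """Mean per-entry application rate over the CP (0 for an empty CP)."""
    if not cp:
        return 0.0
    return sum(entry_application_rate(e, profiles) for e in cp) / len(cp)


def cp_matched_ratio(cp: Sequence[CpEntry],
                     profiles: Sequence[CaseProfile]) -> float:
    """Mean over cases of |profile ∩ cp| / |profile| (distinct entries)."""
    if not cp:
        return 0.0
    cp_set = set(cp)
    ratios = []
    for p in profiles:
        if not p.entries:
            logger.warning("case %s has an empty profile; excluded from "
                           "matched ratio", p.case_id)
            continue
        ratios.append(len(p.entries & cp_set) / len(p.entries))
    if not ratios:
        raise ValueError("no non-empty profiles")
    return sum(ratios) / len(ratios)


def cp_matching_rate(cp: Sequence[CpEntry],
                     profiles: Sequence[CaseProfile]) -> float:
    """Selection objective: application rate + matched ratio, in [0, 2]."""
    if not cp:
        return 0.0
    return cp_application_rate(cp, profiles) + cp_matched_ratio(cp, profiles)


def _selection_key(rate: float, entry: CpEntry):
    # ties: higher rate first, then smaller concept_id, then smaller day
    return (-rate, entry.concept_id, entry.relative_day, entry.source_table)


def greedy_cp_mine(profiles: Sequence[CaseProfile], k_max: int = 500,
                   selection: str = "application_rate") -> ClinicalPathway:
    """Greedy CP construction with optimal-order-count search.

    Iteratively appends the candidate entry maximizing the selection
    criterion (``application_rate`` — the default, static order — or
    ``matching_gain`` — recomputed marginal matching-rate gain), recording
    the metric triple after each append.  ``optimal_k`` is the smallest
    prefix length attaining the maximal matching rate on the curve.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if selection not in ("application_rate", "matching_gain"):
        raise ValueError(f"unknown selection criterion {selection!r}")
    candidates = sorted({e for p in profiles for e in p.entries})
    cp = ClinicalPathway()
    if not candidates:
        return cp

    n = len(profiles)
    rates = {e: entry_application_rate(e, profiles) for e in candidates}
    nonempty = [p for p in profiles if p.entries]
    sizes = [len(p.entries) for p in nonempty]
    covered = [0] * len(nonempty)
    rate_sum = 0.0
    limit = min(k_max, len(candidates))

    if selection == "application_rate":
        order = sorted(candidates, key=lambda e: _selection_key(rates[e], e))
        chosen_iter = order[:limit]
    else:
        chosen_iter = None  # chosen dynamically below

    remaining = set(candidates)
    for k in range(1, limit + 1):
        if selection == "application_rate":
            entry = chosen_iter[k - 1]
        else:
            best, best_total = None, None
            for e in sorted(remaining,
                            key=lambda e: _selection_key(rates[e], e)):
                ar_new = (rate_sum + rates[e]) / k
                mr_new = (sum((c + (e in p.entries)) / s for c, s, p
                              in zip(covered, sizes, nonempty))
                          / max(1, len(nonempty)))
                total = ar_new + mr_new
                if best_total is None or total > best_total:
                    best, best_total = e, total
            entry = best
        remaining.discard(entry)
        rate_sum += rates[entry]
        for i, p in enumerate(nonempty):
            if entry in p.entries:
                covered[i] += 1
        ar = rate_sum / k
        mr = (sum(c / s for c, s in zip(covered, sizes)) / len(nonempty)
              if nonempty else 0.0)
        cp.entries.append(entry)
        cp.curve.append(CpMetrics(ar, mr, ar + mr))
    best_rate = max(m.matching_rate for m in cp.curve)
    cp.optimal_k = next(i + 1 for i, m in enumerate(cp.curve)
                        if m.matching_rate == best_rate)
    return cp


def exhaustive_cp_search(profiles: Sequence[CaseProfile], k: int,
                         cap: int = 1_000_000
                         ) -> tuple[list[CpEntry], CpMetrics]:
    """Exact argmax-matching-rate entry set of size ``k`` (small instances).

    Enumerates all size-k candidate subsets; refuses instances whose
    combination count exceeds ``cap``.  Ties break on sorted entry identity.
    """
    candidates = sorted({e for p in profiles for e in p.entries})
    if k < 1 or k > len(candidates):
        raise ValueError(f"k={k} out of range for {len(candidates)} candidates")
    n_comb = comb(len(candidates), k)
    if n_comb > cap:
        raise ValueError(f"{n_comb} combinations exceed cap {cap}; "
                         "reduce the instance")
    best_set: Optional[tuple] = None
    best_metrics: Optional[CpMetrics] = None
    for subset in combinations(candidates, k):
        ar = cp_application_rate(subset, profiles)
        mr = cp_matched_ratio(subset, profiles)
        metrics = CpMetrics(ar, mr, ar + mr)
        if (best_metrics is None
                or metrics.matching_rate > best_metrics.matching_rate
                or (metrics.matching_rate == best_metrics.matching_rate
                    and subset < best_set)):
            best_set, best_metrics = subset, metrics
    return list(best_set), best_metrics


def _day_label(day: int) -> str:
    if day == 0:
        return "OP day"
    n = abs(day)
    unit = "day" if n == 1 else "days"
    return f"{n} {unit} {'before' if day < 0 else 'after'}"


def cp_report(cp: Sequence[CpEntry], dataset_or_resolver) -> dict:
    """Day-grouped rendering of a CP: day label -> table -> entry strings.

    Entries render as ``"<concept_id>(<concept_name>)"``, grouped by relative
    day (``"1 day before"``, ``"OP day"``, ``"N days after"``) and by source
    table within each day.
    """
    resolve = (dataset_or_resolver.concept_name
               if hasattr(dataset_or_resolver, "concept_name")
               else dataset_or_resolver)
    report: dict[str, dict[str, list[str]]] = {}
    for entry in sorted(cp):
        label = _day_label(entry.relative_day)
        name = resolve(entry.concept_id) or "unknown"
        table_label = entry.source_table.replace("_exposure", "").replace(
            "_occurrence", "").capitalize()
        report.setdefault(label, {}).setdefault(table_label, []).append(
            f"{entry.concept_id}({name})")
    return report


def render_cp_report(report: dict) -> str:
    lines = []

    def _order(label: str) -> int:
        if label == "OP day":
            return 0
        n = int(label.split()[0])
        return -n if label.endswith("before") else n

    for label in sorted(report, key=_order):
        lines.append(label)
        for table in sorted(report[label]):
            lines.append(f"  {table}: " + ", ".join(report[label][table]))
    return "\n".join(lines)
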
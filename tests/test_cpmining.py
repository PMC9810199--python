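"""Clinical-pathway metrics and mining: worked examples, the additive
identity, greedy/exhaustive agreement, and day-grouped reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omopflow.cpmining import (CaseProfile, CpEntry, build_case_profiles,
                               cp_application_rate, cp_matched_ratio,
                               cp_matching_rate, cp_report,
                               entry_application_rate, exhaustive_cp_search,
                               greedy_cp_mine, render_cp_report)
from omopflow.extraction import Event, EventLog, Trace

T = pd.Timestamp


def _profiles(case_entries):
    """Build profiles from a list of entry collections (day 0, drug table)."""
    return [
        CaseProfile(case_id=str(i), anchor_date=T("2021-08-02"),
                    entries=frozenset(
                        CpEntry(0, c, "drug_exposure") for c in entries))
        for i, entries in enumerate(case_entries)]


def _entry(concept, day=0):
    return CpEntry(day, concept, "drug_exposure")


def _trace(case_id, concept_times, anchor=("2021-08-02 09:00:00", 900)):
    events = [Event(event_id=f"{case_id}:a", activity="anchor",
                    timestamp=T(anchor[0]), source_table="procedure_occurrence",
                    concept_id=anchor[1], event_row_id=0)]
    for i, (concept, ts) in enumerate(concept_times, start=1):
        events.append(Event(event_id=f"{case_id}:{i}", activity=str(concept),
                            timestamp=T(ts), source_table="drug_exposure",
                            concept_id=concept, event_row_id=i))
    return Trace(case_id=case_id, events=sorted(events,
                                                key=lambda e: e.timestamp))


class TestCaseProfiles:
    def test_relative_days_are_anchored_on_the_operation_date(self):
        log = EventLog(traces=[_trace("c1", [
            (101, "2021-08-02 10:00:00"),   # OP day
            (102, "2021-08-01 12:00:00"),   # 1 day before
            (103, "2021-08-04 09:00:00"),   # 2 days after
        ])])
        profiles = build_case_profiles(log, 900, (-1, 2))
        assert profiles[0].entries == {
            _entry(101, 0), _entry(102, -1), _entry(103, 2)}

    def test_window_filter_drops_out_of_range_days(self):
        log = EventLog(traces=[_trace("c1", [
            (101, "2021-08-07 10:00:00")])])  # +5 days
        profiles = build_case_profiles(log, 900, (-1, 2))
        assert profiles[0].entries == frozenset()

    def test_case_without_anchor_is_dropped(self):
        log = EventLog(traces=[
            _trace("c1", [(101, "2021-08-02 10:00:00")]),
            Trace(case_id="c2", events=[
                Event(event_id="x", activity="101",
                      timestamp=T("2021-08-02 10:00:00"),
                      source_table="drug_exposure", concept_id=101)])])
        profiles = build_case_profiles(log, 900, (-1, 2))
        assert [p.case_id for p in profiles] == ["c1"]

    def test_anchor_event_is_excluded_but_multiplicity_counted(self):
        log = EventLog(traces=[_trace("c1", [
            (101, "2021-08-02 10:00:00"), (101, "2021-08-02 11:00:00")])])
        profile = build_case_profiles(log, 900, (-1, 2))[0]
        assert profile.entries == {_entry(101)}
        assert profile.counts[_entry(101)] == 2


class TestMetrics:
    def test_entry_application_rate_counts_cases(self):
        profiles = _profiles([{1, 2}, {1}, {3}, {3}, {3}, {4}, {4}, {5}])
        assert entry_application_rate(_entry(3), profiles) == 0.375
        assert entry_application_rate(_entry(1), profiles) == 0.25
        assert entry_application_rate(_entry(99), profiles) == 0.0

    def test_cp_application_rate_is_mean_of_entry_rates(self):
        profiles = _profiles([{1, 2}, {1}])
        cp = [_entry(1), _entry(2)]  # rates 1.0 and 0.5
        assert cp_application_rate(cp, profiles) == 0.75
        assert cp_application_rate([_entry(1)], profiles) == \
            entry_application_rate(_entry(1), profiles)
        assert cp_application_rate([], profiles) == 0.0

    def test_matched_ratio_averages_per_case_coverage(self):
        profiles = _profiles([{1, 2}, {1}])
        assert cp_matched_ratio([_entry(1)], profiles) == 0.75
        assert cp_matched_ratio([_entry(1), _entry(2)], profiles) == 1.0
        assert cp_matched_ratio([], profiles) == 0.0

    def test_matching_rate_is_the_component_sum(self):
        profiles = _profiles([{1, 2}, {1}])
        assert cp_matching_rate([_entry(1)], profiles) == 1.0 + 0.75
        assert cp_matching_rate([], profiles) == 0.0

    def test_worked_example_reproduces_the_published_triple(self):
        """A 10,000-case profile set on which the application rate is 44.17%
        and the matched ratio 38.73% must yield a matching rate of 82.90%."""
        e, f = _entry(1), _entry(2)
        profiles = _profiles([{1}] * 3329 + [{1, 2}] * 1088 + [{2}] * 5583)
        cp = [e]
        ar = cp_application_rate(cp, profiles)
        mr = cp_matched_ratio(cp, profiles)
        assert round(100 * ar, 2) == 44.17
        assert round(100 * mr, 2) == 38.73
        assert round(100 * cp_matching_rate(cp, profiles), 2) == 82.90
        assert f not in cp

    def test_empty_profile_list_is_rejected(self):
        with pytest.raises(ValueError):
            entry_application_rate(_entry(1), [])


@st.composite
def _random_instance(draw):
    n_cases = draw(st.integers(2, 12))
    n_concepts = draw(st.integers(2, 8))
    case_entries = [
        draw(st.sets(st.integers(1, n_concepts), min_size=1, max_size=5))
        for _ in range(n_cases)]
    cp_concepts = draw(st.sets(st.integers(1, n_concepts), min_size=1,
                               max_size=4))
    return case_entries, cp_concepts


@settings(max_examples=200, deadline=None, derandomize=True)
@given(_random_instance())
def test_additive_identity_and_bounds_hold_on_random_instances(instance):
    case_entries, cp_concepts = instance
    profiles = _profiles(case_entries)
    cp = [_entry(c) for c in sorted(cp_concepts)]
    ar = cp_application_rate(cp, profiles)
    mr = cp_matched_ratio(cp, profiles)
    assert 0.0 <= ar <= 1.0 and 0.0 <= mr <= 1.0
    assert abs(cp_matching_rate(cp, profiles) - (ar + mr)) < 1e-12


@settings(max_examples=50, deadline=None, derandomize=True)
@given(_random_instance())
def test_greedy_curve_monotonicity(instance):
    """Along the application-rate greedy sequence the matched ratio never
    decreases and the application rate never increases."""
    case_entries, _ = instance
    profiles = _profiles(case_entries)
    cp = greedy_cp_mine(profiles)
    ars = [m.application_rate for m in cp.curve]
    mrs = [m.matched_ratio for m in cp.curve]
    assert all(a >= b - 1e-12 for a, b in zip(ars, ars[1:]))
    assert all(a <= b + 1e-12 for a, b in zip(mrs, mrs[1:]))
    assert all(0 <= m.matching_rate <= 2 for m in cp.curve)


class TestGreedy:
    def test_highest_application_rate_is_selected_first(self):
        profiles = _profiles([{1, 2}, {1}])
        cp = greedy_cp_mine(profiles)
        assert cp.entries[0] == _entry(1)

    def test_ties_break_by_ascending_concept_id(self):
        profiles = _profiles([{3, 2, 9}])
        cp = greedy_cp_mine(profiles)
        assert [e.concept_id for e in cp.entries] == [2, 3, 9]

    def test_empty_profiles_give_empty_pathway(self):
        cp = greedy_cp_mine(_profiles([set()]))
        assert cp.entries == [] and cp.optimal_k == 0

    def test_optimal_k_is_smallest_argmax(self):
        # one ubiquitous entry and one rare entry: adding the rare entry
        # lowers the application rate more than coverage gains
        profiles = _profiles([{1}] * 9 + [{1, 2}])
        cp = greedy_cp_mine(profiles)
        assert cp.optimal_k == 1
        assert cp.optimal_entries == [_entry(1)]

    def test_matching_gain_selection_accepted(self):
        profiles = _profiles([{1, 2}, {1}])
        cp = greedy_cp_mine(profiles, selection="matching_gain")
        assert cp.entries[0] == _entry(1)


class TestExhaustive:
    def test_picks_the_dominant_entry_at_k1(self):
        profiles = _profiles([{1, 2}, {1}])
        best, metrics = exhaustive_cp_search(profiles, k=1)
        assert best == [_entry(1)]
        assert metrics.matching_rate == 1.75

    def test_full_candidate_set_equals_direct_metrics(self):
        profiles = _profiles([{1, 2}, {2, 3}])
        candidates = sorted({e for p in profiles for e in p.entries})
        best, metrics = exhaustive_cp_search(profiles, k=len(candidates))
        assert set(best) == set(candidates)
        assert metrics.matching_rate == pytest.approx(
            cp_matching_rate(candidates, profiles))

    def test_combination_cap_is_enforced(self):
        profiles = _profiles([set(range(1, 30))])
        with pytest.raises(ValueError, match="cap"):
            exhaustive_cp_search(profiles, k=10, cap=1000)

    def test_greedy_never_beats_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n_cases = int(rng.integers(3, 20))
            n_concepts = int(rng.integers(3, 10))
            k = int(rng.integers(1, 4))
            case_entries = [
                set(rng.choice(n_concepts,
                               size=rng.integers(1, min(5, n_concepts + 1)),
                               replace=False) + 1)
                for _ in range(n_cases)]
            profiles = _profiles(case_entries)
            greedy = greedy_cp_mine(profiles, k_max=k)
            if len(greedy.curve) < k:
                continue
            _, best = exhaustive_cp_search(profiles, k=k)
            assert greedy.curve[k - 1].matching_rate \
                <= best.matching_rate + 1e-12


class TestReport:
    def test_day_grouping_and_rendering(self):
        cp = [CpEntry(-1, 925043, "drug_exposure"),
              CpEntry(0, 35605373, "drug_exposure"),
              CpEntry(1, 3000666, "measurement"),
              CpEntry(2, 19086516, "drug_exposure")]
        names = {925043: "bisacodyl 5 MG", 35605373: "remifentanil 1 MG",
                 3000666: "Metamyelocytes/100 leukocytes in Blood by "
                          "Manual count",
                 19086516: "aceclofenac 100 MG"}
        report = cp_report(cp, names.get)
        assert report["1 day before"]["Drug"] == ["925043(bisacodyl 5 MG)"]
        assert report["OP day"]["Drug"] == ["35605373(remifentanil 1 MG)"]
        assert "Measurement" in report["1 day after"]
        assert report["2 days after"]["Drug"] == [
            "19086516(aceclofenac 100 MG)"]
        text = render_cp_report(report)
        assert text.splitlines()[0] == "1 day before"
        assert text.index("OP day") < text.index("2 days after")
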
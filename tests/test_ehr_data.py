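"""Event-stream I/O, windowing, time deltas and case-control matching."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pave.ehr_data import (
    Cohort,
    CohortParseError,
    CohortValidationError,
    Demographics,
    Event,
    Patient,
    VariableSpec,
    age_group_of,
    compute_time_deltas,
    extract_observation_window,
    match_controls,
    read_cohort,
    write_cohort,
)
from pave.synth_ehr import SyntheticSpec, simulate_cohort


def make_patient(times, label=0, anchor=0.0, var="heart_rate", values=None):
    demo = Demographics(gender="male", age_group="60-69")
    values = values or [80.0] * len(times)
    events = [Event(var, v, t, i) for i, (t, v) in enumerate(zip(times, values))]
    return Patient("p", demo, events, label, anchor_time=anchor)


class TestTypes:
    def test_variable_spec_invariants(self):
        with pytest.raises(CohortValidationError):
            VariableSpec("x", "real", 10.0, 5.0)  # min >= max
        with pytest.raises(CohortValidationError):
            VariableSpec("x", "real", 0.0, 10.0, normal_low=5.0, normal_high=3.0)
        with pytest.raises(CohortValidationError):
            VariableSpec("x", "real", 0.0, 10.0, normal_low=-1.0, normal_high=5.0)
        with pytest.raises(CohortValidationError):
            VariableSpec("x", "boolean", 0.0, 1.0)  # booleans take no range

    def test_event_rejects_non_finite(self):
        with pytest.raises(CohortValidationError):
            Event("hr", 80.0, float("nan"), 0)
        with pytest.raises(CohortValidationError):
            Event("hr", float("inf"), 0.0, 0)

    def test_events_sorted_with_tiebreak(self):
        demo = Demographics(gender="female", age_group="40-49")
        events = [
            Event("b", 1.0, 5.0, 2),
            Event("a", 1.0, 5.0, 2),
            Event("c", 1.0, 1.0, 9),
        ]
        p = Patient("p", demo, events, 0)
        assert [(e.time, e.collection_id, e.variable_id) for e in p.events] == [
            (1.0, 9, "c"), (5.0, 2, "a"), (5.0, 2, "b"),
        ]

    def test_age_group_bins(self):
        assert age_group_of(0) == "0-9"
        assert age_group_of(65) == "60-69"
        assert age_group_of(97) == "90+"

    def test_cohort_rejects_unknown_variable(self, variables):
        p = make_patient([0.0], var="not_a_variable")
        with pytest.raises(CohortValidationError):
            Cohort(patients=[p], variables=variables)


class TestIO:
    def test_round_trip_synthetic_cohort(self, tmp_path):
        cohort = simulate_cohort(SyntheticSpec(n_cases=3, seed=7))
        path, vpath = tmp_path / "c.jsonl", tmp_path / "v.yaml"
        write_cohort(cohort, path, variables_path=vpath)
        back = read_cohort(path, vpath)
        assert len(back.patients) == len(cohort.patients)
        assert back.observation_hours == cohort.observation_hours
        assert back.holdoff_hours == cohort.holdoff_hours
        assert set(back.variables) == set(cohort.variables)
        for a, b in zip(cohort.patients, back.patients):
            assert a.patient_id == b.patient_id
            assert a.label == b.label
            assert a.anchor_time == b.anchor_time
            assert a.demographics == b.demographics
            assert a.events == b.events  # bit-exact values and times

    def test_empty_cohort_round_trips(self, tmp_path, variables):
        cohort = Cohort(patients=[], variables=variables, holdoff_hours=10.0)
        path, vpath = tmp_path / "c.jsonl", tmp_path / "v.yaml"
        write_cohort(cohort, path, variables_path=vpath)
        back = read_cohort(path, vpath)
        assert back.patients == []

    def test_malformed_line_names_line_number(self, tmp_path, variables):
        cohort = simulate_cohort(SyntheticSpec(n_cases=1, seed=0))
        path, vpath = tmp_path / "c.jsonl", tmp_path / "v.yaml"
        write_cohort(cohort, path, variables_path=vpath)
        with open(path, "a") as fh:
            fh.write("{not json\n")
        with pytest.raises(CohortParseError, match="line 5"):  # 4 patients + bad line
            read_cohort(path, vpath)

    def test_nan_time_rejected(self, tmp_path):
        cohort = simulate_cohort(SyntheticSpec(n_cases=1, seed=0))
        path, vpath = tmp_path / "c.jsonl", tmp_path / "v.yaml"
        write_cohort(cohort, path, variables_path=vpath)
        with open(path, "w") as fh:
            fh.write('{"patient_id": "x", "label": 0, "anchor_time": 0.0, '
                     '"demographics": {"gender": "male", "age_group": "60-69"}, '
                     '"events": [["heart_rate", 80.0, NaN, 0]]}\n')
        with pytest.raises((CohortParseError, CohortValidationError)):
            read_cohort(path, vpath)


class TestWindowing:
    def test_interval_membership(self):
        # anchor 0, holdoff 10, obs 48 -> keep times in [-58, -10)
        p = make_patient([-60.0, -40.0, -5.0, -2.0])
        w = extract_observation_window(p, 48.0, 10.0)
        assert [e.time for e in w.events] == [-40.0]
        assert w.label == p.label and w.demographics == p.demographics

    def test_closed_lower_open_upper_boundary(self):
        p = make_patient([-48.0, 0.0])
        w = extract_observation_window(p, 48.0, 0.0)
        assert [e.time for e in w.events] == [-48.0]  # -48 kept, 0 excluded

    def test_all_events_late_yields_empty(self):
        p = make_patient([-3.0, -1.0])
        w = extract_observation_window(p, 48.0, 10.0)
        assert w.events == []

    def test_idempotent(self):
        p = make_patient([-60.0, -40.0, -20.0, -5.0])
        once = extract_observation_window(p, 48.0, 10.0)
        twice = extract_observation_window(once, 48.0, 10.0)
        assert once.events == twice.events


class TestTimeDeltas:
    def test_recency_lags(self):
        p = make_patient([0.0, 2.0, 5.0])
        assert compute_time_deltas(p).tolist() == [5.0, 3.0, 0.0]

    def test_single_and_simultaneous(self):
        assert compute_time_deltas(make_patient([4.0])).tolist() == [0.0]
        assert compute_time_deltas(make_patient([4.0, 4.0])).tolist() == [0.0, 0.0]

    def test_empty_window_errors(self):
        with pytest.raises(ValueError, match="no events"):
            compute_time_deltas(make_patient([]))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-1e5, 1e5), min_size=1, max_size=40))
    def test_nonnegative_antimonotone_zero_at_latest(self, times):
        p = make_patient(times)
        deltas = compute_time_deltas(p)
        assert (deltas >= 0).all()
        assert deltas[np.argmax([e.time for e in p.events])] == 0.0
        ts = np.array([e.time for e in p.events])
        order = np.argsort(ts)
        assert (np.diff(deltas[order]) <= 1e-9).all()  # later event, smaller lag


class TestMatching:
    def pool(self, n, gender="male", age="60-69"):
        demo = Demographics(gender=gender, age_group=age)
        return [Patient(f"c{i}", demo, [], 0) for i in range(n)]

    def test_ratio_controls_per_case(self):
        case = make_patient([-20.0], label=1, anchor=5.0)
        cohort = match_controls([case], self.pool(5), ratio=3, seed=0)
        assert len(cohort.patients) == 4
        controls = [p for p in cohort.patients if p.label == 0]
        assert all(p.anchor_time == 5.0 for p in controls)
        assert all(p.demographics == case.demographics for p in controls)

    def test_insufficient_matches_drops_case(self, caplog):
        case = make_patient([-20.0], label=1)
        cohort = match_controls([case], self.pool(2), ratio=3, seed=0)
        assert cohort.patients == []

    def test_same_seed_same_selection(self):
        cases = [make_patient([-20.0], label=1)]
        a = match_controls(cases, self.pool(20), ratio=3, seed=42)
        b = match_controls(cases, self.pool(20), ratio=3, seed=42)
        assert [p.patient_id for p in a.patients] == [p.patient_id for p in b.patients]

    def test_controls_not_reused_across_cases(self):
        cases = [make_patient([-20.0], label=1) for _ in range(3)]
        cohort = match_controls(cases, self.pool(9), ratio=3, seed=1)
        ids = [p.patient_id for p in cohort.patients if p.label == 0]
        assert len(ids) == len(set(ids)) == 9

    def test_bad_ratio(self):
        with pytest.raises(ValueError):
            match_controls([], [], ratio=0, seed=0)

    def test_nonzero_pool_label_rejected(self):
        with pytest.raises(ValueError):
            match_controls([], [make_patient([0.0], label=1)], ratio=1, seed=0)
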
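"""Domain types and I/O for irregular EHR event streams.

The unit of data is an *event*: one observed measurement of one clinical
variable (a vital sign or lab test) at one point in time.  A *collection*
groups events recorded at the same timestamp (one vital-sign check).  A
patient is static demographics plus an ordered event stream plus a binary
outcome label anchored at a clinical reference time (onset/death for cases,
the matched case's index time for controls).

Only observed measurements are represented; there is no imputation anywhere
in this package — a variable missing from a collection simply contributes no
event.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import yaml

logger = logging.getLogger(__name__)

GENDERS = ("male", "female", "other")

#: Decade age bins used for demographic embedding and case-control matching.
AGE_GROUPS = tuple(f"{10 * i}-{10 * i + 9}" for i in range(9)) + ("90+",)


class CohortParseError(ValueError):
    """Raised when an event-stream or variable-dictionary file is malformed."""


class CohortValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


def age_group_of(age_years: float) -> str:
    """Map an age in years to its decade bin ('0-9' ... '80-89', '90+')."""
    if age_years < 0:
        raise ValueError(f"negative age: {age_years}")
    i = int(age_years // 10)
    return AGE_GROUPS[min(i, 9)]


@dataclass(frozen=True)
class VariableSpec:
    """Definition of one clinical variable.

    ``v_min``/``v_max`` bound the physiologically representable range and
    normalize values for the sinusoidal value embedding; ``normal_low``/
    ``normal_high`` delimit the clinically normal range used by the
    five-level binning of the interpretability module.
    """

    variable_id: str
    kind: str  # {"boolean", "real"}
    v_min: float | None = None
    v_max: float | None = None
    normal_low: float | None = None
    normal_high: float | None = None
    display_name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("boolean", "real"):
            raise CohortValidationError(
                f"{self.variable_id}: kind must be 'boolean' or 'real', got {self.kind!r}"
            )
        if self.kind == "real":
            if self.v_min is None or self.v_max is None:
                raise CohortValidationError(f"{self.variable_id}: real variable needs v_min/v_max")
            if not self.v_min < self.v_max:
                raise CohortValidationError(
                    f"{self.variable_id}: v_min must be < v_max ({self.v_min} >= {self.v_max})"
                )
        else:
            if self.v_min is not None or self.v_max is not None:
                raise CohortValidationError(f"{self.variable_id}: boolean variable takes no range")
        if (self.normal_low is None) != (self.normal_high is None):
            raise CohortValidationError(f"{self.variable_id}: normal range needs both bounds")
        if self.normal_low is not None:
            if not self.normal_low < self.normal_high:
                raise CohortValidationError(f"{self.variable_id}: normal_low >= normal_high")
            if self.kind == "real" and not (
                self.v_min <= self.normal_low and self.normal_high <= self.v_max
            ):
                raise CohortValidationError(
                    f"{self.variable_id}: normal range outside [v_min, v_max]"
                )

    def clamp(self, value: float) -> float:
        """Clamp a real value into [v_min, v_max], warning if out of range."""
        if self.kind != "real":
            return value
        if value < self.v_min or value > self.v_max:
            logger.warning(
                "clamping %s value %g into [%g, %g]", self.variable_id, value, self.v_min, self.v_max
            )
            return min(max(value, self.v_min), self.v_max)
        return value


@dataclass(frozen=True)
class Event:
    """One observed measurement: (variable, value, time, collection).

    ``time`` is in hours on a patient-local clock (larger = later);
    ``collection_id`` groups simultaneous measurements.  Boolean events
    carry value 1.0.
    """

    variable_id: str
    value: float
    time: float
    collection_id: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise CohortValidationError(f"event time must be finite, got {self.time}")
        if not math.isfinite(self.value):
            raise CohortValidationError(f"event value must be finite, got {self.value}")


@dataclass(frozen=True)
class Demographics:
    """Static attributes: gender and decade age group (|d| = 2 attributes)."""

    gender: str
    age_group: str

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise CohortValidationError(f"unknown gender {self.gender!r}")
        if self.age_group not in AGE_GROUPS:
            raise CohortValidationError(f"unknown age group {self.age_group!r}")

    def attributes(self) -> tuple[str, ...]:
        """The |d| attribute keys, one embedding-table row each."""
        return (f"age:{self.age_group}", f"gender:{self.gender}")


def _event_sort_key(e: Event) -> tuple:
    # ties at equal times broken by (collection_id, variable_id) for
    # reproducible serialization; the model itself is permutation-invariant
    return (e.time, e.collection_id, e.variable_id)


@dataclass
class Patient:
    """Demographics + ordered event stream + binary outcome label.

    ``anchor_time`` is the clinical reference point: onset/death time for
    cases, the matched case's index time for controls.  Events are kept
    sorted ascending by time.
    """

    patient_id: str
    demographics: Demographics
    events: list[Event]
    label: int
    anchor_time: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise CohortValidationError(f"label must be 0/1, got {self.label}")
        self.events = sorted(self.events, key=_event_sort_key)

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class Cohort:
    """A set of patients sharing one variable dictionary and window config."""

    patients: list[Patient]
    variables: dict[str, VariableSpec]
    observation_hours: float = 48.0
    holdoff_hours: float = 0.0

    def __post_init__(self) -> None:
        for p in self.patients:
            for e in p.events:
                if e.variable_id not in self.variables:
                    raise CohortValidationError(
                        f"patient {p.patient_id}: unknown variable {e.variable_id!r}"
                    )

    @property
    def cases(self) -> list[Patient]:
        return [p for p in self.patients if p.label == 1]

    @property
    def controls(self) -> list[Patient]:
        return [p for p in self.patients if p.label == 0]


# ---------------------------------------------------------------------------
# File I/O
#
# Event-stream file: UTF-8 line-delimited JSON, one patient per line.
# Variable dictionary: YAML with window config and one record per variable.
# ---------------------------------------------------------------------------


def read_variables(path) -> tuple[dict[str, VariableSpec], float, float]:
    """Read a variable-dictionary YAML file.

    Returns (variables, observation_hours, holdoff_hours).
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "variables" not in doc:
        raise CohortParseError(f"{path}: expected a mapping with a 'variables' list")
    variables: dict[str, VariableSpec] = {}
    for rec in doc["variables"]:
        spec = VariableSpec(**rec)
        if spec.variable_id in variables:
            raise CohortParseError(f"{path}: duplicate variable {spec.variable_id!r}")
        variables[spec.variable_id] = spec
    obs = float(doc.get("observation_hours", 48.0))
    holdoff = float(doc.get("holdoff_hours", 0.0))
    return variables, obs, holdoff


def write_variables(cohort: Cohort, path) -> None:
    """Write the cohort's variable dictionary and window config as YAML."""
    doc = {
        "observation_hours": cohort.observation_hours,
        "holdoff_hours": cohort.holdoff_hours,
        "variables": [
            {k: v for k, v in vars(s).items() if v is not None and v != ""}
            for s in cohort.variables.values()
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _patient_to_record(p: Patient) -> dict:
    return {
        "patient_id": p.patient_id,
        "label": p.label,
        "anchor_time": p.anchor_time,
        "demographics": {"gender": p.demographics.gender, "age_group": p.demographics.age_group},
        "events": [[e.variable_id, e.value, e.time, e.collection_id] for e in p.events],
    }


def _patient_from_record(rec: dict, lineno: int) -> Patient:
    try:
        demo = Demographics(**rec["demographics"])
        events = [
            Event(variable_id=v, value=float(val), time=float(t), collection_id=int(c))
            for v, val, t, c in rec["events"]
        ]
        return Patient(
            patient_id=str(rec["patient_id"]),
            demographics=demo,
            events=events,
            label=int(rec["label"]),
            anchor_time=float(rec["anchor_time"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CohortParseError(f"line {lineno}: {exc}") from exc


def read_cohort(path, variables_path) -> Cohort:
    """Read a cohort from an event-stream JSONL file plus variable dictionary.

    Events are re-sorted per patient; unknown variable ids are rejected.
    Raises :class:`CohortParseError` (with line number) on malformed lines and
    :class:`CohortValidationError` on invariant violations.
    """
    variables, obs, holdoff = read_variables(variables_path)
    patients: list[Patient] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortParseError(f"line {lineno}: invalid JSON: {exc}") from exc
            patients.append(_patient_from_record(rec, lineno))
    return Cohort(
        patients=patients, variables=variables, observation_hours=obs, holdoff_hours=holdoff
    )


def write_cohort(cohort: Cohort, path, variables_path=None) -> None:
    """Write a cohort as event-stream JSONL (and optionally its variables YAML).

    ``read_cohort(write_cohort(c))`` reproduces every field exactly for
    decimal-representable values (floats serialized at full precision).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for p in cohort.patients:
            fh.write(json.dumps(_patient_to_record(p)) + "\n")
    if variables_path is not None:
        write_variables(cohort, variables_path)


# ---------------------------------------------------------------------------
# Windowing, time deltas, matching
# ---------------------------------------------------------------------------


def extract_observation_window(
    patient: Patient, observation_hours: float, holdoff_hours: float
) -> Patient:
    """Restrict a patient to the observation window before the hold-off gap.

    Keeps events with time in the half-open interval
    ``[anchor - holdoff - observation, anchor - holdoff)`` — closed at the
    older edge.  Data inside the hold-off window (the prediction gap) are
    excluded.  Label and demographics are unchanged; an empty result is
    valid and left to the caller to exclude.
    """
    end = patient.anchor_time - holdoff_hours
    start = end - observation_hours
    kept = [e for e in patient.events if start <= e.time < end]
    return replace(patient, events=kept)


def compute_time_deltas(patient: Patient) -> np.ndarray:
    """Per-event recency lag in hours behind the most recent event in the window.

    The i-th entry is ``max(event times) - time_i``; the latest event has
    delta 0 and all deltas are non-negative.  Raises on an empty stream.
    """
    if not patient.events:
        raise ValueError(f"patient {patient.patient_id}: no events in window")
    times = np.array([e.time for e in patient.events], dtype=float)
    return times.max() - times


def match_controls(
    cases: list[Patient],
    pool: list[Patient],
    ratio: int = 3,
    seed: int = 0,
    *,
    variables: dict[str, VariableSpec] | None = None,
    observation_hours: float = 48.0,
    holdoff_hours: float = 0.0,
) -> Cohort:
    """Age/gender-matched case-control selection (ratio controls per case).

    For each case, ``ratio`` pool patients with identical (age_group, gender)
    are sampled without replacement (controls are never reused across cases)
    with the seeded generator, and each selected control inherits the case's
    anchor time.  Cases with insufficient eligible matches are dropped with a
    logged warning.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    for p in pool:
        if p.label != 0:
            raise ValueError(f"pool patient {p.patient_id} has label {p.label}, expected 0")
    rng = np.random.default_rng(seed)
    by_stratum: dict[tuple[str, str], list[Patient]] = {}
    for p in pool:
        by_stratum.setdefault((p.demographics.age_group, p.demographics.gender), []).append(p)

    matched: list[Patient] = []
    dropped = 0
    for case in cases:
        key = (case.demographics.age_group, case.demographics.gender)
        eligible = by_stratum.get(key, [])
        if len(eligible) < ratio:
            logger.warning(
                "case %s dropped: %d eligible controls for stratum %s (need %d)",
                case.patient_id, len(eligible), key, ratio,
            )
            dropped += 1
            continue
        idx = rng.choice(len(eligible), size=ratio, replace=False)
        chosen = [eligible[i] for i in sorted(idx)]
        for c in chosen:
            eligible.remove(c)
        matched.append(case)
        matched.extend(replace(c, anchor_time=case.anchor_time) for c in chosen)
    if dropped:
        logger.warning("match_controls: dropped %d/%d cases", dropped, len(cases))
    if variables is None:
        variables = {}
        seen = {e.variable_id for p in matched for e in p.events}
        variables = {v: VariableSpec(v, "boolean") for v in seen}
    return Cohort(
        patients=matched,
        variables=variables,
        observation_hours=observation_hours,
        holdoff_hours=holdoff_hours,
    )
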
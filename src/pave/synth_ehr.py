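"""Synthetic ICU-style cohort simulator with planted interactive risk patterns.

Real sepsis/mortality cohorts are built from proprietary or credential-gated
ICU databases; this module generates structurally similar data so every other
module is testable: irregular vital-sign collections (exponential
inter-arrival times), per-variable normal ranges, heavy per-cell missingness,
1:3 age/gender-matched controls, and a planted *two-event* risk pattern.

The planted pattern is deliberately interactive, mirroring the clinical
motivation that some event combinations are dangerous only jointly: every
patient — case or control — shows out-of-range excursions of both planted
variables somewhere in the window, but only case patients show them
*simultaneously* (in the same collection), and those co-timed excursions are
drawn from the upper (very-high) part of the out-of-range band.  Marginal
presence of either excursion is therefore nearly uninformative, while
co-occurrence is highly predictive.

Everything here is invented plumbing shaped by typical ICU summary
statistics (about 34 collections and ~190 observed events per 48 h window,
~30% of collection cells missing); it makes no attempt to reproduce real
marginal distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .ehr_data import (
    AGE_GROUPS,
    Cohort,
    Demographics,
    Event,
    Patient,
    VariableSpec,
    extract_observation_window,
    match_controls,
)

logger = logging.getLogger(__name__)


def default_variables() -> list[VariableSpec]:
    """Eight vital-sign variables with physiologic bounds and normal ranges."""
    rows = [
        ("heart_rate", 20, 220, 60, 100, "Heart rate"),
        ("resp_rate", 4, 60, 12, 20, "Respiratory rate"),
        ("temperature", 30, 43, 36.0, 38.0, "Temperature"),
        ("sysbp", 50, 250, 90, 140, "Systolic blood pressure"),
        ("diasbp", 30, 150, 60, 90, "Diastolic blood pressure"),
        ("meanbp", 40, 180, 70, 105, "Mean blood pressure"),
        ("spo2", 50, 100, 94, 100, "SPO2"),
        ("glucose", 30, 600, 70, 140, "Glucose"),
    ]
    return [
        VariableSpec(vid, "real", float(lo), float(hi), float(nl), float(nh), name)
        for vid, lo, hi, nl, nh, name in rows
    ]


#: Which out-of-range side each variable's excursions go to by default.
EXCURSION_SIDE = {
    "heart_rate": "high",
    "resp_rate": "high",
    "temperature": "high",
    "sysbp": "high",
    "diasbp": "low",
    "meanbp": "low",
    "spo2": "low",
    "glucose": "high",
}


@dataclass(frozen=True)
class PlantedPattern:
    """A two-event co-occurrence pattern that raises risk only jointly.

    ``joint_risk`` is the probability a case patient carries the co-timed
    excursions; ``marginal_risk`` the probability any patient carries the
    separated singleton excursions of each planted variable alone.
    """

    variable_a: str = "heart_rate"
    variable_b: str = "resp_rate"
    level_a: str = "very_high"
    level_b: str = "very_high"
    joint_risk: float = 0.95
    marginal_risk: float = 0.93

    def __post_init__(self) -> None:
        for r, name in ((self.joint_risk, "joint_risk"), (self.marginal_risk, "marginal_risk")):
            if not 0.0 < r < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {r}")
        if not self.joint_risk > self.marginal_risk:
            raise ValueError("joint_risk must exceed marginal_risk")

    def side(self, which: str) -> str:
        level = self.level_a if which == "a" else self.level_b
        return "high" if level in ("high", "very_high") else "low"


@dataclass
class SyntheticSpec:
    """All knobs of the simulator; the defaults define the benchmark cohort."""

    variables: list[VariableSpec] = field(default_factory=default_variables)
    n_cases: int = 100
    control_ratio: int = 3
    observation_hours: float = 48.0
    holdoff_hours: float = 10.0
    mean_collections: float = 34.0  # expected collections inside the window
    missing_rate: float = 0.3  # per (collection, variable) cell
    baseline_risk: float = 0.02  # chance a control shows the co-timed pair anyway
    patterns: list[PlantedPattern] = field(default_factory=lambda: [PlantedPattern()])
    noise_sd: dict[str, float] | None = None  # default: normal-range width / 8
    n_joint_collections: int = 5  # co-timed excursion collections per carrier case
    n_singleton_collections: int = 3  # separated excursions per planted variable
    other_excursion_rate: float = 0.5  # per non-planted variable
    joint_timing: str = "any"  # "any" | "late_cases" (timing-only signal, see below)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for p_ in (self.missing_rate, self.baseline_risk, self.other_excursion_rate):
            if not 0.0 <= p_ <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p_}")

    @property
    def variable_map(self) -> dict[str, VariableSpec]:
        return {v.variable_id: v for v in self.variables}


def _side_value(spec: VariableSpec, side: str, u: float) -> float:
    """Value at fraction ``u`` of the out-of-range span on the given side."""
    if side == "high":
        return spec.normal_high + u * (spec.v_max - spec.normal_high)
    return spec.normal_low - u * (spec.normal_low - spec.v_min)


def simulate_patient(
    spec: SyntheticSpec,
    is_case: bool,
    rng: np.random.Generator,
    demographics: Demographics | None = None,
    patient_id: str = "p0",
) -> Patient:
    """Simulate one patient's event stream.

    Collections arrive as a Poisson process over the full history
    ``[-(observation + holdoff), 0)`` (anchor at time 0); base values sit
    inside the normal range with Gaussian noise; excursions are written on
    top (inside the observation window only); per-cell missingness is
    applied last, so excursion cells can be lost like any others.
    """
    vmap = spec.variable_map
    if demographics is None:
        demographics = Demographics(
            gender=str(rng.choice(["male", "female"])),
            age_group=str(rng.choice(AGE_GROUPS[4:9])),  # 40-49 .. 80-89
        )
    window_end = -spec.holdoff_hours
    window_start = window_end - spec.observation_hours
    total_start = window_start

    # irregular collection times: exponential inter-arrivals
    rate = spec.mean_collections / spec.observation_hours
    times: list[float] = []
    t = total_start
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= 0.0:
            break
        times.append(t)
    m = len(times)
    var_ids = list(vmap)
    n_vars = len(var_ids)

    # base process: mid-normal plus noise
    values = np.empty((m, n_vars))
    for j, vid in enumerate(var_ids):
        s = vmap[vid]
        mid = 0.5 * (s.normal_low + s.normal_high)
        width = s.normal_high - s.normal_low
        sd = (spec.noise_sd or {}).get(vid, width / 8.0)
        values[:, j] = mid + rng.normal(0.0, sd, size=m)

    col = {vid: j for j, vid in enumerate(var_ids)}
    in_window = [i for i, ti in enumerate(times) if window_start <= ti < window_end]

    def plant(idx: int, vid: str, side: str, u_lo: float, u_hi: float) -> None:
        values[idx, col[vid]] = _side_value(vmap[vid], side, rng.uniform(u_lo, u_hi))

    for pat in spec.patterns:
        if not in_window:
            break
        # separated singleton excursions: one planted variable in each half of
        # the window (which half is randomized), never co-timed
        halves = [
            [i for i in in_window if times[i] < window_start + spec.observation_hours / 2],
            [i for i in in_window if times[i] >= window_start + spec.observation_hours / 2],
        ]
        order = [0, 1] if rng.random() < 0.5 else [1, 0]
        for which, vid, half in (
            ("a", pat.variable_a, halves[order[0]]),
            ("b", pat.variable_b, halves[order[1]]),
        ):
            if half and rng.random() < pat.marginal_risk:
                k = min(spec.n_singleton_collections, len(half))
                for i in rng.choice(len(half), size=k, replace=False):
                    plant(half[i], vid, pat.side(which), 0.05, 1.0)
        # co-timed joint excursions, very-high band.  In the default mode the
        # signal is the co-occurrence itself (cases only); in "late_cases"
        # mode both classes show co-timed excursions equally often but cases
        # show them in the most recent third of the window and controls in
        # the oldest third, so only their *timing* separates the classes.
        if spec.joint_timing == "late_cases":
            p_joint = pat.joint_risk
            third = spec.observation_hours / 3.0
            if is_case:
                pool = [i for i in in_window if times[i] >= window_end - third]
            else:
                pool = [i for i in in_window if times[i] < window_start + third]
        else:
            p_joint = pat.joint_risk if is_case else spec.baseline_risk
            pool = in_window
        if pool and rng.random() < p_joint:
            k = min(spec.n_joint_collections, len(pool))
            for i in rng.choice(len(pool), size=k, replace=False):
                plant(pool[i], pat.variable_a, pat.side("a"), 0.6, 0.98)
                plant(pool[i], pat.variable_b, pat.side("b"), 0.6, 0.98)

    planted_vars = {p.variable_a for p in spec.patterns} | {
        p.variable_b for p in spec.patterns
    }
    for vid in var_ids:
        if vid in planted_vars or not in_window:
            continue
        if rng.random() < spec.other_excursion_rate:
            i = int(rng.choice(len(in_window)))
            plant(in_window[i], vid, EXCURSION_SIDE.get(vid, "high"), 0.05, 1.0)

    # missingness last: each (collection, variable) cell observed independently
    observed = rng.random((m, n_vars)) >= spec.missing_rate

    events = []
    for i in range(m):
        for j, vid in enumerate(var_ids):
            if not observed[i, j]:
                continue
            s = vmap[vid]
            v = float(np.clip(values[i, j], s.v_min, s.v_max))
            events.append(Event(variable_id=vid, value=v, time=times[i], collection_id=i))
    return Patient(
        patient_id=patient_id,
        demographics=demographics,
        events=events,
        label=int(is_case),
        anchor_time=0.0,
    )


def simulate_cohort(spec: SyntheticSpec) -> Cohort:
    """Simulate cases plus an exactly matched 1:ratio control pool.

    For each case, ``control_ratio`` controls with identical (age group,
    gender) are generated and then selected through
    :func:`pave.ehr_data.match_controls`, so label prevalence is exactly
    ``1 / (1 + control_ratio)``.
    """
    rng = np.random.default_rng(spec.seed)
    cases = [
        simulate_patient(spec, True, rng, patient_id=f"case{i:04d}")
        for i in range(spec.n_cases)
    ]
    pool = []
    for i, case in enumerate(cases):
        for r in range(spec.control_ratio):
            pool.append(
                simulate_patient(
                    spec, False, rng,
                    demographics=case.demographics,
                    patient_id=f"ctrl{i:04d}_{r}",
                )
            )
    return match_controls(
        cases, pool,
        ratio=spec.control_ratio,
        seed=spec.seed,
        variables=spec.variable_map,
        observation_hours=spec.observation_hours,
        holdoff_hours=spec.holdoff_hours,
    )


# ---------------------------------------------------------------------------
# SIRS labeling (sepsis-2 rule)
# ---------------------------------------------------------------------------

SIRS_VARIABLES = ("temperature", "resp_rate", "paco2", "heart_rate", "wbc", "band")


def sirs_label(patient: Patient, variables: dict[str, VariableSpec] | None = None) -> bool:
    """Sepsis-2 SIRS rule: true iff at least two of four criteria are met.

    Criteria, evaluated over every observed value in the stream (a missing
    variable simply cannot meet its criterion):

    1. temperature > 38.0 or < 35.0 (deg C)
    2. respiratory rate > 20 /min or PaCO2 < 32 mmHg
    3. heart rate > 90 /min
    4. WBC > 12 k/uL or < 4 k/uL or band fraction > 10 %
    """
    obs: dict[str, list[float]] = {}
    for e in patient.events:
        obs.setdefault(e.variable_id, []).append(e.value)

    def any_(vid: str, pred) -> bool:
        return any(pred(v) for v in obs.get(vid, ()))

    criteria = [
        any_("temperature", lambda v: v > 38.0 or v < 35.0),
        any_("resp_rate", lambda v: v > 20.0) or any_("paco2", lambda v: v < 32.0),
        any_("heart_rate", lambda v: v > 90.0),
        any_("wbc", lambda v: v > 12.0 or v < 4.0) or any_("band", lambda v: v > 10.0),
    ]
    return sum(criteria) >= 2


# ---------------------------------------------------------------------------
# Interaction structure certification
# ---------------------------------------------------------------------------


def _beyond(value: float, spec: VariableSpec, side: str) -> bool:
    return value > spec.normal_high if side == "high" else value < spec.normal_low


def interaction_check(cohort: Cohort, pattern: PlantedPattern | None = None) -> dict[str, float]:
    """Certify that the planted signal is interactive, not marginal.

    Computes, per patient (observation window applied), binary indicators of
    each planted variable appearing beyond its normal bound anywhere, and a
    joint indicator of both appearing in the *same collection*.  Returns the
    AUROC of a logistic model on the two single-variable indicators and the
    AUROC of the joint indicator used directly as a score.  An interactive
    plant shows near-chance single AUROC and high joint AUROC.
    """
    if pattern is None:
        pattern = PlantedPattern()
    va, vb = pattern.variable_a, pattern.variable_b
    sa_, sb = pattern.side("a"), pattern.side("b")
    spec_a, spec_b = cohort.variables[va], cohort.variables[vb]

    X, joint, y = [], [], []
    for p in cohort.patients:
        w = extract_observation_window(p, cohort.observation_hours, cohort.holdoff_hours)
        a_cols = {e.collection_id for e in w.events if e.variable_id == va and _beyond(e.value, spec_a, sa_)}
        b_cols = {e.collection_id for e in w.events if e.variable_id == vb and _beyond(e.value, spec_b, sb)}
        X.append([float(bool(a_cols)), float(bool(b_cols))])
        joint.append(float(bool(a_cols & b_cols)))
        y.append(p.label)
    X, joint, y = np.array(X), np.array(joint), np.array(y)
    lr = LogisticRegression().fit(X, y)
    single_auroc = float(roc_auc_score(y, lr.predict_proba(X)[:, 1]))
    joint_auroc = float(roc_auc_score(y, joint))
    return {"single_indicator_auroc": single_auroc, "joint_indicator_auroc": joint_auroc}
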
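"""Pattern-level interpretability: contribution matrices and pattern ranking.

The attribution of the model to the ordered event pair (i, j) is
``C_ij = gamma_i * alpha_ij`` — the pattern weight of event i times the
self-attention weight event i puts on event j.  Because both factors are
softmax outputs, the matrix C is non-negative and sums to exactly 1 per
patient: it is a probability distribution of "blame" over event pairs.

For cohort-level summaries each event is first mapped to a five-level bin
(very_low / low / normal / high / very_high) by comparing its value to the
variable's normal range and then splitting each out-of-range side at the
median of the out-of-range values observed on that side.  Contributions are
then aggregated per unordered (variable, level)-pair key and averaged across
case patients (AVG-CR, in percent).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .ehr_data import Cohort, Patient, VariableSpec
from .pave_model import AttentionTrace, PaveModel

LEVELS = ("very_low", "low", "normal", "high", "very_high")

#: Placeholder second member for the (event, itself) diagonal keys, which are
#: tracked for mass conservation but excluded from the two-event ranking.
SELF_KEY = ("__self__", "itself")


@dataclass(frozen=True)
class PatternContribution:
    """One row of the cohort-level pattern ranking."""

    event_a: tuple[str, str]  # (variable_id, level)
    event_b: tuple[str, str]
    avg_cr: float  # percent of per-patient contribution mass

    @property
    def is_self(self) -> bool:
        return self.event_b == SELF_KEY


@dataclass
class ContributionMatrix:
    """Per-patient contribution matrix with event annotations."""

    C: np.ndarray  # (n, n), non-negative, sums to 1
    event_index: list[tuple[str, str, float]]  # (variable_id, level, time)


def side_medians(
    patients: list[Patient], variables: dict[str, VariableSpec]
) -> dict[str, tuple[float | None, float | None]]:
    """Per-variable medians of the out-of-range values on each side.

    Returns ``{variable_id: (median_of_low_values, median_of_high_values)}``;
    a side with no out-of-range observations gets ``None`` (any later value
    on that side then falls in the inner bin).
    """
    lows: dict[str, list[float]] = {v: [] for v in variables}
    highs: dict[str, list[float]] = {v: [] for v in variables}
    for p in patients:
        for e in p.events:
            spec = variables[e.variable_id]
            if spec.normal_low is None:
                continue
            if e.value < spec.normal_low:
                lows[e.variable_id].append(e.value)
            elif e.value > spec.normal_high:
                highs[e.variable_id].append(e.value)
    out = {}
    for vid in variables:
        med_lo = float(np.median(lows[vid])) if lows[vid] else None
        med_hi = float(np.median(highs[vid])) if highs[vid] else None
        out[vid] = (med_lo, med_hi)
    return out


def bin_value(
    value: float,
    spec: VariableSpec,
    side_median_high: float | None,
    side_median_low: float | None,
) -> str:
    """Map a value to one of five levels relative to its normal range.

    In-range values are ``normal``; above-range values split into ``high``
    vs ``very_high`` at the median of the observed high values (ties go to
    the inner bin), and symmetrically below.
    """
    if spec.normal_low is None or spec.normal_high is None:
        raise ValueError(f"{spec.variable_id}: binning requires a normal range")
    if spec.normal_low <= value <= spec.normal_high:
        return "normal"
    if value > spec.normal_high:
        if side_median_high is None or value <= side_median_high:
            return "high"
        return "very_high"
    if side_median_low is None or value >= side_median_low:
        return "low"
    return "very_low"


def contribution_matrix(
    trace: AttentionTrace,
    patient: Patient | None = None,
    variables: dict[str, VariableSpec] | None = None,
    medians: dict[str, tuple[float | None, float | None]] | None = None,
) -> ContributionMatrix:
    """Build ``C_ij = gamma_i alpha_ij`` with optional event annotations."""
    C = trace.gamma[:, None] * trace.alpha
    index: list[tuple[str, str, float]] = []
    if patient is not None:
        for e in patient.events:
            level = ""
            if variables is not None:
                spec = variables[e.variable_id]
                if spec.normal_low is not None:
                    lo, hi = (medians or {}).get(e.variable_id, (None, None))
                    level = bin_value(e.value, spec, hi, lo)
            index.append((e.variable_id, level, e.time))
    return ContributionMatrix(C=C, event_index=index)


def _pair_key(a: tuple[str, str], b: tuple[str, str]) -> tuple:
    return (a, b) if a <= b else (b, a)


def pattern_contributions(
    cohort: Cohort,
    model: PaveModel,
    *,
    medians_from: str = "all",
    denominator: str = "patient",
) -> dict[tuple, float]:
    """Average contribution (percent) per binned pattern key over case patients.

    For each case patient the contribution matrix is computed, every (i, j)
    cell is assigned to the unordered ((variable, level), (variable, level))
    key of its two events (diagonal cells go to an ``(event, itself)`` key),
    and cell masses are summed per key.  With ``denominator='patient'`` each
    patient's key masses (which sum to 100%) are averaged over all case
    patients, keys absent in a patient counting 0; ``denominator='occurrence'``
    averages only over the patients in which the key occurs.

    ``medians_from`` selects whose out-of-range values define the high/low
    side medians: the whole cohort (``'all'``, default) or cases only.
    """
    cases = cohort.cases
    if not cases:
        raise ValueError("cohort contains no case patients")
    pool = cohort.patients if medians_from == "all" else cases
    meds = side_medians(pool, cohort.variables)

    totals: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    for patient in cases:
        trace = model.forward(patient)
        cm = contribution_matrix(trace, patient, cohort.variables, meds)
        keys = [(vid, level) for vid, level, _t in cm.event_index]
        per_patient: dict[tuple, float] = {}
        n = len(keys)
        for i in range(n):
            row = cm.C[i]
            for j in range(n):
                key = (
                    _pair_key(keys[i], keys[j]) if i != j else (keys[i], SELF_KEY)
                )
                per_patient[key] = per_patient.get(key, 0.0) + row[j]
        for key, mass in per_patient.items():
            totals[key] = totals.get(key, 0.0) + 100.0 * mass
            counts[key] = counts.get(key, 0) + 1
    if denominator == "patient":
        return {k: v / len(cases) for k, v in totals.items()}
    return {k: v / counts[k] for k, v in totals.items()}


def rank_patterns(
    cohort: Cohort,
    model: PaveModel,
    top_k: int = 10,
    *,
    medians_from: str = "all",
    denominator: str = "patient",
) -> list[PatternContribution]:
    """Top two-event patterns by average contribution rate among cases.

    Diagonal (event, itself) mass is excluded; ties broken by key for
    reproducibility.
    """
    contrib = pattern_contributions(
        cohort, model, medians_from=medians_from, denominator=denominator
    )
    two_event = [
        PatternContribution(event_a=k[0], event_b=k[1], avg_cr=v)
        for k, v in contrib.items()
        if k[1] != SELF_KEY
    ]
    two_event.sort(key=lambda pc: (-pc.avg_cr, pc.event_a, pc.event_b))
    return two_event[:top_k]


def explain_patient(
    patient: Patient,
    model: PaveModel,
    threshold: float = 0.01,
    *,
    variables: dict[str, VariableSpec] | None = None,
    medians: dict[str, tuple[float | None, float | None]] | None = None,
    path=None,
) -> dict:
    """Per-patient explanation: risk plus all pairs with ``C_ij >= threshold``.

    Returns (and optionally writes as JSON) a record with the predicted risk
    and, for each retained ordered pair, both events' variables, binned
    levels, times and the contribution.  Lowering the threshold yields a
    superset of pairs.
    """
    if variables is None:
        variables = model.stats.variables if model.stats else {}
    trace = model.forward(patient)
    cm = contribution_matrix(trace, patient, variables, medians)
    n = cm.C.shape[0]
    patterns = []
    for i in range(n):
        for j in range(n):
            if cm.C[i, j] >= threshold:
                vi, li, ti = cm.event_index[i]
                vj, lj, tj = cm.event_index[j]
                patterns.append(
                    {
                        "event_i": {"variable": vi, "level": li, "time": ti},
                        "event_j": {"variable": vj, "level": lj, "time": tj},
                        "contribution": float(cm.C[i, j]),
                    }
                )
    patterns.sort(key=lambda r: -r["contribution"])
    record = {"patient_id": patient.patient_id, "y": trace.y, "patterns": patterns}
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(record, fh, indent=1)
    return record
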
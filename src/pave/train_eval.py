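"""Training loop, AUROC evaluation, rotating tenfold cross-validation.

Optimization is plain mini-batch Adam on the binary cross-entropy, with
per-patient sequences processed at their natural length (gradients averaged
over the mini-batch, which is exactly what a padded-and-masked batch would
compute).  Normalization statistics — per-variable value ranges and means
and the maximum time lag ``t_m`` — are always derived from the training
split only, so no information leaks from validation or test patients.

Cross-validation follows a rotating 7/1/2 scheme over 10 label-stratified
sets: fold f trains on sets f..f+6, validates on f+7 and tests on f+8, f+9
(indices mod 10), so every patient is tested exactly twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from .ehr_data import AGE_GROUPS, GENDERS, Cohort, Patient, extract_observation_window
from .embeddings import EmbeddingConfig
from .pave_model import ModelVariant, PaveModel

logger = logging.getLogger(__name__)

DEMO_VOCAB = [f"age:{g}" for g in AGE_GROUPS] + [f"gender:{g}" for g in GENDERS]


@dataclass
class TrainConfig:
    """Optimizer and model-size settings.

    The defaults are the desk-scale preset (k=32, 20 epochs, Adam lr 2e-3,
    batch 16) sized for synthetic cohorts of a few hundred patients;
    :meth:`paper_scale` restores the full-scale setting (k=512, 50 epochs,
    lr 1e-4, batch 64).
    """

    learning_rate: float = 2e-3
    batch_size: int = 16
    epochs: int = 20
    k: int = 32
    seed: int = 0
    variant: ModelVariant = field(default_factory=lambda: ModelVariant())
    j_base: int = 0
    include_self: bool = True
    scale_scores: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def paper_scale(cls, **kw) -> "TrainConfig":
        kw.setdefault("learning_rate", 1e-4)
        kw.setdefault("batch_size", 64)
        kw.setdefault("epochs", 50)
        kw.setdefault("k", 512)
        return cls(**kw)


@dataclass
class CVResult:
    """Per-fold AUROCs with their mean and standard deviation."""

    fold_aurocs: list[float]
    mean: float
    std: float

    @classmethod
    def from_folds(cls, aurocs: list[float]) -> "CVResult":
        arr = np.asarray(aurocs, dtype=float)
        return cls(fold_aurocs=list(map(float, arr)), mean=float(arr.mean()), std=float(arr.std()))


class Adam:
    """Standard Adam with bias correction, updating parameters in place."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p[...] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def prepare_patients(cohort: Cohort) -> list[Patient]:
    """Apply the observation window and drop patients left with no events."""
    out, empty = [], 0
    for p in cohort.patients:
        w = extract_observation_window(p, cohort.observation_hours, cohort.holdoff_hours)
        if w.events:
            out.append(w)
        else:
            empty += 1
    if empty:
        logger.info("excluded %d patients with empty observation windows", empty)
    return out


def _check_two_classes(patients: list[Patient], what: str) -> None:
    labels = {p.label for p in patients}
    if labels != {0, 1}:
        raise ValueError(f"{what} requires both classes, got labels {sorted(labels)}")


def train(
    cohort: Cohort,
    config: TrainConfig,
    val_cohort: Cohort | None = None,
) -> tuple[PaveModel, list[dict]]:
    """Train a PAVE model; returns (model, per-epoch history).

    When a validation cohort is given, the parameters with the best
    validation AUROC across epochs are restored at the end (the run always
    completes all epochs); otherwise the final parameters are kept.
    """
    patients = prepare_patients(cohort)
    _check_two_classes(patients, "training")
    val_patients = prepare_patients(val_cohort) if val_cohort is not None else None

    vocab = sorted(cohort.variables)
    model = PaveModel(
        vocab, DEMO_VOCAB,
        EmbeddingConfig(k=config.k, t_m=1.0, j_base=config.j_base),
        variant=config.variant, seed=config.seed,
        include_self=config.include_self, scale_scores=config.scale_scores,
    )
    model.fit_stats(patients, cohort.variables)
    encs = [model.encode(p) for p in patients]
    val_encs = [model.encode(p) for p in val_patients] if val_patients else None

    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best_auroc, best_params = -np.inf, None

    for epoch in range(config.epochs):
        order = rng.permutation(len(encs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            acc = {k: np.zeros_like(v) for k, v in params.items()}
            for i in batch:
                loss, grads, _y = model.loss_and_grads(encs[i])
                losses.append(loss)
                for k in acc:
                    acc[k] += grads[k]
            for k in acc:
                acc[k] /= len(batch)
            opt.step(acc)
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_encs is not None:
            ys = [model._forward(e)["y"] for e in val_encs]
            labels = [e.label for e in val_encs]
            rec["val_auroc"] = float(roc_auc_score(labels, ys))
            if rec["val_auroc"] > best_auroc:
                best_auroc = rec["val_auroc"]
                best_params = {k: v.copy() for k, v in params.items()}
        history.append(rec)
        logger.info("epoch %d: %s", epoch, rec)

    if best_params is not None:
        for k, v in params.items():
            v[...] = best_params[k]
    return model, history


def evaluate_auroc(model: PaveModel, cohort: Cohort | list[Patient]) -> float:
    """Rank-based AUROC of predicted risks against labels (midrank ties)."""
    patients = prepare_patients(cohort) if isinstance(cohort, Cohort) else list(cohort)
    _check_two_classes(patients, "evaluation")
    ys = [model.predict(p) for p in patients]
    return float(roc_auc_score([p.label for p in patients], ys))


def stratified_sets(patients: list[Patient], n_sets: int, seed: int) -> list[list[Patient]]:
    """Partition patients into label-stratified sets of near-equal size."""
    rng = np.random.default_rng(seed)
    sets: list[list[Patient]] = [[] for _ in range(n_sets)]
    for label in (1, 0):
        group = [p for p in patients if p.label == label]
        for i in rng.permutation(len(group)):
            sets[min(range(n_sets), key=lambda s: len(sets[s]))].append(group[i])
    return sets


def _subcohort(cohort: Cohort, patients: list[Patient]) -> Cohort:
    return Cohort(
        patients=patients,
        variables=cohort.variables,
        observation_hours=cohort.observation_hours,
        holdoff_hours=cohort.holdoff_hours,
    )


def fold_indices(n_sets: int = 10, n_train: int = 7) -> list[tuple[list[int], int, list[int]]]:
    """Rotating (train sets, val set, test sets) index triples."""
    folds = []
    for f in range(n_sets):
        train_sets = [(f + i) % n_sets for i in range(n_train)]
        val_set = (f + n_train) % n_sets
        test_sets = [(f + n_train + 1 + i) % n_sets for i in range(n_sets - n_train - 1)]
        folds.append((train_sets, val_set, test_sets))
    return folds


def crossval(cohort: Cohort, config: TrainConfig, n_sets: int = 10) -> CVResult:
    """Rotating 7/1/2 tenfold cross-validation.

    Normalization statistics are refit inside every fold from its training
    sets only.  Requires at least ``n_sets`` patients per class.
    """
    for label in (0, 1):
        n = sum(1 for p in cohort.patients if p.label == label)
        if n < n_sets:
            raise ValueError(f"need >= {n_sets} patients of class {label}, got {n}")
    sets = stratified_sets(cohort.patients, n_sets, config.seed)
    aurocs = []
    for train_sets, val_set, test_sets in fold_indices(n_sets):
        train_p = [p for s in train_sets for p in sets[s]]
        test_p = [p for s in test_sets for p in sets[s]]
        model, _hist = train(
            _subcohort(cohort, train_p), config, val_cohort=_subcohort(cohort, sets[val_set])
        )
        aurocs.append(evaluate_auroc(model, _subcohort(cohort, test_p)))
    return CVResult.from_folds(aurocs)


def run_ablation(cohort: Cohort, config: TrainConfig, n_sets: int = 10) -> dict[str, CVResult]:
    """Cross-validate the full model and both ablations under identical folds."""
    results = {}
    for variant in (ModelVariant(True, True), ModelVariant(False, True), ModelVariant(True, False)):
        cfg = replace(config, variant=variant)
        results[variant.name] = crossval(cohort, cfg, n_sets=n_sets)
    return results
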
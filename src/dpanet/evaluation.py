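"""Patient-stratified cross-validation and metrics.

Splitting is always by PATIENT: all slices of a patient live in exactly one
fold, so no patient contributes to both train and test of the same fold.
Stratification is class-wise: within each class, patients are shuffled with
the seeded generator and dealt round-robin; the remainder patients of
successive classes are placed on the currently smallest folds so totals stay
balanced.  With 65 ER / 102 NER and k = 10 every fold gets 6-7 ER and 10-11
NER (16-17 patients).

Metrics default to slice level: each selected slice is scored independently;
accuracy thresholds the ER probability at 0.5 and AUC is the rank statistic
(concordant pairs + half ties over all ER x NER pairs).  A patient-level
option averages slice probabilities per patient first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .model import (
    DPAModel,
    ModelConfig,
    TrainConfig,
    TrainingSet,
    predict_proba,
    train,
)

__all__ = [
    "FoldAssignment",
    "MetricReport",
    "stratified_patient_folds",
    "select_slices",
    "auc",
    "accuracy",
    "build_slice_dataset",
    "cross_validate",
]


@dataclass
class FoldAssignment:
    k: int
    assignment: dict[str, int]  # patient_id -> fold

    def fold_patients(self, fold: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == fold]


@dataclass
class MetricReport:
    fold_accuracy: list[float]
    fold_auc: list[float]
    mean_accuracy: float
    sd_accuracy: float
    mean_auc: float
    sd_auc: float
    folds: FoldAssignment | None = None
    fold_seeds: list[int] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fold_accuracy": self.fold_accuracy,
            "fold_auc": self.fold_auc,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "fold_seeds": self.fold_seeds,
            "assignment": self.folds.assignment if self.folds else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def stratified_patient_folds(
    labels: dict[str, int], k: int, seed: int
) -> FoldAssignment:
    """Class-stratified patient-to-fold map; within-class sizes differ by <= 1."""
    classes = sorted(set(labels.values()))
    rng = np.random.default_rng(seed)
    counts = {c: sum(1 for v in labels.values() if v == c) for c in classes}
    for c in classes:
        if counts[c] < k:
            raise ValueError(f"class {c} has {counts[c]} patients, fewer than k={k}")
    fold_sizes = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for c in classes:
        pids = sorted(p for p, v in labels.items() if v == c)
        rng.shuffle(pids)
        base, extra = divmod(len(pids), k)
        # put this class's remainder on the currently lightest folds
        order = np.lexsort((np.arange(k), fold_sizes))
        per_fold = np.full(k, base)
        per_fold[order[:extra]] += 1
        idx = 0
        for f in range(k):
            for _ in range(per_fold[f]):
                assignment[pids[idx]] = f
                idx += 1
        fold_sizes += per_fold
    return FoldAssignment(k, assignment)


def select_slices(tumor_area_by_slice, margin: int = 2) -> list[int]:
    """Central slice (largest cross-section; ties -> lower index) +/- margin,
    restricted to slices that actually contain tumor."""
    areas = np.asarray(tumor_area_by_slice, dtype=float)
    if areas.size == 0 or (areas <= 0).all():
        raise ValueError("no slice with positive tumor area")
    center = int(np.argmax(areas))
    lo = max(center - margin, 0)
    hi = min(center + margin, areas.size - 1)
    return [i for i in range(lo, hi + 1) if areas[i] > 0]


def auc(scores, labels) -> float:
    """Rank-statistic AUC: P(score_ER > score_NER) + 1/2 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    return float(((scores > threshold).astype(int) == labels).mean())


def build_slice_dataset(patients, margin: int = 2) -> tuple[TrainingSet, np.ndarray]:
    """Stack the selected slices of each patient into a slice-level dataset.

    Returns the dataset plus the per-slice patient index (for patient-level
    aggregation).
    """
    images, clin, labels, owner = [], [], [], []
    for i, p in enumerate(patients):
        for s in select_slices(p.areas, margin):
            images.append(p.images[s])
            clin.append(p.clinical_vector)
            labels.append(p.label)
            owner.append(i)
    return (
        TrainingSet(
            np.stack(images).astype(np.float32),
            np.stack(clin).astype(np.float32),
            np.asarray(labels, dtype=int),
        ),
        np.asarray(owner, dtype=int),
    )


def _strip(dataset: TrainingSet, variant: str) -> TrainingSet:
    if variant == "clinical_only":
        return TrainingSet(None, dataset.clinical, dataset.labels)
    if variant == "image_only":
        return TrainingSet(dataset.images, None, dataset.labels)
    return dataset


def cross_validate(
    cohort,
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 10,
    seed: int = 0,
    margin: int = 2,
    level: str = "slice",
    label_shuffle: bool = False,
) -> MetricReport:
    """k-fold patient-stratified cross-validation of the phase-attention model.

    ``label_shuffle=True`` permutes patient labels once before splitting — a
    null control in which any measured AUC reflects overfitting/noise only.
    """
    patients = list(cohort.patients if hasattr(cohort, "patients") else cohort)
    if label_shuffle:
        import copy

        rng = np.random.default_rng(seed + 999_983)
        perm = rng.permutation([p.label for p in patients])
        patients = [copy.copy(p) for p in patients]
        for p, lab in zip(patients, perm):
            p.label = int(lab)
    labels = {p.patient_id: p.label for p in patients}
    folds = stratified_patient_folds(labels, k, seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s % (2**31 - 1)) for s in ss.generate_state(k)]
    accs, aucs, histories = [], [], []
    for f in range(k):
        test_ids = set(folds.fold_patients(f))
        train_p = [p for p in patients if p.patient_id not in test_ids]
        test_p = [p for p in patients if p.patient_id in test_ids]
        train_set, _ = build_slice_dataset(train_p, margin)
        test_set, owner = build_slice_dataset(test_p, margin)
        train_set = _strip(train_set, model_config.variant)
        test_set = _strip(test_set, model_config.variant)
        model = DPAModel(model_config, seed=fold_seeds[f])
        try:
            hist = train(
                model,
                train_set,
                TrainConfig(
                    batch_size=train_config.batch_size,
                    epochs=train_config.epochs,
                    learning_rate=train_config.learning_rate,
                    seed=fold_seeds[f],
                    augment=train_config.augment,
                ),
            )
        except Exception as exc:  # annotate with the failing fold
            raise RuntimeError(f"training failed in fold {f}: {exc}") from exc
        histories.append(hist)
        probs = predict_proba(model, test_set)[:, 0]
        y = test_set.labels
        if level == "patient":
            uniq = np.unique(owner)
            probs = np.array([probs[owner == u].mean() for u in uniq])
            y = np.array([y[owner == u][0] for u in uniq])
        accs.append(accuracy(probs, y))
        aucs.append(auc(probs, y))
    return MetricReport(
        accs,
        aucs,
        float(np.mean(accs)),
        float(np.std(accs, ddof=1)),
        float(np.mean(aucs)),
        float(np.std(aucs, ddof=1)),
        folds,
        fold_seeds,
        histories,
    )
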
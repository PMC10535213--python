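"""Experiment harness: subject splits, training, cross-validation, and the
with/without-IDM cross-subject comparison.

Subjects are split 0.6/0.2/0.2 into train / test / cross-subject sets; the
classifier is trained on all training-subject sequences (Adam, MSE loss),
assessed by ten-fold cross-validation within the training subjects, and
evaluated per subject with confusion matrices.  On cross subjects the
individual-difference module calibrates each subject's scores on half their
data and is scored on the other half, paired against the uncalibrated
predictions on the same half.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass

import numpy as np

from . import idm as idm_mod
from .features import FeatureTensor
from .model import (
    EmotionClassifier,
    ModelConfig,
    SequenceBatch,
    build_sequences,
    mse_loss,
    predict_class,
)
from .nn import Adam
from .synthetic import distort_scores

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "TrainingConfig",
    "split_subjects",
    "confusion_matrix",
    "accuracy_from_confusion",
    "concat_batches",
    "train_model",
    "run_cv",
    "train_full",
    "evaluate",
]


@dataclass(frozen=True)
class SplitPlan:
    train_subjects: tuple[int, ...]
    test_subjects: tuple[int, ...]
    cross_subjects: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.train_subjects), set(self.test_subjects), set(self.cross_subjects)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split subject sets must be pairwise disjoint")


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 100
    lr: float = 0.001
    batch_size: int = 32
    folds: int = 10
    seed: int = 0
    dimension: str = "valence"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.dimension not in ("valence", "arousal"):
            raise ValueError("dimension must be 'valence' or 'arousal'")


def split_subjects(
    subject_ids,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    leftover: str = "unassigned",
) -> SplitPlan:
    """Seeded shuffle, then floor(n * ratio) subjects per split in order
    train/test/cross.  With 32 subjects and default ratios: 19/6/6 with one
    subject left over; the leftover policy is ``unassigned`` (default) or
    ``train``.
    """
    subject_ids = list(subject_ids)
    if len(subject_ids) < 3:
        raise ValueError("need at least 3 subjects to split")
    if sum(ratios) > 1.0 + 1e-9 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be nonnegative and sum to at most 1")
    if leftover not in ("unassigned", "train"):
        raise ValueError("leftover policy must be 'unassigned' or 'train'")
    rng = np.random.default_rng(seed)
    order = [subject_ids[i] for i in rng.permutation(len(subject_ids))]
    n = len(order)
    n_train = math.floor(n * ratios[0])
    n_test = math.floor(n * ratios[1])
    n_cross = math.floor(n * ratios[2])
    train = order[:n_train]
    test = order[n_train : n_train + n_test]
    cross = order[n_train + n_test : n_train + n_test + n_cross]
    if leftover == "train":
        train = train + order[n_train + n_test + n_cross :]
    return SplitPlan(tuple(train), tuple(test), tuple(cross), seed=seed)


def confusion_matrix(predicted: np.ndarray, true: np.ndarray) -> np.ndarray:
    """2x2 counts; rows are predicted class, columns true class."""
    predicted = np.asarray(predicted, dtype=np.int64)
    true = np.asarray(true, dtype=np.int64)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true misaligned")
    cm = np.zeros((2, 2), dtype=np.int64)
    for p, t in zip(predicted, true):
        cm[p, t] += 1
    return cm


def accuracy_from_confusion(cm: np.ndarray) -> float:
    total = int(cm.sum())
    return float(np.trace(cm)) / total if total else float("nan")


def concat_batches(batches: list[SequenceBatch]) -> SequenceBatch:
    return SequenceBatch(
        inputs=np.concatenate([b.inputs for b in batches]),
        labels=np.concatenate([b.labels for b in batches]),
        subject_ids=np.concatenate([b.subject_ids for b in batches]),
        trial_index=np.concatenate([b.trial_index for b in batches]),
    )


def train_model(
    model: EmotionClassifier, batch: SequenceBatch, cfg: TrainingConfig
) -> list[float]:
    """Adam/MSE minibatch training; returns the per-epoch mean loss curve."""
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.lr)
    n = len(batch)
    losses = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            scores = model.forward(batch.inputs[idx], train=True, rng=rng)
            loss, dloss = mse_loss(scores, batch.labels[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (loss={loss}) at epoch {epoch}")
            model.backward(dloss)
            opt.step()
            epoch_loss += loss * idx.size
        losses.append(epoch_loss / n)
    return losses


def run_cv(
    batch: SequenceBatch,
    model_cfg: ModelConfig,
    train_cfg: TrainingConfig,
) -> dict:
    """K-fold cross-validation over training-subject sequences.

    Seeded fold assignment partitions the sequences (fold sizes differ by at
    most one); each fold trains a fresh model on the rest and scores the
    held-out fold.  Returns per-fold accuracies and their mean.
    """
    n = len(batch)
    if train_cfg.folds > n:
        raise ValueError("more folds than sequences")
    rng = np.random.default_rng(train_cfg.seed)
    assignment = np.repeat(np.arange(train_cfg.folds), -(-n // train_cfg.folds))[:n]
    assignment = assignment[rng.permutation(n)]
    fold_acc = []
    for fold in range(train_cfg.folds):
        hold = assignment == fold
        model = EmotionClassifier(model_cfg, seed=train_cfg.seed + fold)
        sub = SequenceBatch(
            inputs=batch.inputs[~hold],
            labels=batch.labels[~hold],
            subject_ids=batch.subject_ids[~hold],
            trial_index=batch.trial_index[~hold],
        )
        t0 = time.perf_counter()
        train_model(model, sub, train_cfg)
        scores = model.predict_scores(batch.inputs[hold])
        pred = predict_class(scores)
        true = np.argmax(batch.labels[hold], axis=1)
        acc = float(np.mean(pred == true))
        fold_acc.append(acc)
        logger.info("fold %d: acc=%.3f (%.1fs)", fold, acc, time.perf_counter() - t0)
    return {"fold_accuracies": fold_acc, "mean_accuracy": float(np.mean(fold_acc))}


def train_full(
    batch: SequenceBatch, model_cfg: ModelConfig, train_cfg: TrainingConfig
) -> tuple[EmotionClassifier, list[float]]:
    """Train one model on all supplied sequences; returns (model, loss curve)."""
    if len(batch) == 0:
        raise ValueError("empty training set")
    model = EmotionClassifier(model_cfg, seed=train_cfg.seed)
    losses = train_model(model, batch, train_cfg)
    return model, losses


def evaluate(
    model: EmotionClassifier,
    features_by_subject: dict[int, FeatureTensor],
    dimension: str = "valence",
    with_idm: bool = False,
    calib_fraction: float = 0.5,
    seed: int = 0,
    distortions: dict[int, object] | None = None,
) -> dict:
    """Per-subject evaluation report, optionally with IDM calibration.

    ``distortions`` optionally maps subject id to that subject's monotone
    response distortion (synthetic cohorts expose it on the profile); when
    given, raw model scores are passed through it before prediction, so the
    report measures what an uncorrected system would show for that subject.
    With ``with_idm`` the subject's observed scores are split into
    calibration/evaluation halves; both the uncalibrated and the calibrated
    accuracies are computed on the evaluation half only.
    """
    report: dict = {
        "dimension": dimension,
        "with_idm": with_idm,
        "seed": seed,
        "subjects": {},
    }
    for sid, feats in sorted(features_by_subject.items()):
        batch = build_sequences(feats, dimension=dimension, seq_len=model.cfg.seq_len)
        scores = model.predict_scores(batch.inputs)
        if distortions and sid in distortions and distortions[sid] is not None:
            scores = distort_scores(scores, distortions[sid])
        true = np.argmax(batch.labels, axis=1)
        entry: dict = {"n_sequences": int(len(batch))}
        if with_idm:
            cal = idm_mod.calibrate_subject(
                scores, true, calib_fraction=calib_fraction, seed=seed + sid, subject_id=sid
            )
            eval_true = cal["labels"]
            cm_raw = confusion_matrix(cal["predicted_raw"], eval_true)
            cm_cal = confusion_matrix(cal["predicted_calibrated"], eval_true)
            entry.update(
                {
                    "n_evaluated": int(eval_true.size),
                    "confusion_without_idm": cm_raw.tolist(),
                    "confusion_with_idm": cm_cal.tolist(),
                    "accuracy_without_idm": accuracy_from_confusion(cm_raw),
                    "accuracy_with_idm": accuracy_from_confusion(cm_cal),
                }
            )
            entry["accuracy_delta"] = entry["accuracy_with_idm"] - entry["accuracy_without_idm"]
        else:
            pred = predict_class(scores)
            cm = confusion_matrix(pred, true)
            entry.update(
                {
                    "n_evaluated": int(true.size),
                    "confusion": cm.tolist(),
                    "accuracy": accuracy_from_confusion(cm),
                }
            )
        report["subjects"][int(sid)] = entry

    accs_key = "accuracy_with_idm" if with_idm else "accuracy"
    accs = [e[accs_key] for e in report["subjects"].values()]
    report["mean_accuracy"] = float(np.mean(accs)) if accs else float("nan")
    if with_idm:
        base = [e["accuracy_without_idm"] for e in report["subjects"].values()]
        report["mean_accuracy_without_idm"] = float(np.mean(base)) if base else float("nan")
        report["mean_accuracy_with_idm"] = report["mean_accuracy"]
    return report
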
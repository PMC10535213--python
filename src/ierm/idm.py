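"""Individual Difference Module: per-subject isotonic calibration of scores.

A generic classifier systematically misjudges an unseen subject whose
emotional responses are shifted or compressed relative to the training
population.  The IDM observes (score, label) pairs from part of that
subject's data and fits a weighted isotonic regression — the monotone
least-squares step function, solved exactly by the pair-adjacent violators
(PAV) algorithm — mapping raw scores to calibrated probabilities.  The
calibrated map preserves the ranking of scores while absorbing the subject's
monotone response distortion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .model import predict_class

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationSet",
    "IsotonicModel",
    "pav_fit",
    "calibrate_score",
    "calibrate_subject",
    "observer_residuals",
]


@dataclass
class CalibrationSet:
    """Observed (raw score f, label y, weight w) triples for one subject."""

    f: np.ndarray
    y: np.ndarray
    w: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.f.size == 0:
            raise ValueError("calibration set must be non-empty")
        if self.f.shape != self.y.shape:
            raise ValueError("f and y must have the same length")
        if self.w is None:
            self.w = np.ones_like(self.f)
        else:
            self.w = np.asarray(self.w, dtype=np.float64)
            if self.w.shape != self.f.shape:
                raise ValueError("weights must match f in length")
            if np.any(self.w <= 0):
                raise ValueError("weights must be positive")


@dataclass
class IsotonicModel:
    """Fitted nondecreasing step function from raw score to calibrated value.

    ``thresholds`` are the (strictly ascending) training scores after tie
    pooling; ``block_values`` the fitted values at those scores.  Evaluation
    is right-continuous stepwise-constant with clamping outside the range.
    """

    thresholds: np.ndarray
    block_values: np.ndarray
    subject_id: int | None = None
    n_train: int = 0
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.block_values = np.asarray(self.block_values, dtype=np.float64)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly ascending")
        if np.any(np.diff(self.block_values) < -1e-12):
            raise ValueError("block values must be nondecreasing")

    def to_json(self) -> str:
        return json.dumps(
            {
                "thresholds": self.thresholds.tolist(),
                "block_values": self.block_values.tolist(),
                "subject_id": self.subject_id,
                "n_train": self.n_train,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "IsotonicModel":
        d = json.loads(text)
        return cls(
            thresholds=np.array(d["thresholds"]),
            block_values=np.array(d["block_values"]),
            subject_id=d.get("subject_id"),
            n_train=d.get("n_train", 0),
        )


def _identity_model(subject_id: int | None = None) -> IsotonicModel:
    return IsotonicModel(
        thresholds=np.array([0.0, 1.0]),
        block_values=np.array([0.0, 1.0]),
        subject_id=subject_id,
    )


def pav_fit(cal: CalibrationSet, subject_id: int | None = None) -> IsotonicModel:
    """Weighted isotonic regression by pair-adjacent violators.

    Items are sorted by score (ties pre-pooled to their weighted mean label);
    adjacent order violations are pooled to the weighted mean of the run,
    cascading left while a violation remains.  Returns the unique minimizer
    of sum w_m (y_m - yhat_m)^2 subject to yhat nondecreasing in f.
    """
    order = np.argsort(cal.f, kind="stable")
    f, y, w = cal.f[order], cal.y[order], cal.w[order]

    # pre-pool exact score ties by weighted mean
    uf, inverse = np.unique(f, return_inverse=True)
    wt = np.bincount(inverse, weights=w)
    yt = np.bincount(inverse, weights=w * y) / wt

    # stack-based PAV over blocks of (value, weight, count)
    vals: list[float] = []
    wts: list[float] = []
    cnts: list[int] = []
    for v, wi in zip(yt, wt):
        vals.append(float(v))
        wts.append(float(wi))
        cnts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2, c2 = vals.pop(), wts.pop(), cnts.pop()
            v1, w1, c1 = vals.pop(), wts.pop(), cnts.pop()
            vals.append((v1 * w1 + v2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
            cnts.append(c1 + c2)
    fitted = np.repeat(vals, cnts)

    # residuals per original item, in the original item order
    res_sorted = y - fitted[inverse]
    residuals = np.empty_like(res_sorted)
    residuals[order] = res_sorted
    return IsotonicModel(
        thresholds=uf,
        block_values=fitted,
        subject_id=subject_id,
        n_train=int(cal.f.size),
        residuals=residuals,
    )


def calibrate_score(model: IsotonicModel, f: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the fitted step function at raw score(s) ``f``.

    Right-continuous: the value of the last threshold at or below f; clamped
    to the first/last block value outside the fitted range.
    """
    scalar = np.isscalar(f)
    fa = np.atleast_1d(np.asarray(f, dtype=np.float64))
    idx = np.searchsorted(model.thresholds, fa, side="right") - 1
    idx = np.clip(idx, 0, model.block_values.size - 1)
    out = model.block_values[idx]
    return float(out[0]) if scalar else out


def _stratified_split(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Split indices into (calibration, evaluation), stratified by label."""
    cal_idx, eval_idx = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        n_cal = int(round(fraction * idx.size))
        n_cal = min(max(n_cal, 1), idx.size - 1) if idx.size > 1 else idx.size
        cal_idx.append(idx[:n_cal])
        eval_idx.append(idx[n_cal:])
    return np.sort(np.concatenate(cal_idx)), np.sort(np.concatenate(eval_idx))


def calibrate_subject(
    scores: np.ndarray,
    labels: np.ndarray,
    calib_fraction: float = 0.5,
    seed: int = 0,
    subject_id: int | None = None,
):
    """Fit and apply per-subject calibration on held-out data.

    ``scores`` is (n, 2) raw sigmoid outputs for one subject, ``labels`` the
    subject's 0/1 labels.  The subject's items are split (stratified, seeded)
    into a calibration part and an evaluation part; one isotonic model is
    fitted per output unit on the calibration part and applied to the
    evaluation part.  Returns a dict with the fitted models, index arrays,
    and raw/calibrated evaluation scores.  If the calibration part contains a
    single class the models fall back to the identity map (logged).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(np.int64)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be (n, 2)")
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels misaligned")
    if scores.shape[0] < 10:
        raise ValueError("need at least 10 sequences to calibrate a subject")
    rng = np.random.default_rng(seed)
    cal_idx, eval_idx = _stratified_split(labels, calib_fraction, rng)

    onehot = np.stack([1 - labels, labels], axis=1).astype(np.float64)
    if np.unique(labels[cal_idx]).size < 2:
        logger.warning(
            "subject %s: calibration split has a single class; identity fallback", subject_id
        )
        models = [_identity_model(subject_id), _identity_model(subject_id)]
        raw_eval = scores[eval_idx]
        calibrated = raw_eval.copy()  # identity calibration passes scores through
    else:
        models = [
            pav_fit(CalibrationSet(scores[cal_idx, u], onehot[cal_idx, u]), subject_id=subject_id)
            for u in (0, 1)
        ]
        raw_eval = scores[eval_idx]
        calibrated = np.stack(
            [np.atleast_1d(calibrate_score(models[u], raw_eval[:, u])) for u in (0, 1)], axis=1
        )
    return {
        "models": models,
        "calibration_index": cal_idx,
        "evaluation_index": eval_idx,
        "raw_scores": raw_eval,
        "calibrated_scores": calibrated,
        "labels": labels[eval_idx],
        "predicted_raw": predict_class(raw_eval),
        "predicted_calibrated": _predict_calibrated(calibrated, raw_eval),
    }


def _predict_calibrated(calibrated: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Argmax of calibrated scores; exact ties fall back to the raw ordering.

    The fitted step functions are many-to-one, so distinct raw scores can
    collapse onto identical calibrated values; since calibration preserves
    the raw rank order, the raw scores are the natural tie-break.
    """
    out = np.where(calibrated[:, 1] > calibrated[:, 0], 1, 0)
    tie = calibrated[:, 1] == calibrated[:, 0]
    if np.any(tie):
        out[tie] = predict_class(raw[tie])
    return out.astype(np.int64)


def observer_residuals(scores: np.ndarray, labels: np.ndarray, subject_ids: np.ndarray) -> dict:
    """Per-subject mean residual (label minus positive-unit score).

    The residual is the observer's error signal; its per-subject mean should
    shrink after calibration.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    subject_ids = np.asarray(subject_ids)
    if not (scores.shape[0] == labels.shape[0] == subject_ids.shape[0]):
        raise ValueError("scores, labels, subject_ids misaligned")
    pos = scores[:, 1] if scores.ndim == 2 else scores
    out = {}
    for sid in np.unique(subject_ids):
        mask = subject_ids == sid
        out[int(sid)] = float(np.mean(labels[mask] - pos[mask]))
    return out
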
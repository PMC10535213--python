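"""Differential-entropy band features on the 9x9 electrode grid.

For a band-filtered, approximately Gaussian EEG segment the differential
entropy reduces to ``0.5 * ln(2*pi*e*sigma^2)`` (nats), with ``sigma^2``
estimated as the unbiased sample variance of the segment.  Per-channel DE
values are placed on a 9x9 grid laid out after the 10-20 montage (row 0 =
prefrontal line, column 0 = left); the four band planes stack into a 4x9x9
map per segment, and a subject yields an (n_segments, 4, 9, 9) tensor with
per-segment labels and provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import (
    DEFAULT_BANDS,
    BandDefinition,
    LabelRule,
    binarize_rating,
    butter_sos,
    strip_baseline,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANCE_FLOOR",
    "ElectrodeGrid",
    "DEFeatureMap",
    "FeatureTensor",
    "default_grid",
    "differential_entropy",
    "map_to_grid",
    "featurize",
]

VARIANCE_FLOOR = 1e-12

# 10-20 labels -> (row, col) on the 9x9 scalp grid; row 0 frontal, col 0 left.
_DEFAULT_PLACEMENT: dict[str, tuple[int, int]] = {
    "Fp1": (0, 3), "Fp2": (0, 5),
    "AF3": (1, 3), "AF4": (1, 5),
    "F7": (2, 0), "F3": (2, 2), "Fz": (2, 4), "F4": (2, 6), "F8": (2, 8),
    "FC5": (3, 1), "FC1": (3, 3), "FC2": (3, 5), "FC6": (3, 7),
    "T7": (4, 0), "C3": (4, 2), "Cz": (4, 4), "C4": (4, 6), "T8": (4, 8),
    "CP5": (5, 1), "CP1": (5, 3), "CP2": (5, 5), "CP6": (5, 7),
    "P7": (6, 0), "P3": (6, 2), "Pz": (6, 4), "P4": (6, 6), "P8": (6, 8),
    "PO3": (7, 3), "PO4": (7, 5),
    "O1": (8, 3), "Oz": (8, 4), "O2": (8, 5),
}


@dataclass(frozen=True)
class ElectrodeGrid:
    """Registry mapping channel names to cells of a rows x cols scalp grid."""

    rows: int = 9
    cols: int = 9
    placement: Mapping[str, tuple[int, int]] = field(default_factory=lambda: dict(_DEFAULT_PLACEMENT))

    def __post_init__(self) -> None:
        coords = list(self.placement.values())
        if len(set(coords)) != len(coords):
            raise ValueError("electrode placements must be unique")
        for name, (r, c) in self.placement.items():
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise ValueError(f"{name} placed outside the {self.rows}x{self.cols} grid")

    def coords(self, channel_names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        missing = [n for n in channel_names if n not in self.placement]
        if missing:
            raise KeyError(f"channels not in the electrode grid: {missing}")
        rc = np.array([self.placement[n] for n in channel_names])
        return rc[:, 0], rc[:, 1]


@dataclass
class DEFeatureMap:
    """One segment's 4x9x9 DE map (nats) with provenance."""

    values: np.ndarray
    subject_id: int
    trial_index: int
    segment_index: int


@dataclass
class FeatureTensor:
    """Per-subject stack of segment feature maps: values (n, 4, 9, 9)."""

    values: np.ndarray
    labels_valence: np.ndarray
    labels_arousal: np.ndarray
    trial_index: np.ndarray
    segment_index: np.ndarray
    subject_id: int

    def __post_init__(self) -> None:
        n = self.values.shape[0]
        for name in ("labels_valence", "labels_arousal", "trial_index", "segment_index"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match segment count")


def default_grid() -> ElectrodeGrid:
    """The 32-channel DEAP layout on the 9x9 grid."""
    return ElectrodeGrid()


def differential_entropy(x: np.ndarray) -> float:
    """DE of a signal under the Gaussian model: 0.5*ln(2*pi*e*var(x)), nats.

    Variance is the unbiased sample estimate, floored at 1e-12 so constant
    segments return a finite (logged) floor value instead of -inf.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    var = float(np.var(x, ddof=1))
    if var < VARIANCE_FLOOR:
        logger.warning("variance %.3g below floor; DE clamped", var)
        var = VARIANCE_FLOOR
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def map_to_grid(per_channel: Mapping[str, float], grid: ElectrodeGrid | None = None) -> np.ndarray:
    """Place per-channel values on the grid; cells without an electrode are 0."""
    grid = grid or default_grid()
    out = np.zeros((grid.rows, grid.cols))
    rows, cols = grid.coords(list(per_channel.keys()))
    out[rows, cols] = list(per_channel.values())
    return out


def featurize(
    rec,
    ratings=None,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    grid: ElectrodeGrid | None = None,
    window_s: float = 0.5,
    baseline_s: float = 3.0,
    label_threshold: int = 5,
) -> FeatureTensor:
    """Full feature extraction for one subject.

    Strips the baseline, zero-phase band-filters each whole trial (filtering
    before segmentation avoids filter transients inside the short windows),
    computes per-channel DE for every non-overlapping window, and assembles
    the band planes on the electrode grid.  ``ratings`` (a DataFrame with
    per-trial valence/arousal) provides segment labels; without it the label
    arrays are -1.
    """
    from scipy.signal import sosfiltfilt

    grid = grid or default_grid()
    stripped = strip_baseline(rec, baseline_s) if baseline_s > 0 else rec
    n_trials, n_ch, n_samples = stripped.data.shape
    win = window_s * rec.sample_rate_hz
    if abs(win - round(win)) > 1e-9:
        raise ValueError("window_s x sample_rate_hz must be an integer")
    win = int(round(win))
    if n_samples % win != 0:
        raise ValueError("post-baseline trial length not divisible by the window")
    per_trial = n_samples // win
    n_seg = n_trials * per_trial

    rows, cols = grid.coords(stripped.channel_names)
    values = np.zeros((n_seg, len(bands), grid.rows, grid.cols))
    for bi, band in enumerate(bands):
        sos = butter_sos(band, rec.sample_rate_hz)
        filt = sosfiltfilt(sos, stripped.data, axis=-1)
        segs = filt.reshape(n_trials, n_ch, per_trial, win)
        var = np.maximum(segs.var(axis=-1, ddof=1), VARIANCE_FLOOR)
        de = 0.5 * np.log(2.0 * np.pi * np.e * var)  # (trials, ch, per_trial)
        de = de.transpose(0, 2, 1).reshape(n_seg, n_ch)
        values[:, bi, rows, cols] = de

    trial_index = np.repeat(np.arange(n_trials, dtype=np.int64), per_trial)
    segment_index = np.tile(np.arange(per_trial, dtype=np.int64), n_trials)

    if ratings is not None:
        rule_v = LabelRule("valence", label_threshold)
        rule_a = LabelRule("arousal", label_threshold)
        by_trial = ratings.set_index("trial")
        lv = np.array(
            [binarize_rating(int(by_trial.loc[t, "valence"]), rule_v) for t in range(n_trials)]
        )
        la = np.array(
            [binarize_rating(int(by_trial.loc[t, "arousal"]), rule_a) for t in range(n_trials)]
        )
        labels_v = lv[trial_index]
        labels_a = la[trial_index]
    else:
        labels_v = np.full(n_seg, -1, dtype=np.int64)
        labels_a = np.full(n_seg, -1, dtype=np.int64)

    return FeatureTensor(
        values=values,
        labels_valence=labels_v,
        labels_arousal=labels_a,
        trial_index=trial_index,
        segment_index=segment_index,
        subject_id=rec.subject_id,
    )
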
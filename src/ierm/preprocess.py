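"""Preprocessing: baseline removal, resampling, segmentation, band filtering,
and rating binarization.

Conventions follow the standard DEAP-style pipeline: the first 3 s of every
trial are discarded as stimulus-free baseline, signals are kept at (or
polyphase-resampled to) 128 Hz, each trial is cut into strict non-overlapping
0.5-s segments, a zero-phase 4th-order Butterworth bank isolates the
theta/alpha/beta/gamma bands, and 1-9 self-ratings are binarized at 5
(ratings 1-5 negative, 6-9 positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import signal

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import RawRecording

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "LabelRule",
    "Segment",
    "butter_sos",
    "strip_baseline",
    "resample",
    "segment_trials",
    "bandpass_bank",
    "binarize_rating",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma", 31.0, 50.0),
)


@dataclass(frozen=True)
class LabelRule:
    """Binarization rule: rating <= threshold -> 0 (negative/low), else 1."""

    dimension: str = "valence"
    threshold: int = 5

    def __post_init__(self) -> None:
        if self.dimension not in ("valence", "arousal"):
            raise ValueError("dimension must be 'valence' or 'arousal'")
        if not 1 <= self.threshold <= 9:
            raise ValueError("threshold must lie in [1, 9]")


@dataclass
class Segment:
    """One window of one trial: (channels, window_samples)."""

    data: np.ndarray
    trial_index: int
    segment_index: int
    subject_id: int


def butter_sos(band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    """4th-order Butterworth band-pass in second-order sections."""
    nyq = fs / 2.0
    if band.high_hz >= nyq:
        raise ValueError(f"band {band.name} upper edge {band.high_hz} Hz reaches Nyquist ({nyq} Hz)")
    return signal.butter(order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos")


def strip_baseline(rec: "RawRecording", baseline_s: float = 3.0) -> "RawRecording":
    """Drop the first ``baseline_s`` seconds of every trial."""
    from .synthetic import RawRecording

    n_cut = int(round(baseline_s * rec.sample_rate_hz))
    if n_cut < 0:
        raise ValueError("baseline_s must be >= 0")
    if n_cut >= rec.data.shape[2]:
        raise ValueError("baseline is not shorter than the trial")
    return RawRecording(
        data=rec.data[:, :, n_cut:],
        sample_rate_hz=rec.sample_rate_hz,
        channel_names=rec.channel_names,
        subject_id=rec.subject_id,
    )


def resample(rec: "RawRecording", target_hz: float = 128.0) -> "RawRecording":
    """Polyphase down-sampling to ``target_hz``; identity when rates match."""
    from .synthetic import RawRecording

    if target_hz > rec.sample_rate_hz:
        raise ValueError("upsampling is not supported")
    if target_hz == rec.sample_rate_hz:
        return rec
    frac = Fraction(target_hz / rec.sample_rate_hz).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=2)
    return RawRecording(
        data=data,
        sample_rate_hz=target_hz,
        channel_names=rec.channel_names,
        subject_id=rec.subject_id,
    )


def segment_trials(rec: "RawRecording", window_s: float = 0.5) -> list[Segment]:
    """Cut every trial into strict non-overlapping windows of ``window_s``.

    The trial length must be an integer multiple of the window; partial
    windows are an error, never silently dropped.
    """
    win = window_s * rec.sample_rate_hz
    if abs(win - round(win)) > 1e-9 or round(win) < 1:
        raise ValueError("window_s x sample_rate_hz must be a positive integer")
    win = int(round(win))
    n_trials, _, n_samples = rec.data.shape
    if n_samples % win != 0:
        raise ValueError(f"trial length {n_samples} not divisible by window {win}")
    per_trial = n_samples // win
    segments = []
    for trial in range(n_trials):
        for k in range(per_trial):
            segments.append(
                Segment(
                    data=rec.data[trial, :, k * win : (k + 1) * win],
                    trial_index=trial,
                    segment_index=k,
                    subject_id=rec.subject_id,
                )
            )
    return segments


def bandpass_bank(
    data: np.ndarray | Segment,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    fs: float = 128.0,
) -> list[np.ndarray] | list[Segment]:
    """Zero-phase (forward-backward) Butterworth filtering into each band.

    Accepts a raw array (filtered along the last axis) or a Segment, and
    returns one same-shaped copy per band.
    """
    if isinstance(data, Segment):
        filtered = bandpass_bank(data.data, bands, fs)
        return [
            Segment(arr, data.trial_index, data.segment_index, data.subject_id) for arr in filtered
        ]
    arr = np.asarray(data, dtype=np.float64)
    return [signal.sosfiltfilt(butter_sos(b, fs), arr, axis=-1) for b in bands]


def binarize_rating(rating: int, rule: LabelRule = LabelRule()) -> int:
    """1-9 self-rating -> 0 (at or below threshold) / 1 (above)."""
    if not 1 <= rating <= 9:
        raise ValueError(f"rating {rating} outside [1, 9]")
    return 0 if rating <= rule.threshold else 1
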
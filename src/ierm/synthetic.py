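"""Synthetic EEG cohort generator with DEAP-like geometry.

Each subject yields a (trials x channels x samples) recording at 128 Hz —
defaults reproduce the (40, 32, 8064) shape of a 63-s trial (3-s baseline +
60 s of stimulus) on the 32-channel 10-20 montage — plus 1-9 valence/arousal
self-ratings.  Every trial is pink background noise plus four band-limited
noise components (theta/alpha/beta/gamma); the beta and gamma components in
frontal channels are amplified or attenuated by the trial's latent valence
class, switching on only after the subject's emotional-response latency.
Per-subject individual differences are modelled by an amplitude gain, a
response latency, an intensity bias on the self-rating, and a monotone
distortion of reported class probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import DEFAULT_BANDS, BandDefinition, butter_sos

__all__ = [
    "DEAP_CHANNELS",
    "FRONTAL_CHANNELS",
    "PowerDistortion",
    "SubjectProfile",
    "GeneratorConfig",
    "RawRecording",
    "generate_subject",
    "generate_cohort",
    "distort_scores",
]

# DEAP channel order (10-20 labels, Geneva ordering).
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

# Channels carrying the valence effect (prefrontal/frontal line).
FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "AF3", "AF4")

_EFFECT_BANDS = ("beta", "gamma")
_RAMP_S = 0.25  # the class effect fades in over this many seconds past latency


class PowerDistortion:
    """Monotone map p -> p**a on [0, 1]; a = 1 is the identity.

    Models how a subject's reported confidence relates to the ideal class
    probability (their individual difference, which calibration must undo).
    """

    def __init__(self, exponent: float) -> None:
        if exponent <= 0:
            raise ValueError("exponent must be positive")
        self.exponent = float(exponent)

    def __call__(self, p: np.ndarray | float) -> np.ndarray | float:
        return np.clip(p, 0.0, 1.0) ** self.exponent

    def __repr__(self) -> str:  # pragma: no cover
        return f"PowerDistortion(exponent={self.exponent:g})"


@dataclass
class SubjectProfile:
    subject_id: int
    gain: float = 1.0
    latency_s: float = 0.0
    intensity_bias: float = 0.0
    score_distortion: Callable[[float], float] = field(default_factory=lambda: PowerDistortion(1.0))

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if not 0.0 <= self.latency_s <= 2.0:
            raise ValueError("latency_s must lie in [0, 2] seconds")


@dataclass(frozen=True)
class GeneratorConfig:
    n_trials: int = 40
    n_channels: int = 32
    sample_rate_hz: float = 128.0
    trial_len_s: float = 63.0  # 3-s baseline + 60 s stimulus
    baseline_s: float = 3.0
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    channel_names: tuple[str, ...] = DEAP_CHANNELS
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        n = self.trial_len_s * self.sample_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_len_s x sample_rate_hz must be an integer sample count")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_len_s * self.sample_rate_hz))


@dataclass
class RawRecording:
    """Per-subject EEG array (trials x channels x samples) with metadata."""

    data: np.ndarray
    sample_rate_hz: float
    channel_names: tuple[str, ...]
    subject_id: int

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """1/f-amplitude noise via FFT shaping of white noise, unit variance."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _band_noise(rng: np.random.Generator, shape: tuple[int, ...], band: BandDefinition, fs: float) -> np.ndarray:
    """White noise filtered to one band with the preprocessing Butterworth bank."""
    sos = butter_sos(band, fs)
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _balanced_latents(rng: np.random.Generator, n: int) -> np.ndarray:
    lat = np.zeros(n, dtype=np.int64)
    lat[n // 2 :] = 1
    rng.shuffle(lat)
    return lat


def generate_subject(profile: SubjectProfile, cfg: GeneratorConfig) -> tuple[RawRecording, pd.DataFrame]:
    """Synthesize one subject's recording and rating table.

    Returns the recording and a DataFrame with columns trial, valence,
    arousal, latent_valence, latent_arousal (latents are ground truth, only
    available synthetically).  Fully reproducible from (cfg.seed,
    profile.subject_id).
    """
    unknown = set(cfg.channel_names) - set(DEAP_CHANNELS)
    if unknown:
        raise KeyError(f"channel names not in the electrode registry: {sorted(unknown)}")
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, profile.subject_id])
    fs = cfg.sample_rate_hz
    n_t, n_c, n_s = cfg.n_trials, cfg.n_channels, cfg.n_samples

    latent_v = _balanced_latents(rng, n_t)
    latent_a = _balanced_latents(rng, n_t)

    frontal_idx = np.array([i for i, name in enumerate(cfg.channel_names) if name in FRONTAL_CHANNELS])

    # Class-effect envelope: 0 during baseline + latency, ramps to 1 over _RAMP_S.
    t = np.arange(n_s) / fs
    onset = cfg.baseline_s + profile.latency_s
    env = np.clip((t - onset) / _RAMP_S, 0.0, 1.0)

    data = cfg.noise_sd * _pink_noise(rng, (n_t, n_c, n_s))
    for band in cfg.bands:
        comp = 0.5 * cfg.noise_sd * _band_noise(rng, (n_t, n_c, n_s), band, fs)
        if band.name in _EFFECT_BANDS and frontal_idx.size:
            s = 1.0 + cfg.effect_size * (2.0 * latent_v - 1.0)  # per-trial factor
            factor = 1.0 + (s[:, None] - 1.0) * env[None, :]  # (trials, samples)
            comp[:, frontal_idx, :] *= factor[:, None, :]
        data += comp
    data *= profile.gain

    def ratings_for(latent: np.ndarray) -> np.ndarray:
        raw = (
            5.0
            + (2.0 * latent - 1.0) * (2.0 + cfg.effect_size)
            + profile.intensity_bias
            + rng.normal(0.0, 0.5, size=latent.shape)
        )
        return np.clip(np.rint(raw), 1, 9).astype(np.int64)

    ratings = pd.DataFrame(
        {
            "trial": np.arange(n_t, dtype=np.int64),
            "valence": ratings_for(latent_v),
            "arousal": ratings_for(latent_a),
            "latent_valence": latent_v,
            "latent_arousal": latent_a,
        }
    )
    rec = RawRecording(
        data=data,
        sample_rate_hz=fs,
        channel_names=tuple(cfg.channel_names),
        subject_id=profile.subject_id,
    )
    return rec, ratings


def draw_profiles(
    n_subjects: int, distortion_strength: float, seed: int, start_id: int = 0
) -> list[SubjectProfile]:
    """Sample subject profiles: gain ~ lognormal(0, 0.1), latency ~ U[0, 1] s,
    intensity bias ~ U[-1, 1], distortion exponent log-uniform in
    [1/(1+strength), 1+strength] (strength 0 -> identity)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if distortion_strength < 0:
        raise ValueError("distortion_strength must be >= 0")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xC0F0])
    profiles = []
    log_hi = np.log1p(distortion_strength)
    for i in range(n_subjects):
        exponent = float(np.exp(rng.uniform(-log_hi, log_hi))) if distortion_strength > 0 else 1.0
        profiles.append(
            SubjectProfile(
                subject_id=start_id + i,
                gain=float(rng.lognormal(0.0, 0.1)),
                latency_s=float(rng.uniform(0.0, 1.0)),
                intensity_bias=float(rng.uniform(-1.0, 1.0)),
                score_distortion=PowerDistortion(exponent),
            )
        )
    return profiles


def generate_cohort(
    n_subjects: int,
    cfg: GeneratorConfig = GeneratorConfig(),
    distortion_strength: float = 0.0,
    start_id: int = 0,
) -> list[tuple[RawRecording, pd.DataFrame, SubjectProfile]]:
    """Generate ``n_subjects`` recordings with profiles drawn from cfg.seed."""
    profiles = draw_profiles(n_subjects, distortion_strength, cfg.seed, start_id=start_id)
    return [(*generate_subject(p, cfg), p) for p in profiles]


def distort_scores(scores: np.ndarray, distortion: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    """Apply a subject's monotone response distortion d to two-unit class scores.

    The positive unit becomes d(p1) and the negative unit the dual
    1 - d(1 - p0): the subject's reported confidence is biased toward one
    pole, which shifts the argmax decision for borderline items — the effect
    the individual-difference module is there to remove.  Applying the same d
    to both units directly would leave the argmax unchanged and the
    individual difference unobservable.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be (n, 2)")
    out = np.empty_like(scores)
    out[:, 1] = distortion(scores[:, 1])
    out[:, 0] = 1.0 - np.asarray(distortion(1.0 - scores[:, 0]))
    return out
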
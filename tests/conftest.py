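"""Shared fixtures: scaled-down cohorts, a trained classifier, and the
exhaustive isotonic-regression oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ierm.features import featurize
from ierm.model import ModelConfig, build_sequences
from ierm.pipeline import TrainingConfig, concat_batches, train_full
from ierm.synthetic import GeneratorConfig, SubjectProfile, generate_cohort, generate_subject

# Scaled-down study geometry used by the training-heavy tests: 12 trials of
# 13 s (3-s baseline + 10 s), i.e. 20 half-second segments per trial.
SMALL_TRIALS = 12
SMALL_LEN_S = 13.0


def small_gen_cfg(effect_size: float = 2.0, seed: int = 100, n_trials: int = SMALL_TRIALS) -> GeneratorConfig:
    return GeneratorConfig(
        n_trials=n_trials, trial_len_s=SMALL_LEN_S, effect_size=effect_size, seed=seed
    )


def small_model_cfg() -> ModelConfig:
    return ModelConfig(conv_channels=(8, 16, 16, 8), lstm_hidden=32, seq_len=5)


@pytest.fixture(scope="session")
def default_subject():
    """One full DEAP-geometry subject: (40, 32, 8064) at 128 Hz."""
    cfg = GeneratorConfig(seed=1, effect_size=1.0)
    return generate_subject(SubjectProfile(subject_id=0), cfg)


@pytest.fixture(scope="session")
def default_features(default_subject):
    rec, ratings = default_subject
    return featurize(rec, ratings)


@pytest.fixture(scope="session")
def train_cohort_features():
    """Eight training subjects at effect size 2 (scaled geometry)."""
    cohort = generate_cohort(8, small_gen_cfg(effect_size=2.0, seed=100))
    return {p.subject_id: featurize(rec, r) for rec, r, p in cohort}


@pytest.fixture(scope="session")
def trained_model(train_cohort_features):
    """Classifier trained for 20 epochs on the eight training subjects."""
    mcfg = small_model_cfg()
    tcfg = TrainingConfig(epochs=20, lr=0.001, seed=11)
    batch = concat_batches(
        [build_sequences(f, "valence", mcfg.seq_len) for f in train_cohort_features.values()]
    )
    model, losses = train_full(batch, mcfg, tcfg)
    return model, losses


def exhaustive_isotonic(y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Brute-force isotonic regression for sorted inputs.

    Enumerates all 2^(M-1) contiguous block partitions; each block takes its
    weighted mean; a partition is admissible iff block means are
    nondecreasing; returns the admissible fit with minimal weighted SSE.
    """
    y = np.asarray(y, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    m = y.size
    best_fit, best_sse = None, np.inf
    for cuts in itertools.product([0, 1], repeat=m - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [m]
        means = []
        fit = np.empty(m)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mu = float(np.sum(w[lo:hi] * y[lo:hi]) / np.sum(w[lo:hi]))
            means.append(mu)
            fit[lo:hi] = mu
        if any(b < a - 1e-12 for a, b in zip(means[:-1], means[1:])):
            continue
        sse = float(np.sum(w * (y - fit) ** 2))
        if sse < best_sse - 1e-15:
            best_sse, best_fit = sse, fit
    return best_fit, best_sse
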
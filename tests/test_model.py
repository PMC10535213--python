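"""Classifier contracts: ECA kernel rule, attention behavior, sequence
construction, loss and decision rules, shape conservation, checkpointing,
and the overfit sanity check."""

import numpy as np
import pytest

from ierm import nn
from ierm.features import FeatureTensor
from ierm.model import (
    EcaConfig,
    EmotionClassifier,
    ModelConfig,
    build_sequences,
    eca_kernel_size,
    load_checkpoint,
    mse_loss,
    predict_class,
    save_checkpoint,
)
from ierm.pipeline import TrainingConfig, concat_batches, train_model
from conftest import small_model_cfg

TINY = ModelConfig(conv_channels=(3, 4, 5, 3), dropout=0.0, lstm_hidden=4, seq_len=2)


class TestEcaKernelSize:
    @pytest.mark.parametrize("channels,expected", [(32, 3), (256, 5), (2, 1), (64, 3), (128, 5)])
    def test_known_values(self, channels, expected):
        assert eca_kernel_size(channels) == expected

    def test_always_odd_and_positive(self):
        for c in range(1, 513):
            k = eca_kernel_size(c)
            assert k >= 1 and k % 2 == 1

    def test_invalid_channel_count(self):
        with pytest.raises(ValueError):
            eca_kernel_size(0)

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            EcaConfig(gamma=0)


class TestEcaForward:
    def test_shape_preserved_and_weights_bounded(self):
        rng = np.random.default_rng(0)
        eca = nn.ECALayer(eca_kernel_size(64), rng)
        x = rng.normal(size=(2, 64, 9, 9))
        out = eca.forward(x)
        assert out.shape == x.shape
        w = eca.channel_weights(x)
        assert np.all((w > 0) & (w < 1))

    def test_zero_input_zero_output(self):
        eca = nn.ECALayer(3, np.random.default_rng(0))
        out = eca.forward(np.zeros((2, 8, 5, 5)))
        assert np.all(out == 0.0)


def test_leaky_relu_keeps_scaled_negatives():
    act = nn.LeakyReLU(0.01)
    x = np.array([-2.0, -0.5, 0.0, 1.5])
    assert np.allclose(act.forward(x), [-0.02, -0.005, 0.0, 1.5])


class TestForwardContracts:
    @pytest.mark.parametrize("seq_len", [1, 3])
    def test_end_to_end_shapes(self, seq_len):
        cfg = ModelConfig(conv_channels=(3, 4, 5, 3), dropout=0.0, lstm_hidden=4, seq_len=seq_len)
        model = EmotionClassifier(cfg, seed=0)
        x = np.random.default_rng(0).normal(size=(5, seq_len, 4, 9, 9))
        scores = model.forward(x)
        assert scores.shape == (5, 2)
        assert np.all((scores > 0) & (scores < 1))

    def test_encode_conserves_sequence_length(self):
        model = EmotionClassifier(TINY, seed=0)
        x = np.random.default_rng(1).normal(size=(2, 2, 4, 9, 9))
        h = model.encode(x)
        assert h.shape[:2] == (2, 2)

    def test_reversed_sequence_changes_scores(self):
        """Both temporal directions contribute: reversing the segment order
        changes the output for a generic input."""
        model = EmotionClassifier(ModelConfig(conv_channels=(3, 4, 5, 3), dropout=0.0, lstm_hidden=4, seq_len=4), seed=0)
        x = np.random.default_rng(2).normal(size=(2, 4, 4, 9, 9))
        assert not np.allclose(model.forward(x), model.forward(x[:, ::-1]))


class TestLossAndDecision:
    def test_perfect_prediction_zero_loss(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert mse_loss(y, y)[0] == 0.0

    def test_uniform_prediction_quarter_loss(self):
        loss, _ = mse_loss(np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]]))
        assert loss == pytest.approx(0.25)

    def test_loss_nonnegative_random(self):
        rng = np.random.default_rng(0)
        p = rng.random((20, 2))
        y = rng.random((20, 2))
        assert mse_loss(p, y)[0] >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((2, 2)), np.zeros((3, 2)))

    @pytest.mark.parametrize(
        "scores,expected",
        [([0.9, 0.1], 0), ([0.5, 0.5], 0), ([0.2, 0.8], 1)],
    )
    def test_predict_class(self, scores, expected):
        assert predict_class(np.array([scores]))[0] == expected


class TestBuildSequences:
    def make_features(self, segments_per_trial=7, n_trials=3):
        n = segments_per_trial * n_trials
        rng = np.random.default_rng(0)
        return FeatureTensor(
            values=rng.normal(size=(n, 4, 9, 9)),
            labels_valence=np.repeat([0, 1, 1], segments_per_trial),
            labels_arousal=np.repeat([1, 0, 1], segments_per_trial),
            trial_index=np.repeat(np.arange(n_trials), segments_per_trial),
            segment_index=np.tile(np.arange(segments_per_trial), n_trials),
            subject_id=5,
        )

    def test_runs_never_span_trials(self):
        feats = self.make_features()
        batch = build_sequences(feats, "valence", seq_len=3)
        # 7 segments per trial -> 2 runs of 3, trailing segment dropped
        assert len(batch) == 6
        assert np.all(np.bincount(batch.trial_index) == 2)

    def test_labels_one_hot_per_dimension(self):
        feats = self.make_features()
        v = build_sequences(feats, "valence", seq_len=7)
        a = build_sequences(feats, "arousal", seq_len=7)
        assert np.array_equal(v.labels, [[1, 0], [0, 1], [0, 1]])
        assert np.array_equal(a.labels, [[0, 1], [1, 0], [0, 1]])

    def test_bad_dimension_rejected(self):
        with pytest.raises(ValueError):
            build_sequences(self.make_features(), "dominance", 3)


def test_checkpoint_roundtrip_bit_exact(tmp_path):
    model = EmotionClassifier(TINY, seed=3)
    x = np.random.default_rng(4).normal(size=(3, 2, 4, 9, 9))
    before = model.forward(x)
    save_checkpoint(model, str(tmp_path / "ckpt"))
    restored = load_checkpoint(str(tmp_path / "ckpt"))
    assert np.array_equal(before, restored.forward(x))


def test_overfits_small_synthetic_cohort(train_cohort_features):
    """On 64 strongly separated sequences, 100 epochs reach >= 0.95 training
    accuracy."""
    mcfg = small_model_cfg()
    batch = concat_batches(
        [build_sequences(f, "valence", mcfg.seq_len) for f in train_cohort_features.values()]
    )
    rng = np.random.default_rng(0)
    idx = rng.choice(len(batch), size=64, replace=False)
    from ierm.model import SequenceBatch

    sub = SequenceBatch(batch.inputs[idx], batch.labels[idx], batch.subject_ids[idx], batch.trial_index[idx])
    model = EmotionClassifier(mcfg, seed=2)
    train_model(model, sub, TrainingConfig(epochs=100, seed=2))
    pred = predict_class(model.predict_scores(sub.inputs))
    acc = float(np.mean(pred == np.argmax(sub.labels, axis=1)))
    assert acc >= 0.95
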
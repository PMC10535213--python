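"""The emotion classifier: attention CNN encoder + BiLSTM head.

Each 0.5-s EEG segment arrives as a 4x9x9 differential-entropy map (four
frequency bands on a 9x9 electrode grid).  A stack of four convolutional
blocks — convolution, batch normalization, efficient channel attention (ECA),
dropout, leaky ReLU — encodes every segment; 2x2 max pooling and flattening
turn each into a feature vector; a bidirectional LSTM reads runs of
consecutive segments and a linear layer with two sigmoid units scores the
negative/positive class.  Training minimizes mean squared error against
one-hot labels.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import mse_loss  # re-exported: the training criterion

__all__ = [
    "EcaConfig",
    "ModelConfig",
    "SequenceBatch",
    "eca_kernel_size",
    "ConvBlock",
    "EmotionClassifier",
    "build_sequences",
    "mse_loss",
    "predict_class",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class EcaConfig:
    """Parameters of the adaptive ECA kernel-size rule k = odd(floor(|(log2 C + b) / gamma|))."""

    b: int = 1
    gamma: int = 2

    def __post_init__(self) -> None:
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")


@dataclass(frozen=True)
class ModelConfig:
    conv_channels: tuple[int, int, int, int] = (64, 128, 256, 64)
    kernel: int = 3
    dropout: float = 0.5
    lstm_hidden: int = 128
    bidirectional: bool = True
    seq_len: int = 10
    out_units: int = 2
    leaky_slope: float = 0.01
    eca: EcaConfig = field(default_factory=EcaConfig)

    def __post_init__(self) -> None:
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class SequenceBatch:
    """Runs of consecutive segment feature maps with one one-hot label per run.

    ``inputs`` has shape (n_seqs, seq_len, 4, 9, 9); sequences never span
    trial boundaries.
    """

    inputs: np.ndarray
    labels: np.ndarray  # (n_seqs, 2) one-hot
    subject_ids: np.ndarray
    trial_index: np.ndarray

    def __post_init__(self) -> None:
        if self.inputs.shape[0] != self.labels.shape[0]:
            raise ValueError("inputs and labels disagree on n_seqs")
        if self.labels.ndim != 2 or not np.allclose(self.labels.sum(axis=1), 1.0):
            raise ValueError("labels must be one-hot rows")

    def __len__(self) -> int:
        return self.inputs.shape[0]


def eca_kernel_size(n_channels: int, cfg: EcaConfig = EcaConfig()) -> int:
    """Adaptive 1-D convolution size for ECA over ``n_channels`` channels.

    t = floor(|(log2 C + b) / gamma|); the kernel is t bumped to the next odd
    integer, and never smaller than 1.
    """
    if n_channels < 1:
        raise ValueError("channel count must be >= 1")
    t = math.floor(abs((math.log2(n_channels) + cfg.b) / cfg.gamma))
    k = t if t % 2 == 1 else t + 1
    return max(k, 1)


class ConvBlock:
    """conv -> batch norm -> ECA -> dropout -> leaky ReLU, spatial size preserved."""

    def __init__(self, in_ch: int, out_ch: int, cfg: ModelConfig, rng: np.random.Generator) -> None:
        self.conv = nn.Conv2d(in_ch, out_ch, cfg.kernel, rng)
        self.bn = nn.BatchNorm2d(out_ch)
        self.eca = nn.ECALayer(eca_kernel_size(out_ch, cfg.eca), rng)
        self.drop = nn.Dropout(cfg.dropout)
        self.act = nn.LeakyReLU(cfg.leaky_slope)

    def params(self) -> list[nn.Param]:
        return self.conv.params() + self.bn.params() + self.eca.params()

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        x = self.conv.forward(x)
        x = self.bn.forward(x, train=train)
        x = self.eca.forward(x)
        x = self.drop.forward(x, train=train, rng=rng)
        return self.act.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.act.backward(grad)
        grad = self.drop.backward(grad)
        grad = self.eca.backward(grad)
        grad = self.bn.backward(grad)
        return self.conv.backward(grad)


class EmotionClassifier:
    """(n, seq_len, 4, 9, 9) feature sequences -> (n, 2) sigmoid class scores."""

    def __init__(self, cfg: ModelConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        chans = (4,) + tuple(cfg.conv_channels)
        self.blocks = [ConvBlock(chans[i], chans[i + 1], cfg, rng) for i in range(4)]
        self.pool = nn.MaxPool2d(2)
        self.feat_dim = cfg.conv_channels[-1] * 4 * 4  # 9x9 pooled to 4x4
        self.lstm_f = nn.LSTM(self.feat_dim, cfg.lstm_hidden, rng)
        self.lstm_b = nn.LSTM(self.feat_dim, cfg.lstm_hidden, rng) if cfg.bidirectional else None
        head_in = cfg.lstm_hidden * (2 if cfg.bidirectional else 1)
        self.head = nn.Linear(head_in, cfg.out_units, rng)
        self._cache = None

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for b in self.blocks:
            out.extend(b.params())
        out.extend(self.lstm_f.params())
        if self.lstm_b is not None:
            out.extend(self.lstm_b.params())
        out.extend(self.head.params())
        return out

    def encode(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        """CNN encoding of each segment: (n, T, 4, 9, 9) -> (n, T, feat_dim)."""
        n, t = x.shape[:2]
        z = x.reshape(n * t, *x.shape[2:]).astype(np.float64)
        for block in self.blocks:
            z = block.forward(z, train=train, rng=rng)
        z = self.pool.forward(z)
        return z.reshape(n, t, -1)

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        n, t = x.shape[:2]
        h = self.encode(x, train=train, rng=rng)
        hs_f = self.lstm_f.forward(h)
        parts = [hs_f[:, -1, :]]
        if self.lstm_b is not None:
            hs_b = self.lstm_b.forward(h[:, ::-1, :])
            parts.append(hs_b[:, -1, :])
        concat = np.concatenate(parts, axis=1)
        logits = self.head.forward(concat)
        scores = nn.sigmoid(logits)
        self._cache = (n, t, scores)
        return scores

    def backward(self, dscores: np.ndarray) -> None:
        n, t, scores = self._cache
        hdim = self.cfg.lstm_hidden
        dlogits = dscores * scores * (1.0 - scores)
        dconcat = self.head.backward(dlogits)
        dhs_f = np.zeros((n, t, hdim))
        dhs_f[:, -1, :] = dconcat[:, :hdim]
        dh = self.lstm_f.backward(dhs_f)
        if self.lstm_b is not None:
            dhs_b = np.zeros((n, t, hdim))
            dhs_b[:, -1, :] = dconcat[:, hdim:]
            dh = dh + self.lstm_b.backward(dhs_b)[:, ::-1, :]
        dz = dh.reshape(n * t, -1)
        dz = self.pool.backward(dz.reshape(n * t, self.cfg.conv_channels[-1], 4, 4))
        for block in reversed(self.blocks):
            dz = block.backward(dz)

    def predict_scores(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Eval-mode scores, deterministic, batched for memory."""
        outs = []
        for start in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[start : start + batch_size], train=False))
        return np.concatenate(outs, axis=0) if outs else np.zeros((0, self.cfg.out_units))


def predict_class(scores: np.ndarray) -> np.ndarray:
    """argmax over the two sigmoid outputs; exact ties go to class 0."""
    scores = np.asarray(scores)
    return (scores[:, 1] > scores[:, 0]).astype(np.int64)


def build_sequences(features, dimension: str = "valence", seq_len: int = 10) -> SequenceBatch:
    """Cut a subject's per-segment feature tensor into non-overlapping runs of
    ``seq_len`` consecutive segments within each trial.

    Each run inherits the trial label (one-hot over negative/positive);
    trailing segments that do not fill a run are dropped.
    """
    if dimension not in ("valence", "arousal"):
        raise ValueError("dimension must be 'valence' or 'arousal'")
    labels = features.labels_valence if dimension == "valence" else features.labels_arousal
    inputs, onehots, trials = [], [], []
    for trial in np.unique(features.trial_index):
        mask = features.trial_index == trial
        order = np.argsort(features.segment_index[mask])
        vals = features.values[mask][order]
        lab = int(labels[mask][0])
        n_runs = vals.shape[0] // seq_len
        for r in range(n_runs):
            inputs.append(vals[r * seq_len : (r + 1) * seq_len])
            onehots.append([1.0 - lab, float(lab)])
            trials.append(int(trial))
    inputs_arr = np.asarray(inputs)
    return SequenceBatch(
        inputs=inputs_arr,
        labels=np.asarray(onehots),
        subject_ids=np.full(len(trials), features.subject_id, dtype=np.int64),
        trial_index=np.asarray(trials, dtype=np.int64),
    )


def save_checkpoint(model: EmotionClassifier, directory: str) -> None:
    """Write weights (+ batch-norm running stats) and a JSON config sidecar.

    The weight file is a raw float64 vector with a JSON manifest of shapes, so
    re-saving an identical model is byte-identical.
    """
    os.makedirs(directory, exist_ok=True)
    params = model.params()
    stats = [(b.bn.running_mean, b.bn.running_var) for b in model.blocks]
    arrays = [p.value for p in params] + [a for pair in stats for a in pair]
    flat = np.concatenate([a.ravel() for a in arrays])
    flat.astype("<f8").tofile(os.path.join(directory, "weights.bin"))
    cfg = model.cfg
    manifest = {
        "shapes": [list(a.shape) for a in arrays],
        "config": {
            "conv_channels": list(cfg.conv_channels),
            "kernel": cfg.kernel,
            "dropout": cfg.dropout,
            "lstm_hidden": cfg.lstm_hidden,
            "bidirectional": cfg.bidirectional,
            "seq_len": cfg.seq_len,
            "out_units": cfg.out_units,
            "leaky_slope": cfg.leaky_slope,
            "eca": {"b": cfg.eca.b, "gamma": cfg.eca.gamma},
        },
    }
    with open(os.path.join(directory, "model.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_checkpoint(directory: str) -> EmotionClassifier:
    with open(os.path.join(directory, "model.json")) as fh:
        manifest = json.load(fh)
    c = manifest["config"]
    cfg = ModelConfig(
        conv_channels=tuple(c["conv_channels"]),
        kernel=c["kernel"],
        dropout=c["dropout"],
        lstm_hidden=c["lstm_hidden"],
        bidirectional=c["bidirectional"],
        seq_len=c["seq_len"],
        out_units=c["out_units"],
        leaky_slope=c["leaky_slope"],
        eca=EcaConfig(**c["eca"]),
    )
    model = EmotionClassifier(cfg, seed=0)
    flat = np.fromfile(os.path.join(directory, "weights.bin"), dtype="<f8")
    params = model.params()
    stats_targets = []
    for b in model.blocks:
        stats_targets.extend([("rm", b.bn), ("rv", b.bn)])
    offset = 0
    shapes = manifest["shapes"]
    for i, p in enumerate(params):
        size = int(np.prod(shapes[i])) if shapes[i] else 1
        p.value = flat[offset : offset + size].reshape(shapes[i])
        offset += size
    for j, (kind, bn) in enumerate(stats_targets):
        shape = shapes[len(params) + j]
        size = int(np.prod(shape))
        arr = flat[offset : offset + size].reshape(shape)
        if kind == "rm":
            bn.running_mean = arr
        else:
            bn.running_var = arr
        offset += size
    if offset != flat.size:
        raise ValueError("checkpoint size mismatch")
    return model
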
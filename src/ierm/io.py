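"""HDF5/CSV persistence for recordings and feature tensors.

One file per subject: dataset ``data`` (trials x channels x samples) with
``sample_rate_hz`` and ``channel_names`` attributes, plus a companion CSV of
per-trial ratings.  Feature tensors store ``features`` (n x 4 x 9 x 9), label
and provenance arrays.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .features import FeatureTensor
from .synthetic import RawRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_features",
    "load_features",
]

RATING_COLUMNS = ["trial", "valence", "arousal", "latent_valence", "latent_arousal"]


def _subject_paths(directory: str, subject_id: int) -> tuple[str, str]:
    stem = os.path.join(directory, f"subject_{subject_id:02d}")
    return stem + ".h5", stem + "_ratings.csv"


def save_recording(directory: str, rec: RawRecording, ratings: pd.DataFrame) -> str:
    os.makedirs(directory, exist_ok=True)
    h5_path, csv_path = _subject_paths(directory, rec.subject_id)
    with h5py.File(h5_path, "w") as fh:
        ds = fh.create_dataset("data", data=rec.data)
        ds.attrs["sample_rate_hz"] = rec.sample_rate_hz
        ds.attrs["channel_names"] = list(rec.channel_names)
        ds.attrs["subject_id"] = rec.subject_id
    ratings[RATING_COLUMNS].to_csv(csv_path, index=False)
    return h5_path


def load_recording(directory: str, subject_id: int) -> tuple[RawRecording, pd.DataFrame]:
    h5_path, csv_path = _subject_paths(directory, subject_id)
    with h5py.File(h5_path, "r") as fh:
        ds = fh["data"]
        rec = RawRecording(
            data=ds[...],
            sample_rate_hz=float(ds.attrs["sample_rate_hz"]),
            channel_names=tuple(str(c) for c in ds.attrs["channel_names"]),
            subject_id=int(ds.attrs["subject_id"]),
        )
    ratings = pd.read_csv(csv_path)
    return rec, ratings


def save_features(directory: str, feats: FeatureTensor) -> str:
    os.makedirs(directory, exist_ok=True)
    path = os.path.join(directory, f"features_{feats.subject_id:02d}.h5")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("features", data=feats.values)
        fh.create_dataset("labels_valence", data=feats.labels_valence)
        fh.create_dataset("labels_arousal", data=feats.labels_arousal)
        fh.create_dataset("trial_index", data=feats.trial_index)
        fh.create_dataset("segment_index", data=feats.segment_index)
        fh.attrs["subject_id"] = feats.subject_id
    return path


def load_features(directory: str, subject_id: int) -> FeatureTensor:
    path = os.path.join(directory, f"features_{subject_id:02d}.h5")
    with h5py.File(path, "r") as fh:
        return FeatureTensor(
            values=fh["features"][...],
            labels_valence=fh["labels_valence"][...],
            labels_arousal=fh["labels_arousal"][...],
            trial_index=fh["trial_index"][...],
            segment_index=fh["segment_index"][...],
            subject_id=int(fh.attrs["subject_id"]),
        )


def list_subject_ids(directory: str, prefix: str = "subject_") -> list[int]:
    ids = []
    for name in sorted(os.listdir(directory)):
        if name.startswith(prefix) and name.endswith(".h5"):
            ids.append(int(name[len(prefix) : -3]))
    return ids
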
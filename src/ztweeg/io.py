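"""Trial-store file I/O.

Two layouts are supported:

* the native layout — a directory holding ``data.h5`` (datasets ``data``:
  trials x channels x samples float32, ``fs``: scalar) and ``labels.csv``
  (columns ``trial_id, subject, emotion, valence, arousal, dominance,
  liking``); write-then-read round-trips bit-identically;
* an adapter for per-subject arrays in the layout of the public
  valence/arousal-rated EEG corpus: ``data`` 40 x 40 x samples with the first
  32 rows being EEG channels (peripheral channels are dropped) and ``labels``
  40 x 4 carrying (valence, arousal, dominance, liking) ratings that are
  mapped onto discrete emotion labels.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .dataset import (
    DEFAULT_BANDS,
    BandSpec,
    Electrode,
    Trial,
    TrialStore,
    standard_montage,
    vad_to_emotion,
)
from .exceptions import FormatError

LABEL_COLUMNS = ["trial_id", "subject", "emotion", "valence", "arousal", "dominance", "liking"]


def write_store(store: TrialStore, path: str) -> None:
    """Write a store to ``path`` (a directory) in the native layout.

    All trials must share one shape; data is stored as float32.
    """
    if not store.trials:
        raise FormatError("refusing to write an empty store")
    shapes = {t.data.shape for t in store.trials}
    if len(shapes) > 1:
        raise FormatError(f"native layout needs equal trial shapes, got {sorted(shapes)}")
    os.makedirs(path, exist_ok=True)
    data = np.stack([t.data for t in store.trials]).astype(np.float32)
    with h5py.File(os.path.join(path, "data.h5"), "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset("fs", data=float(store.fs))
        f.create_dataset(
            "montage", data=np.array([e.label for e in store.montage], dtype="S16")
        )
    rows = []
    for t in store.trials:
        r = t.ratings if t.ratings is not None else (np.nan,) * 4
        rows.append([t.trial_id, t.subject, t.emotion or "", *r])
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(
        os.path.join(path, "labels.csv"), index=False
    )


def read_store(path: str, bands: Sequence[BandSpec] = DEFAULT_BANDS) -> TrialStore:
    """Read a store written by :func:`write_store`."""
    h5_path = os.path.join(path, "data.h5")
    csv_path = os.path.join(path, "labels.csv")
    if not os.path.exists(h5_path) or not os.path.exists(csv_path):
        raise FormatError(f"{path!r} is not a native store (missing data.h5/labels.csv)")
    with h5py.File(h5_path, "r") as f:
        data = f["data"][()]
        fs = float(f["fs"][()])
        labels = [lb.decode() for lb in f["montage"][()]]
    table = pd.read_csv(csv_path, dtype={"trial_id": str, "subject": str})
    if list(table.columns) != LABEL_COLUMNS:
        raise FormatError(f"labels.csv columns {list(table.columns)} != {LABEL_COLUMNS}")
    if len(table) != data.shape[0]:
        n_missing = data.shape[0] - len(table)
        raise FormatError(
            f"labels.csv has {len(table)} rows for {data.shape[0]} trials "
            f"({n_missing} unlabelled); first trial index without a row: {len(table)}"
        )
    trials = []
    for i, row in table.iterrows():
        ratings: Optional[tuple] = tuple(
            float(row[c]) for c in ("valence", "arousal", "dominance", "liking")
        )
        if any(np.isnan(v) for v in ratings):
            ratings = None
        emotion = row["emotion"] if isinstance(row["emotion"], str) and row["emotion"] else None
        trials.append(
            Trial(
                trial_id=str(row["trial_id"]),
                subject=str(row["subject"]),
                emotion=emotion,
                ratings=ratings,
                data=data[i],
                fs=fs,
            )
        )
    montage = standard_montage(labels)
    return TrialStore(trials, montage=montage, bands=bands)


# -- adapter for per-subject rating-labelled arrays ------------------------

N_EEG_CHANNELS = 32  # rows 0..31 are EEG; later rows are peripheral signals


def _load_subject_arrays(path: str) -> tuple[np.ndarray, np.ndarray]:
    if path.endswith(".npz"):
        with np.load(path) as f:
            return np.asarray(f["data"]), np.asarray(f["labels"])
    if path.endswith(".mat"):
        from scipy.io import loadmat

        m = loadmat(path)
        return np.asarray(m["data"]), np.asarray(m["labels"])
    if path.endswith(".dat"):  # pickled dict release
        import pickle

        with open(path, "rb") as fh:
            d = pickle.load(fh, encoding="latin1")
        return np.asarray(d["data"]), np.asarray(d["labels"])
    raise FormatError(f"unrecognised per-subject array format: {path!r}")


def read_subject_array(
    path: str,
    subject: str,
    fs: float = 128.0,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    montage: Optional[Sequence[Electrode]] = None,
) -> TrialStore:
    """Read one per-subject array file (``.npz``/``.mat``/``.dat``).

    Expects ``data`` shaped (trials, channels, samples) and ``labels``
    (trials, 4).  Only the first 32 (EEG) channels are kept; ratings are
    mapped to discrete emotions via :func:`vad_to_emotion`.
    """
    data, labels = _load_subject_arrays(path)
    if data.ndim != 3 or labels.ndim != 2 or labels.shape[1] != 4:
        raise FormatError(
            f"{path!r}: expected data (trials, channels, samples) and labels "
            f"(trials, 4); got {data.shape} and {labels.shape}"
        )
    if labels.shape[0] != data.shape[0]:
        raise FormatError(
            f"{path!r}: {data.shape[0]} trials but {labels.shape[0]} label rows"
        )
    if data.shape[1] < N_EEG_CHANNELS:
        raise FormatError(
            f"{path!r}: {data.shape[1]} channels < {N_EEG_CHANNELS} EEG channels"
        )
    trials = []
    for i in range(data.shape[0]):
        valence, arousal, dominance, liking = (float(v) for v in labels[i])
        trials.append(
            Trial(
                trial_id=f"{subject}_t{i:02d}",
                subject=subject,
                emotion=vad_to_emotion(valence, arousal),
                ratings=(valence, arousal, dominance, liking),
                data=data[i, :N_EEG_CHANNELS, :],
                fs=fs,
            )
        )
    return TrialStore(
        trials, montage=montage if montage is not None else standard_montage(), bands=bands
    )
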
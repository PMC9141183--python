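"""Containers and preprocessing for multi-subject EEG recordings.

A :class:`Recording` holds one subject's trials (trials x channels x samples,
microvolts) plus the per-trial continuous self-report ratings
(valence, arousal, dominance, liking). Preprocessing follows the standard
cross-subject protocol: keep only the trailing segment of each trial (the
subject needs time to enter the emotional state), slice into fixed,
non-overlapping windows, select a frontal/parietal/temporal/occipital
electrode subset, binarize the valence rating, and z-score features with
parameters estimated on the training portion only.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

#: The 15-electrode subset used by default (10-20 system names):
#: 8 frontal, 2 parietal, 2 temporal, 2 occipital and the central electrode.
DEFAULT_CHANNELS = (
    "AF3", "AF4", "F3", "F4", "F7", "F8", "FP1", "FP2",
    "P7", "P8", "T7", "T8", "O1", "O2", "CZ",
)

#: The 32-electrode Geneva ordering of the DEAP preprocessed release.
DEAP_CHANNELS = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "C4",
    "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2", "Cz",
)

RATING_NAMES = ("valence", "arousal", "dominance", "liking")


@dataclass
class Recording:
    """One subject's EEG block: trials x channels x samples, with ratings."""

    subject_id: str
    signal: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    sampling_rate: float = 128.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    ratings: np.ndarray | None = None  # (n_trials, 4)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 3:
            raise ValueError("signal must be (n_trials, n_channels, n_samples)")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.signal.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[1]} channels"
            )
        if len(set(c.upper() for c in self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.signal.shape[0] < 1:
            raise ValueError("need at least one trial")
        if self.ratings is not None:
            self.ratings = np.asarray(self.ratings, dtype=np.float64)
            if self.ratings.shape[0] != self.signal.shape[0]:
                raise ValueError("ratings rows must match n_trials")

    @property
    def n_trials(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[2]


@dataclass
class WindowedDataset:
    """Non-overlapping fixed-length windows pooled across subjects.

    ``windows`` is (n_windows, n_channels, window_len); ``labels`` holds the
    binarized valence of each window's source trial; ``subject_ids``,
    ``trial_ids`` and ``window_index`` record provenance so evaluation
    protocols can split by subject without leakage.
    """

    windows: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    trial_ids: np.ndarray
    window_index: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n = self.windows.shape[0]
        for name in ("labels", "subject_ids", "trial_ids", "window_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length n_windows={n}")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "trial_id": self.trial_ids,
                "window_index": self.window_index,
                "label": self.labels,
            }
        )

    @staticmethod
    def concatenate(parts: list["WindowedDataset"]) -> "WindowedDataset":
        if not parts:
            raise ValueError("no datasets to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.channel_names != first.channel_names:
                raise ValueError("channel sets differ")
            if p.sampling_rate != first.sampling_rate:
                raise ValueError("sampling rates differ")
        return WindowedDataset(
            windows=np.concatenate([p.windows for p in parts], axis=0),
            labels=np.concatenate([p.labels for p in parts]),
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            trial_ids=np.concatenate([p.trial_ids for p in parts]),
            window_index=np.concatenate([p.window_index for p in parts]),
            sampling_rate=first.sampling_rate,
            channel_names=first.channel_names,
        )


@dataclass
class ZScoreParams:
    """Per-feature standardization parameters (population form, divide by N)."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must have the same shape")
        if np.any(self.std < 0):
            raise ValueError("std must be nonnegative")


def trim_to_last_seconds(rec: Recording, seconds: float) -> Recording:
    """Keep only the trailing ``seconds`` of every trial.

    The opening portion of each trial is discarded because the subject has not
    yet entered the target emotional state; only the final segment (40 s by
    convention) is analysed. Works for both 60 s and baseline-padded 63 s
    trials since it always counts back from the end.
    """
    n_keep = int(round(seconds * rec.sampling_rate))
    if n_keep > rec.n_samples:
        raise ValueError(
            f"requested {seconds} s = {n_keep} samples but trials have only "
            f"{rec.n_samples} samples"
        )
    return replace(rec, signal=rec.signal[:, :, rec.n_samples - n_keep:])


def slice_windows(rec: Recording, window_seconds: float = 10.0,
                  valence_threshold: float = 5.0) -> WindowedDataset:
    """Slice every trial into contiguous non-overlapping windows.

    The trial length must be an exact multiple of the window length; no sample
    is dropped or reused. Each window inherits the binarized valence label of
    its source trial.
    """
    wlen = int(round(window_seconds * rec.sampling_rate))
    if wlen <= 0:
        raise ValueError("window length must be positive")
    if rec.n_samples % wlen != 0:
        raise ValueError(
            f"trial length {rec.n_samples} not divisible by window length {wlen}; "
            "trim first"
        )
    per_trial = rec.n_samples // wlen
    windows = rec.signal.reshape(rec.n_trials, rec.n_channels, per_trial, wlen)
    windows = windows.transpose(0, 2, 1, 3).reshape(
        rec.n_trials * per_trial, rec.n_channels, wlen
    )
    if rec.ratings is not None:
        trial_labels = binarize_valence(rec.ratings[:, 0], valence_threshold)
    else:
        trial_labels = np.zeros(rec.n_trials, dtype=np.int64)
    return WindowedDataset(
        windows=windows,
        labels=np.repeat(trial_labels, per_trial),
        subject_ids=np.asarray([rec.subject_id] * (rec.n_trials * per_trial)),
        trial_ids=np.repeat(np.arange(rec.n_trials), per_trial),
        window_index=np.tile(np.arange(per_trial), rec.n_trials),
        sampling_rate=rec.sampling_rate,
        channel_names=rec.channel_names,
    )


def binarize_valence(ratings: np.ndarray, threshold: float = 5.0) -> np.ndarray:
    """Label 0 for rating <= threshold (negative valence), 1 otherwise."""
    ratings = np.asarray(ratings, dtype=np.float64)
    if not np.all(np.isfinite(ratings)):
        raise ValueError("ratings must be finite")
    return (ratings > threshold).astype(np.int64)


def select_channels(rec: Recording, names: tuple[str, ...] = DEFAULT_CHANNELS) -> Recording:
    """Restrict (and reorder) a recording to the requested electrode subset.

    Matching is case-insensitive so that DEAP's mixed-case labels ("Fp1",
    "Cz") resolve against upper-case 10-20 names.
    """
    lookup = {c.upper(): i for i, c in enumerate(rec.channel_names)}
    idx = []
    for name in names:
        key = str(name).upper()
        if key not in lookup:
            raise KeyError(
                f"channel {name!r} not in recording; available: "
                f"{list(rec.channel_names)}"
            )
        idx.append(lookup[key])
    return replace(
        rec,
        signal=rec.signal[:, idx, :],
        channel_names=tuple(str(n) for n in names),
    )


def zscore_fit(features: np.ndarray) -> ZScoreParams:
    """Estimate per-column mean and population standard deviation (divide by N)."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    return ZScoreParams(mean=features.mean(axis=0), std=features.std(axis=0, ddof=0))


def zscore_apply(features: np.ndarray, params: ZScoreParams) -> np.ndarray:
    """Standardize columns; constant columns (sigma = 0) map to 0."""
    features = np.asarray(features, dtype=np.float64)
    std = np.where(params.std > 0, params.std, 1.0)
    out = (features - params.mean) / std
    out[:, params.std == 0] = 0.0
    return out


# ---------------------------------------------------------------------------
# I/O: DEAP per-subject container dialect and the portable archive dialect
# ---------------------------------------------------------------------------

def read_deap_recording(path: str | os.PathLike, subject_id: str | None = None,
                        sampling_rate: float = 128.0) -> Recording:
    """Read a DEAP-dialect per-subject archive.

    The dialect is a serialized map with a ``data`` array of shape
    (n_trials, 32, n_samples) in the Geneva channel order and a ``labels``
    array of shape (n_trials, 4) holding the continuous ratings. Stored here
    as an NPZ archive.
    """
    with np.load(path, allow_pickle=False) as archive:
        data = np.asarray(archive["data"], dtype=np.float64)
        labels = np.asarray(archive["labels"], dtype=np.float64)
    n_channels = data.shape[1]
    if n_channels == len(DEAP_CHANNELS):
        channels = DEAP_CHANNELS
    else:
        raise ValueError(
            f"DEAP dialect expects 32 channels, got {n_channels}"
        )
    if subject_id is None:
        subject_id = os.path.splitext(os.path.basename(path))[0]
    return Recording(
        subject_id=subject_id,
        signal=data,
        sampling_rate=sampling_rate,
        channel_names=channels,
        ratings=labels,
    )


def write_deap_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording in the DEAP per-subject dialect (32-channel only)."""
    if rec.n_channels != len(DEAP_CHANNELS):
        raise ValueError("DEAP dialect requires the full 32-channel montage")
    ratings = rec.ratings if rec.ratings is not None else np.zeros((rec.n_trials, 4))
    np.savez(path, data=rec.signal, labels=ratings)


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write the portable dialect: NPZ (.npz) or HDF5 (.h5/.hdf5)."""
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=rec.signal)
            if rec.ratings is not None:
                f.create_dataset("ratings", data=rec.ratings)
            f.create_dataset(
                "channel_names",
                data=np.asarray(rec.channel_names, dtype="S"),
            )
            f.attrs["sampling_rate"] = rec.sampling_rate
            f.attrs["subject_id"] = rec.subject_id
    else:
        np.savez(
            path,
            signal=rec.signal,
            ratings=rec.ratings if rec.ratings is not None else np.zeros((rec.n_trials, 4)),
            channel_names=np.asarray(rec.channel_names, dtype="U"),
            sampling_rate=np.asarray(rec.sampling_rate),
            subject_id=np.asarray(rec.subject_id),
        )


def read_recording(path: str | os.PathLike) -> Recording:
    """Read the portable dialect written by :func:`write_recording`."""
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            return Recording(
                subject_id=str(f.attrs.get("subject_id", "unknown")),
                signal=f["signal"][()],
                sampling_rate=float(f.attrs["sampling_rate"]),
                channel_names=tuple(c.decode() for c in f["channel_names"][()]),
                ratings=f["ratings"][()] if "ratings" in f else None,
            )
    with np.load(path, allow_pickle=False) as archive:
        return Recording(
            subject_id=str(archive["subject_id"]),
            signal=archive["signal"],
            sampling_rate=float(archive["sampling_rate"]),
            channel_names=tuple(archive["channel_names"]),
            ratings=archive["ratings"],
        )


def write_provenance_csv(ds: WindowedDataset, path: str | os.PathLike | io.IOBase) -> None:
    """CSV export of a windowed dataset's provenance (no signal data)."""
    ds.provenance_frame().to_csv(path, index=False)
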
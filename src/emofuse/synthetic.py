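"""DEAP-shaped synthetic EEG with controllable class structure.

Each trial is a sum of band-limited Gaussian oscillations (alpha, beta,
gamma; filtered white noise, so entropy and fractal features are
non-degenerate) over a 1/f pink-noise background, with log-normal per-trial
power jitter and a multiplicative per-subject random effect. Positive-valence
trials receive a relative beta-power elevation on the frontal channels and a
left/right alpha asymmetry shift — the same band-power premises the feature
battery is designed to detect. Ratings are generated so that thresholding at
5 recovers the true label exactly when the rating noise is zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from emofuse.data_model import (
    DEAP_CHANNELS,
    DEFAULT_CHANNELS,
    Recording,
    write_deap_recording,
    write_recording,
)

#: left/right frontal homologues used for the asymmetry effect
_ASYM_PAIRS = (("F3", "F4"), ("AF3", "AF4"))
_FRONTAL = ("AF3", "AF4", "F3", "F4", "F7", "F8", "FP1", "FP2")


@dataclass
class SyntheticConfig:
    n_subjects: int = 32
    n_trials: int = 40
    trial_seconds: float = 60.0
    sampling_rate: float = 128.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    #: relative beta-power elevation on frontal channels for positive trials
    beta_effect: float = 0.6
    #: left/right alpha-amplitude ratio shift for positive trials
    asymmetry_effect: float = 0.3
    #: SD of the log-normal per-subject power offset
    subject_sd: float = 0.2
    #: SD of the log-normal per-trial band-power jitter
    trial_sd: float = 0.3
    #: amplitude (muV) of the 1/f background
    pink_amplitude: float = 8.0
    #: base band amplitudes in muV (alpha > beta > gamma, 1/f-like)
    band_amplitudes: dict = field(default_factory=lambda: {
        "alpha": 6.0, "beta": 3.0, "gamma": 1.5,
    })
    #: rating distance from the threshold for a noiseless trial
    rating_margin: float = 2.0
    rating_noise_sd: float = 0.5
    valence_threshold: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_trials) < 1:
            raise ValueError("sizes must be positive")
        if self.trial_seconds <= 0 or self.sampling_rate <= 0:
            raise ValueError("durations and rates must be positive")
        if self.beta_effect < 0 or self.asymmetry_effect < 0:
            raise ValueError("effect sizes must be nonnegative")


_BAND_EDGES = {"alpha": (8.0, 14.0), "beta": (14.0, 30.0), "gamma": (30.0, 47.0)}
_FILTER_PAD = 256  # samples discarded around each band-noise segment


def _band_noise(rng: np.random.Generator, band: str, shape: tuple[int, ...],
                fs: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (4th-order zero-phase Butterworth).

    ``shape`` gives the output shape; filtering runs along the last axis.
    """
    low, high = _BAND_EDGES[band]
    n = shape[-1]
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal(shape[:-1] + (n + _FILTER_PAD,))
    y = sps.sosfiltfilt(sos, white, axis=-1)[..., _FILTER_PAD // 2:
                                             _FILTER_PAD // 2 + n]
    rms = np.sqrt(np.mean(y * y, axis=-1, keepdims=True))
    return y / np.maximum(rms, 1e-12)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping along the last axis."""
    n = shape[-1]
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    freqs[0] = freqs[1]
    y = np.fft.irfft(spec / np.sqrt(freqs), n, axis=-1)
    rms = np.sqrt(np.mean(y * y, axis=-1, keepdims=True))
    return y / np.maximum(rms, 1e-12)


def generate(config: SyntheticConfig) -> tuple[list[Recording], np.ndarray]:
    """Generate one recording per subject plus the true trial labels.

    Returns ``(recordings, labels)`` with ``labels`` of shape
    (n_subjects, n_trials). Identical config + seed give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.trial_seconds * config.sampling_rate))
    fs = config.sampling_rate
    channels = tuple(config.channels)
    n_ch = len(channels)
    n_tr = config.n_trials
    upper = [c.upper() for c in channels]
    frontal = np.isin(upper, _FRONTAL)
    left = np.isin(upper, [l for l, _ in _ASYM_PAIRS])
    right = np.isin(upper, [r for _, r in _ASYM_PAIRS])

    recordings: list[Recording] = []
    all_labels = np.empty((config.n_subjects, n_tr), dtype=np.int64)
    for s in range(config.n_subjects):
        subject_gain = float(np.exp(rng.normal(0.0, config.subject_sd)))
        # balanced trial list per subject (the stimulus sets these data emulate
        # are curated to cover both valence halves evenly); odd counts get a
        # random extra label
        labels = np.repeat([0, 1], n_tr // 2)
        if n_tr % 2:
            labels = np.append(labels, rng.integers(0, 2))
        labels = rng.permutation(labels)
        positive = labels.astype(bool)[:, None]  # (T, 1) broadcast over channels
        signal = config.pink_amplitude * _pink_noise(rng, (n_tr, n_ch, n))
        for band, amp in config.band_amplitudes.items():
            gain = amp * np.exp(rng.normal(0.0, config.trial_sd, (n_tr, n_ch)))
            if band == "beta":
                # power (amplitude^2) elevated on frontal channels of positive trials
                gain = np.where(positive & frontal,
                                gain * np.sqrt(1.0 + config.beta_effect), gain)
            elif band == "alpha":
                shift = np.sqrt(1.0 + config.asymmetry_effect)
                gain = np.where(positive & left, gain * shift, gain)
                gain = np.where(positive & right, gain / shift, gain)
            signal += gain[:, :, None] * _band_noise(rng, band, (n_tr, n_ch, n), fs)
        signal *= subject_gain
        sign = np.where(labels == 1, 1.0, -1.0)
        valence = (config.valence_threshold + sign * config.rating_margin
                   + rng.normal(0.0, config.rating_noise_sd, n_tr))
        ratings = np.column_stack([
            np.clip(valence, 1.0, 9.0),
            rng.uniform(1.0, 9.0, size=(n_tr, 3)),
        ])
        recordings.append(Recording(
            subject_id=f"s{s + 1:02d}",
            signal=signal,
            sampling_rate=fs,
            channel_names=channels,
            ratings=ratings,
        ))
        all_labels[s] = labels
    return recordings, all_labels


def make_fixture_file(config: SyntheticConfig, path: str | os.PathLike,
                      dialect: str = "portable") -> list[str]:
    """Write synthetic recordings to disk; returns the file paths written.

    ``dialect="deap"`` writes the per-subject DEAP container (requires the
    full 32-channel montage in the config); ``"portable"`` writes the NPZ
    archive dialect; ``"hdf5"`` the HDF5 flavor. A truth CSV
    (subject, trial, valence rating, true label) is written alongside.
    """
    recordings, labels = generate(config)
    os.makedirs(path, exist_ok=True)
    written = []
    for rec, lab in zip(recordings, labels):
        if dialect == "deap":
            if rec.n_channels != len(DEAP_CHANNELS):
                raise ValueError("DEAP dialect needs channels=DEAP_CHANNELS (32)")
            fp = os.path.join(path, f"{rec.subject_id}.npz")
            write_deap_recording(rec, fp)
        elif dialect == "portable":
            fp = os.path.join(path, f"{rec.subject_id}.npz")
            write_recording(rec, fp)
        elif dialect == "hdf5":
            fp = os.path.join(path, f"{rec.subject_id}.h5")
            write_recording(rec, fp)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        written.append(fp)
    truth = os.path.join(path, "truth.csv")
    with open(truth, "w") as f:
        f.write("subject_id,trial_id,valence,true_label\n")
        for rec, lab in zip(recordings, labels):
            for t in range(rec.n_trials):
                f.write(f"{rec.subject_id},{t},{rec.ratings[t, 0]:.4f},{lab[t]}\n")
    written.append(truth)
    return written
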
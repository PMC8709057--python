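"""Preprocessing and feature extraction for P300 classification.

Chain (applied identically to training and testing trials):

1. window to 50–600 ms post-onset (half-open, sample ``i`` at time ``i/fs``)
2. zero-phase low-pass: 8th-order Butterworth at 15 Hz, forward–backward
3. detrend: per-channel mean removal over the window
4. downsample by block averaging (factor 4 → 32 Sa/s at fs = 128 Hz)
5. per-trial z-scoring of the flattened (channel, sample) vector

At the defaults with a 14-channel, 128 Hz trial this yields
70 samples/channel → 17 after decimation → a 238-element feature vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import DataError
from .synthgen import EEGTrial

__all__ = [
    "PrepConfig",
    "FeatureVector",
    "window_trial",
    "lowpass_zero_phase",
    "detrend_global_mean",
    "downsample_by_mean",
    "normalize_trial",
    "extract_features",
    "feature_length",
    "features_matrix",
]


@dataclass(frozen=True)
class PrepConfig:
    """Preprocessing parameters (defaults follow the stated pipeline)."""

    window_start_ms: float = 50.0
    window_end_ms: float = 600.0
    filter_order: int = 8
    cutoff_hz: float = 15.0
    decim_factor: int = 4
    #: "per_channel": subtract each channel's own mean;
    #: "grand_average": subtract the across-channel average waveform.
    detrend_mode: str = "per_channel"
    #: "trial": one z-score over the flattened vector; "channel": per channel.
    normalize_scope: str = "trial"

    def __post_init__(self):
        if self.window_start_ms >= self.window_end_ms:
            raise ValueError("window_start must precede window_end")
        if self.decim_factor < 1:
            raise ValueError("decim_factor must be >= 1")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.detrend_mode not in ("per_channel", "grand_average"):
            raise ValueError(f"unknown detrend_mode {self.detrend_mode!r}")
        if self.normalize_scope not in ("trial", "channel"):
            raise ValueError(f"unknown normalize_scope {self.normalize_scope!r}")


@dataclass
class FeatureVector:
    """Flattened per-trial features in (channel, decimated-sample) order."""

    values: np.ndarray
    layout: str
    label: str | None = None

    def __len__(self) -> int:
        return len(self.values)


def _window_indices(fs: float, onset: int, start_ms: float, end_ms: float):
    # sample i sits at (i - onset)/fs; keep start <= t < end (half-open).
    # round() guards float artifacts like 0.05*1000 = 50.000000000000004
    i0 = onset + math.ceil(round(start_ms / 1000.0 * fs, 9))
    i1 = onset + math.ceil(round(end_ms / 1000.0 * fs, 9))
    return i0, i1


def window_trial(trial: EEGTrial, cfg: PrepConfig = PrepConfig()) -> np.ndarray:
    """Extract the analysis window (default 50–600 ms post-onset)."""
    i0, i1 = _window_indices(
        trial.fs, trial.onset_index, cfg.window_start_ms, cfg.window_end_ms
    )
    if i0 < 0 or i1 > trial.n_samples:
        raise DataError(
            f"trial ({trial.n_samples} samples) does not cover the "
            f"{cfg.window_start_ms}-{cfg.window_end_ms} ms window "
            f"(needs samples {i0}..{i1 - 1})"
        )
    return trial.data[:, i0:i1].copy()


def lowpass_zero_phase(x: np.ndarray, fs: float, cfg: PrepConfig = PrepConfig()) -> np.ndarray:
    """Zero-phase Butterworth low-pass, applied forward–backward per channel.

    The filter is designed at ``cfg.filter_order`` and run through
    ``sosfiltfilt``, so the effective magnitude response is the squared
    one-pass response and the group delay is zero.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite input to low-pass filter")
    if cfg.cutoff_hz >= fs / 2.0:
        raise ValueError("cutoff frequency must be below Nyquist")
    sos = signal.butter(cfg.filter_order, cfg.cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def detrend_global_mean(x: np.ndarray, mode: str = "per_channel") -> np.ndarray:
    """Remove the average trend.

    ``per_channel`` subtracts each channel's mean over the window (output
    channel means are 0). ``grand_average`` subtracts the across-channel
    average waveform from every channel.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.size == 0:
        raise ValueError("empty input")
    if mode == "per_channel":
        return x - x.mean(axis=1, keepdims=True)
    if mode == "grand_average":
        return x - x.mean(axis=0, keepdims=True)
    raise ValueError(f"unknown detrend mode {mode!r}")


def downsample_by_mean(x: np.ndarray, factor: int) -> np.ndarray:
    """Replace non-overlapping blocks of ``factor`` samples by their mean.

    Trailing samples that do not fill a block are discarded.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n_keep = (x.shape[1] // factor) * factor
    return x[:, :n_keep].reshape(x.shape[0], -1, factor).mean(axis=2)


def normalize_trial(x: np.ndarray, scope: str = "trial") -> np.ndarray:
    """Z-score to zero mean, unit standard deviation; returns the flattened
    (channel-major) vector. A zero-variance trial is a data error."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if scope == "channel":
        sd = x.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise DataError("zero-variance channel cannot be normalized")
        return ((x - x.mean(axis=1, keepdims=True)) / sd).ravel(order="C")
    flat = x.ravel(order="C")
    sd = flat.std()
    if sd == 0:
        raise DataError("zero-variance trial cannot be normalized")
    return (flat - flat.mean()) / sd


def extract_features(trial: EEGTrial, cfg: PrepConfig = PrepConfig()) -> FeatureVector:
    """Full chain: window → low-pass → detrend → downsample → normalize."""
    w = window_trial(trial, cfg)
    f = lowpass_zero_phase(w, trial.fs, cfg)
    d = detrend_global_mean(f, cfg.detrend_mode)
    m = downsample_by_mean(d, cfg.decim_factor)
    v = normalize_trial(m, cfg.normalize_scope)
    return FeatureVector(values=v, layout="channel-major", label=trial.label)


def feature_length(fs: float, n_channels: int, cfg: PrepConfig = PrepConfig()) -> int:
    """Feature-vector length as a pure function of (fs, n_channels, cfg)."""
    i0, i1 = _window_indices(fs, 0, cfg.window_start_ms, cfg.window_end_ms)
    return n_channels * ((i1 - i0) // cfg.decim_factor)


def features_matrix(trials, cfg: PrepConfig = PrepConfig()):
    """Stack features for a sequence of trials → (X, y) arrays."""
    feats = [extract_features(t, cfg) for t in trials]
    X = np.stack([f.values for f in feats])
    y = np.array([f.label for f in feats])
    return X, y
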
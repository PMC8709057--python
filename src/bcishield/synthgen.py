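"""Synthetic multi-channel EEG generation for P300 speller experiments.

Emulates the statistical structure of a 14-channel, 128 Hz consumer-headset
P300 speller recording: a pink-noise (1/f) background per channel, optional
white sensor noise, and — on target trials — a positive Gaussian-shaped
event-related deflection peaking in the 250–500 ms post-stimulus window,
strongest over parietal sites. Every generator is deterministic given its
seed, so full datasets are reproducible bit-for-bit.

The default "paper scale" dataset holds 240 P300 and 1,200 non-P300 trials
per subject (1:5 class ratio); a ``scale`` argument shrinks both counts
while preserving the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DataError

__all__ = [
    "EEGTrial",
    "SubjectDataset",
    "SubjectProfile",
    "NoiseSpec",
    "EPOC_CHANNELS",
    "DEFAULT_CHANNEL_WEIGHTS",
    "AMPLITUDE_BOUND_UV",
    "make_pink_noise",
    "make_p300_template",
    "subject_profile",
    "synth_trial",
    "synth_subject",
    "synth_dataset",
]

#: Channel montage of the 14-channel wireless headset the generator emulates.
EPOC_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Per-channel P300 amplitude weighting — parietal-dominant, falling off
#: toward frontal sites. A stand-in topography, not a claim about any
#: particular real dataset.
DEFAULT_CHANNEL_WEIGHTS = {
    "AF3": 0.20, "F7": 0.25, "F3": 0.30, "FC5": 0.35, "T7": 0.40,
    "P7": 1.00, "O1": 0.80, "O2": 0.80, "P8": 1.00, "T8": 0.40,
    "FC6": 0.35, "F4": 0.30, "F8": 0.25, "AF4": 0.20,
}

#: Soft amplitude range bound R (µV). Generated trials are soft-clipped so
#: |sample| <= R, which the channel-mixing integrity layer relies on and
#: which mirrors winsorizing-style artifact limits.
AMPLITUDE_BOUND_UV = 100.0

P300_LABEL = "P300"
NONP300_LABEL = "nonP300"
LABELS = (P300_LABEL, NONP300_LABEL)


@dataclass
class EEGTrial:
    """One stimulus-locked multi-channel recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potentials in µV; row ``i`` is channel ``i``.
    fs : float
        Sampling rate in Hz.
    label : str
        ``"P300"`` or ``"nonP300"``.
    provenance : str
        ``"real"``, ``"synthetic"`` or ``"fake"``.
    onset_index : int
        Sample index of the stimulus onset (time zero).
    """

    data: np.ndarray
    fs: float
    label: str
    provenance: str = "synthetic"
    subject_id: str = "S0"
    onset_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("trial data must be a channel x sample matrix")
        if not np.all(np.isfinite(self.data)):
            raise DataError("trial contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self, **changes) -> "EEGTrial":
        new = replace(self, **changes)
        if "data" not in changes:
            new.data = self.data.copy()
        return new


@dataclass
class SubjectDataset:
    """Ordered collection of trials for one subject."""

    trials: list
    subject_id: str = "S0"

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def labels(self) -> list:
        return [t.label for t in self.trials]

    @property
    def counts(self) -> dict:
        labels = self.labels
        return {lab: labels.count(lab) for lab in LABELS}

    @property
    def fs(self) -> float:
        return self.trials[0].fs

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    def channel_limits(self) -> np.ndarray:
        """Per-channel (min, max) over every trial, shape (n_channels, 2)."""
        stack = np.concatenate([t.data for t in self.trials], axis=1)
        return np.stack([stack.min(axis=1), stack.max(axis=1)], axis=1)


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one background-noise component."""

    kind: str = "pink"  # {"pink", "white"}
    amplitude: float = 10.0  # µV RMS
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("pink", "white"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generative parameters (all config-exposed).

    Defaults describe the stated world: 14 channels at 128 Hz, a 6 µV
    Gaussian P300 deflection peaking at 300 ms with 80 ms width, over a
    pink-noise background of 10 µV RMS plus 1 µV white sensor noise.
    """

    fs: float = 128.0
    n_channels: int = 14
    duration_s: float = 0.7
    peak_latency_ms: float = 300.0
    width_ms: float = 80.0
    amplitude_uv: float = 6.0
    pink_rms_uv: float = 10.0
    white_rms_uv: float = 1.0
    channel_weights: tuple = field(
        default=tuple(DEFAULT_CHANNEL_WEIGHTS[ch] for ch in EPOC_CHANNELS)
    )
    latency_jitter_ms: float = 15.0
    amplitude_jitter: float = 0.25
    subject_id: str = "S0"

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_pink_noise(n_samples: int, seed) -> np.ndarray:
    """Zero-mean, unit-variance 1/f ("pink") noise of length ``n_samples``.

    White Gaussian noise is shaped in the frequency domain with a 1/sqrt(f)
    amplitude mask (DC removed) and transformed back, giving a power
    spectral density falling as 1/f. Deterministic given ``seed``.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    if n_samples == 0:
        return np.zeros(0)
    rng = _as_rng(seed)
    white = rng.standard_normal(n_samples)
    if n_samples == 1:
        return np.zeros(1)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    mask = np.zeros_like(freqs)
    mask[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * mask, n=n_samples)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def make_p300_template(
    fs: float = 128.0,
    peak_latency_ms: float = 300.0,
    amplitude_uv: float = 6.0,
    width_ms: float = 80.0,
    duration_s: float = 0.7,
) -> np.ndarray:
    """Single-channel P300 waveform: a positive Gaussian bump.

    The maximum sits at ``peak_latency_ms`` (within one sample) and the
    deflection is zero outside a bounded support of ±3 widths.
    """
    if amplitude_uv < 0:
        raise ValueError("amplitude must be >= 0")
    if width_ms <= 0:
        raise ValueError("width must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(duration_s * fs))
    t_ms = np.arange(n) / fs * 1000.0
    sigma = width_ms / 2.0
    wave = amplitude_uv * np.exp(-0.5 * ((t_ms - peak_latency_ms) / sigma) ** 2)
    wave[np.abs(t_ms - peak_latency_ms) > 3.0 * width_ms] = 0.0
    return wave


def subject_profile(seed, subject_id: str = "S0", base: SubjectProfile | None = None) -> SubjectProfile:
    """Draw a randomized per-subject profile around the defaults.

    Peak latency, amplitude, width and channel topography are jittered so
    that subjects differ (as real participants do) while staying inside the
    canonical 250–500 ms P300 window.
    """
    rng = _as_rng(seed)
    base = base or SubjectProfile()
    weights = np.asarray(base.channel_weights) * rng.uniform(0.8, 1.2, size=base.n_channels)
    return replace(
        base,
        peak_latency_ms=float(rng.uniform(280.0, 380.0)),
        amplitude_uv=float(base.amplitude_uv * rng.uniform(0.85, 1.25)),
        width_ms=float(rng.uniform(70.0, 90.0)),
        channel_weights=tuple(np.round(weights, 6)),
        subject_id=subject_id,
    )


def _soft_clip(x: np.ndarray, bound: float = AMPLITUDE_BOUND_UV) -> np.ndarray:
    return bound * np.tanh(x / bound)


def synth_trial(label: str, profile: SubjectProfile | None = None, seed=0) -> EEGTrial:
    """Generate one trial: pink + white background, plus the P300 deflection
    (latency/amplitude-jittered, parietal-weighted) on target trials.

    Deterministic given ``(label, profile, seed)``; output soft-clipped to
    the amplitude bound R = 100 µV.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    profile = profile or SubjectProfile()
    rng = _as_rng(seed)
    n_ch, n = profile.n_channels, profile.n_samples

    data = np.empty((n_ch, n))
    for ch in range(n_ch):
        data[ch] = profile.pink_rms_uv * make_pink_noise(n, rng)
    if profile.white_rms_uv > 0:
        data += profile.white_rms_uv * rng.standard_normal((n_ch, n))

    if label == P300_LABEL:
        latency = profile.peak_latency_ms + rng.uniform(
            -profile.latency_jitter_ms, profile.latency_jitter_ms
        )
        amp = profile.amplitude_uv * rng.uniform(
            1.0 - profile.amplitude_jitter, 1.0 + profile.amplitude_jitter
        )
        wave = make_p300_template(
            profile.fs, latency, amp, profile.width_ms, profile.duration_s
        )
        weights = np.asarray(profile.channel_weights)[:, None]
        data += weights * wave[None, :]

    return EEGTrial(
        data=_soft_clip(data),
        fs=profile.fs,
        label=label,
        provenance="synthetic",
        subject_id=profile.subject_id,
        onset_index=0,
    )


def synth_subject(
    profile: SubjectProfile,
    n_p300: int = 240,
    n_nonp300: int = 1200,
    seed=0,
) -> SubjectDataset:
    """Generate one subject's dataset with a seeded, shuffled trial order."""
    if n_p300 < 0 or n_nonp300 < 0:
        raise ValueError("trial counts must be >= 0")
    rng = _as_rng(seed)
    labels = np.array([P300_LABEL] * n_p300 + [NONP300_LABEL] * n_nonp300)
    rng.shuffle(labels)
    trials = [synth_trial(lab, profile, rng) for lab in labels]
    return SubjectDataset(trials=trials, subject_id=profile.subject_id)


def synth_dataset(
    n_subjects: int = 5,
    seed: int = 0,
    scale: float = 1.0,
    base_profile: SubjectProfile | None = None,
) -> list:
    """Generate ``n_subjects`` subject datasets at the requested scale.

    At ``scale=1`` each subject holds 240 P300 and 1,200 non-P300 trials
    (1,440 total, 1:5 class ratio); any other scale multiplies both counts,
    preserving the ratio. Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    n_p300 = int(round(240 * scale))
    n_nonp300 = 5 * n_p300
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    datasets = []
    for i, child in enumerate(children):
        prof_ss, trial_ss = child.spawn(2)
        prof = subject_profile(
            np.random.default_rng(prof_ss), subject_id=f"S{i}", base=base_profile
        )
        datasets.append(
            synth_subject(prof, n_p300, n_nonp300, np.random.default_rng(trial_ss))
        )
    return datasets
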
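"""Fake-trial forging and dataset hacking.

Two attack families on the headset→framework link are simulated:

* **AWGN** — additive white Gaussian noise calibrated to a target SNR, with
  the noise variance derived per channel from the measured signal power
  (``var = P / 10^(SNR/10)``).
* **MN_MF** (modulated noise + median filter) — a physiological-looking
  forgery built from donor subjects: class-average waveforms are median
  filtered, amplitude-modulated with locally generated pink noise, and
  rescaled per channel to stay inside the victim stream's amplitude limits
  (evading winsorizing-style rejection)::

      MN_MF[ch, t] = (1 + alpha1 * pn[ch, t]) * MF_sig[ch, t] * k[ch]

Five named presets are shipped: AWGN20, AWGN40, MF3_001, MF9_001, MF9_05.
At "paper scale" a hacked dataset substitutes 400 of 1,440 trials (27.8%),
selected by a Mersenne Twister permutation with seed 4; each substituted
slot receives a fake trial of the same class, so class counts are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .synthgen import (
    AMPLITUDE_BOUND_UV,
    LABELS,
    NONP300_LABEL,
    P300_LABEL,
    EEGTrial,
    SubjectDataset,
    make_pink_noise,
)

__all__ = [
    "AttackTemplate",
    "HackedDataset",
    "AttackPreset",
    "ATTACK_PRESETS",
    "awgn_attack",
    "median_filter",
    "build_templates",
    "mnmf_attack",
    "inject",
]


@dataclass(frozen=True)
class AttackPreset:
    """One named attack configuration."""

    name: str
    family: str  # {"awgn", "mnmf"}
    snr_db: float | None = None
    filter_order: int | None = None
    alpha1: float | None = None


ATTACK_PRESETS = {
    "AWGN20": AttackPreset("AWGN20", "awgn", snr_db=20.0),
    "AWGN40": AttackPreset("AWGN40", "awgn", snr_db=40.0),
    "MF3_001": AttackPreset("MF3_001", "mnmf", filter_order=3, alpha1=0.01),
    "MF9_001": AttackPreset("MF9_001", "mnmf", filter_order=9, alpha1=0.01),
    "MF9_05": AttackPreset("MF9_05", "mnmf", filter_order=9, alpha1=0.5),
}


@dataclass
class AttackTemplate:
    """Donor-derived forging material.

    ``mP3``/``mNP3`` are channel×time class means over donor trials (donors
    must exclude the victim); ``MF_mP3``/``MF_mNP3`` their channel-wise
    median-filtered versions.
    """

    mP3: np.ndarray
    mNP3: np.ndarray
    MF_mP3: np.ndarray
    MF_mNP3: np.ndarray
    filter_order: int
    fs: float
    alpha1: float = 0.01

    @property
    def atck_lims(self) -> dict:
        """Per-class, per-channel (min, max) of the attack waveforms."""
        return {
            P300_LABEL: np.stack(
                [self.MF_mP3.min(axis=1), self.MF_mP3.max(axis=1)], axis=1
            ),
            NONP300_LABEL: np.stack(
                [self.MF_mNP3.min(axis=1), self.MF_mNP3.max(axis=1)], axis=1
            ),
        }


@dataclass
class HackedDataset:
    """A subject dataset with some trials replaced by forgeries."""

    dataset: SubjectDataset
    substituted_indices: np.ndarray
    attack_kind: str

    def __post_init__(self):
        idx = np.asarray(self.substituted_indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("substituted indices must be distinct")
        if len(idx) and (idx.min() < 0 or idx.max() >= len(self.dataset)):
            raise ValueError("substituted index out of range")
        self.substituted_indices = idx

    def __len__(self) -> int:
        return len(self.dataset)

    @property
    def trials(self):
        return self.dataset.trials


def _soft_clip(x: np.ndarray, bound: float) -> np.ndarray:
    return bound * np.tanh(x / bound)


def awgn_attack(
    trial: EEGTrial,
    snr_db: float,
    seed=0,
    amplitude_bound: float | None = AMPLITUDE_BOUND_UV,
) -> EEGTrial:
    """Add white Gaussian noise at the requested SNR.

    Per channel, the mean signal power P is measured and noise of variance
    ``P / 10^(snr_db/10)`` is added. The result is soft-clipped at the
    amplitude bound (the attacker keeps the forged stream inside
    winsorizing limits); pass ``amplitude_bound=None`` to disable.
    Label preserved, provenance ``fake``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    power = np.mean(trial.data**2, axis=1, keepdims=True)
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    noisy = trial.data + sigma * rng.standard_normal(trial.data.shape)
    if amplitude_bound is not None:
        # hard clip: identity inside the winsorizing limits
        noisy = np.clip(noisy, -amplitude_bound, amplitude_bound)
    return trial.copy(data=noisy, provenance="fake")


def median_filter(x: np.ndarray, n: int) -> np.ndarray:
    """Sliding median of odd order ``n`` with a shrinking window at edges.

    ``y[m]`` is the median of the centered ``n``-sample window around
    ``x[m]``; near the edges the window shrinks to the available samples,
    so the output length equals the input length. Works on 1-D sequences
    and channel×time matrices (filtered along time).
    """
    if n < 1 or n % 2 == 0:
        raise ValueError("median filter order must be an odd positive integer")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        return (
            pd.Series(x).rolling(n, center=True, min_periods=1).median().to_numpy()
        )
    if x.ndim == 2:
        return np.stack([median_filter(row, n) for row in x])
    raise ValueError("median_filter expects a 1-D or 2-D array")


def build_templates(donor_trials, n: int, alpha1: float = 0.01) -> AttackTemplate:
    """Average donor trials per class and median-filter each class mean.

    ``donor_trials`` must contain both classes and must come from subjects
    other than the victim (the attacker has no access to the victim's own
    recordings).
    """
    p300 = [t.data for t in donor_trials if t.label == P300_LABEL]
    nonp300 = [t.data for t in donor_trials if t.label == NONP300_LABEL]
    if not p300 or not nonp300:
        raise DataError("donor pool must contain both P300 and nonP300 trials")
    mP3 = np.mean(p300, axis=0)
    mNP3 = np.mean(nonp300, axis=0)
    return AttackTemplate(
        mP3=mP3,
        mNP3=mNP3,
        MF_mP3=median_filter(mP3, n),
        MF_mNP3=median_filter(mNP3, n),
        filter_order=n,
        fs=donor_trials[0].fs,
        alpha1=alpha1,
    )


def _mnmf_forge(
    tmpl: AttackTemplate,
    label: str,
    victim_lims: np.ndarray,
    rng: np.random.Generator,
    alpha1: float | None = None,
    mode: str = "modulate",
) -> EEGTrial:
    """Forge one MN_MF trial of the given class (noise already seeded)."""
    alpha1 = tmpl.alpha1 if alpha1 is None else alpha1
    mf_sig = tmpl.MF_mP3 if label == P300_LABEL else tmpl.MF_mNP3
    if not np.any(mf_sig):
        raise DataError("degenerate (all-zero) attack template")
    n_ch, n = mf_sig.shape
    pn = np.stack([make_pink_noise(n, rng) for _ in range(n_ch)])
    if mode == "modulate":
        wave = (1.0 + alpha1 * pn) * mf_sig
    elif mode == "convolve":
        # literal reading of the combination operator as convolution
        wave = np.stack(
            [np.convolve(alpha1 * pn[ch], mf_sig[ch], mode="same") for ch in range(n_ch)]
        )
    else:
        raise ValueError(f"unknown MN_MF mode {mode!r}")

    victim_lims = np.asarray(victim_lims, dtype=np.float64)
    eeg_abs = np.max(np.abs(victim_lims), axis=1)
    wave_abs = np.max(np.abs(wave), axis=1)
    # shrink-only correction: never amplify toward the winsorizing limits
    with np.errstate(divide="ignore"):
        k = np.minimum(1.0, np.where(wave_abs > 0, eeg_abs / wave_abs, 1.0))
    out = wave * k[:, None]
    return EEGTrial(
        data=out, fs=tmpl.fs, label=label, provenance="fake", onset_index=0
    )


def mnmf_attack(
    tmpl: AttackTemplate,
    victim_lims: np.ndarray,
    class_seed=0,
    noise_seed=0,
    alpha1: float | None = None,
    mode: str = "modulate",
) -> EEGTrial:
    """Forge one modulated-noise/median-filter fake trial.

    The class (P300 vs non-P300 template) is selected at random so both
    targets and non-targets are attacked; the pink-noise modulation and the
    per-channel winsorizing correction ``k = min(1, max|EEG_lims| /
    max|waveform|)`` keep the forgery inside the victim's amplitude limits.
    """
    class_rng = np.random.default_rng(class_seed)
    label = P300_LABEL if class_rng.integers(2) == 0 else NONP300_LABEL
    noise_rng = (
        noise_seed
        if isinstance(noise_seed, np.random.Generator)
        else np.random.default_rng(noise_seed)
    )
    return _mnmf_forge(tmpl, label, victim_lims, noise_rng, alpha1, mode)


def inject(
    dataset: SubjectDataset,
    attack_kind: str,
    templates: AttackTemplate | None = None,
    n_fake: int = 400,
    selection_seed: int = 4,
    attack_seed: int = 0,
) -> HackedDataset:
    """Substitute ``n_fake`` trials of ``dataset`` with forged ones.

    Positions are the first ``n_fake`` entries of a Mersenne Twister
    (MT19937) permutation seeded with ``selection_seed`` (default 4).
    Each substituted slot receives a fake trial of the same class, so the
    class composition of the dataset is unchanged. MN_MF attacks require
    donor ``templates``.
    """
    if attack_kind not in ATTACK_PRESETS:
        raise ValueError(
            f"unknown attack kind {attack_kind!r}; expected one of {sorted(ATTACK_PRESETS)}"
        )
    if n_fake > len(dataset):
        raise ValueError("n_fake exceeds dataset size")
    preset = ATTACK_PRESETS[attack_kind]
    if preset.family == "mnmf":
        if templates is None:
            raise ValueError(f"{attack_kind} requires donor templates")
        if templates.filter_order != preset.filter_order:
            raise ValueError(
                f"{attack_kind} needs order-{preset.filter_order} templates, "
                f"got order {templates.filter_order}"
            )

    mt = np.random.Generator(np.random.MT19937(selection_seed))
    chosen = mt.permutation(len(dataset))[:n_fake]

    rng = np.random.default_rng(attack_seed)
    victim_lims = dataset.channel_limits() if preset.family == "mnmf" else None
    trials = [t.copy() for t in dataset.trials]
    for pos in chosen:
        victim = dataset.trials[pos]
        if preset.family == "awgn":
            fake = awgn_attack(victim, preset.snr_db, rng)
        else:
            fake = _mnmf_forge(
                templates, victim.label, victim_lims, rng, alpha1=preset.alpha1
            )
            fake.subject_id = victim.subject_id
        trials[pos] = fake
    hacked = SubjectDataset(trials=trials, subject_id=dataset.subject_id)
    return HackedDataset(
        dataset=hacked, substituted_indices=np.sort(chosen), attack_kind=attack_kind
    )
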
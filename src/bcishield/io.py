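"""Dataset serialization and import.

A dataset directory holds one JSON manifest (subject id, sampling rate,
channel names, trial list with labels and provenance) plus one delimited
text file per trial (rows = channels, comma-separated µV values). Real
recordings can be imported from delimited text; EDF import requires an EDF
reader (``mne`` or ``pyedflib``) which is looked up lazily.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .attacks import HackedDataset
from .synthgen import EPOC_CHANNELS, EEGTrial, SubjectDataset

__all__ = [
    "save_dataset",
    "load_dataset",
    "read_text_trial",
    "read_edf",
]

_MANIFEST = "manifest.json"


def save_dataset(dataset, out_dir, channel_names=None) -> Path:
    """Write a SubjectDataset (or HackedDataset) to a directory."""
    hacked = isinstance(dataset, HackedDataset)
    subs = dataset.substituted_indices.tolist() if hacked else None
    kind = dataset.attack_kind if hacked else None
    ds = dataset.dataset if hacked else dataset

    out = Path(out_dir)
    trials_dir = out / "trials"
    trials_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, t in enumerate(ds.trials):
        fname = f"trial_{i:05d}.csv"
        np.savetxt(trials_dir / fname, t.data, delimiter=",", fmt="%.6f")
        entries.append(
            {
                "file": f"trials/{fname}",
                "label": t.label,
                "provenance": t.provenance,
                "onset_index": t.onset_index,
            }
        )
    manifest = {
        "subject_id": ds.subject_id,
        "fs": ds.fs,
        "channel_names": list(channel_names or EPOC_CHANNELS[: ds.n_channels]),
        "trials": entries,
    }
    if hacked:
        manifest["attack_kind"] = kind
        manifest["substituted_indices"] = subs
    (out / _MANIFEST).write_text(json.dumps(manifest, indent=1))
    return out


def load_dataset(in_dir):
    """Read a dataset directory back; returns SubjectDataset or HackedDataset."""
    root = Path(in_dir)
    manifest = json.loads((root / _MANIFEST).read_text())
    trials = []
    for e in manifest["trials"]:
        data = np.loadtxt(root / e["file"], delimiter=",", ndmin=2)
        trials.append(
            EEGTrial(
                data=data,
                fs=manifest["fs"],
                label=e["label"],
                provenance=e["provenance"],
                subject_id=manifest["subject_id"],
                onset_index=e["onset_index"],
            )
        )
    ds = SubjectDataset(trials=trials, subject_id=manifest["subject_id"])
    if "attack_kind" in manifest:
        return HackedDataset(
            dataset=ds,
            substituted_indices=np.array(manifest["substituted_indices"], dtype=int),
            attack_kind=manifest["attack_kind"],
        )
    return ds


def read_text_trial(
    path, fs: float, label: str, delimiter=",", subject_id="imported", onset_index=0
) -> EEGTrial:
    """Import one real trial from a delimited-text channel×sample matrix."""
    data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return EEGTrial(
        data=data,
        fs=fs,
        label=label,
        provenance="real",
        subject_id=subject_id,
        onset_index=onset_index,
    )


def read_edf(path, label: str, subject_id="imported"):  # pragma: no cover - optional dep
    """Import one trial from an EDF file (needs ``mne`` or ``pyedflib``)."""
    try:
        import mne  # type: ignore
    except ImportError:
        mne = None
    if mne is not None:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return EEGTrial(
            data=raw.get_data() * 1e6,  # volts → µV
            fs=float(raw.info["sfreq"]),
            label=label,
            provenance="real",
            subject_id=subject_id,
        )
    try:
        import pyedflib  # type: ignore
    except ImportError as exc:
        raise ImportError(
            "EDF import needs the optional 'mne' or 'pyedflib' package; "
            "neither is installed. Use read_text_trial for delimited text."
        ) from exc
    f = pyedflib.EdfReader(str(path))
    try:
        data = np.stack([f.readSignal(i) for i in range(f.signals_in_file)])
        fs = float(f.getSampleFrequency(0))
    finally:
        f.close()
    return EEGTrial(data=data, fs=fs, label=label, provenance="real", subject_id=subject_id)
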
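"""File formats and data-preparation rules.

Hypnograms travel as CSV/TSV with header ``epoch_index,stage`` (0-based,
strictly increasing). Recordings and featurized tensors are stored as .npz
array containers with a JSON sidecar manifest. Preparation rules cover the
R&K-to-5-class remapping (N4 merged into N3; MOVEMENT/UNKNOWN dropped),
in-bed trimming (lights-off to lights-on), the 20-s-to-30-s epoch
conversion (±5 s symmetric margins), and optional EDF reading with
polyphase resampling to 100 Hz (requires mne).

Epoch indexing is 0-based with half-open time windows [n*30 s, (n+1)*30 s).
"""

from __future__ import annotations

import json
import warnings
from fractions import Fraction
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stages import AASM5, StageSequence, StageVocabulary
from .synthetic import EpochSignal, Recording

__all__ = [
    "read_hypnogram",
    "write_hypnogram",
    "remap_stages",
    "trim_to_inbed",
    "convert_epoch_length_20_to_30",
    "read_edf",
    "save_recording",
    "load_recording",
    "save_tfimages",
    "load_tfimages",
    "RK_VOCAB",
]

#: The eight-category R&K scoring vocabulary.
RK_VOCAB = StageVocabulary(
    labels=("W", "N1", "N2", "N3", "N4", "REM", "MOVEMENT", "UNKNOWN")
)

_RK_TO_5CLASS = {
    "W": "W", "N1": "N1", "N2": "N2", "N3": "N3", "N4": "N3", "REM": "REM",
    "MOVEMENT": None, "UNKNOWN": None,
}


def _dialect_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_hypnogram(
    path, vocab: StageVocabulary = AASM5, epoch_sec: float = 30.0
) -> StageSequence:
    """Read an ``epoch_index,stage`` CSV/TSV file into a StageSequence."""
    path = Path(path)
    df = pd.read_csv(path, sep=_dialect_sep(path))
    required = {"epoch_index", "stage"}
    if not required.issubset(df.columns):
        raise ValueError(f"hypnogram file must have columns {sorted(required)}")
    idx = df["epoch_index"].to_numpy()
    if len(idx) and (idx[0] != 0 or np.any(np.diff(idx) <= 0)):
        raise ValueError(
            "epoch_index must be strictly increasing from 0 "
            f"(got first={idx[0] if len(idx) else None})"
        )
    labels = [str(s) for s in df["stage"]]
    return StageSequence(
        tuple(labels), vocab=vocab, epoch_sec=epoch_sec, recording_id=path.stem
    )


def write_hypnogram(seq: StageSequence, path) -> None:
    """Write a StageSequence as an ``epoch_index,stage`` CSV/TSV file."""
    path = Path(path)
    df = pd.DataFrame(
        {"epoch_index": np.arange(len(seq)), "stage": list(seq.labels)}
    )
    df.to_csv(path, sep=_dialect_sep(path), index=False)


def remap_stages(
    seq: StageSequence, scheme: str = "rk_to_5class"
) -> Tuple[StageSequence, np.ndarray]:
    """Remap a scored sequence onto the 5-class vocabulary.

    ``rk_to_5class`` merges N4 into N3 and drops MOVEMENT/UNKNOWN epochs;
    the returned kept-index array realigns any parallel signal arrays.
    ``aasm_passthrough`` validates against the 5-class vocabulary and keeps
    everything.
    """
    if scheme == "aasm_passthrough":
        for lab in seq.labels:
            if lab not in AASM5:
                raise KeyError(
                    f"label {lab!r} not in the 5-class vocabulary "
                    f"{list(AASM5.labels)}"
                )
        out = StageSequence(
            seq.labels, vocab=AASM5, epoch_sec=seq.epoch_sec,
            recording_id=seq.recording_id,
        )
        return out, np.arange(len(seq))
    if scheme != "rk_to_5class":
        raise ValueError(f"unknown remapping scheme {scheme!r}")
    kept_labels: List[str] = []
    kept_idx: List[int] = []
    for i, lab in enumerate(seq.labels):
        if lab not in _RK_TO_5CLASS:
            raise KeyError(
                f"label {lab!r} is not mappable; known source labels are "
                f"{sorted(_RK_TO_5CLASS)}"
            )
        target = _RK_TO_5CLASS[lab]
        if target is None:
            continue
        kept_labels.append(target)
        kept_idx.append(i)
    if not kept_labels:
        warnings.warn("all epochs were MOVEMENT/UNKNOWN; returning empty sequence")
        return (
            StageSequence((), vocab=AASM5, epoch_sec=seq.epoch_sec,
                          recording_id=seq.recording_id),
            np.array([], dtype=np.int64),
        )
    out = StageSequence(
        tuple(kept_labels), vocab=AASM5, epoch_sec=seq.epoch_sec,
        recording_id=seq.recording_id,
    )
    return out, np.asarray(kept_idx, dtype=np.int64)


def trim_to_inbed(
    recording: Recording, lights_off_epoch: int, lights_on_epoch: int
) -> Recording:
    """Keep only the in-bed epochs, indices [lights_off, lights_on)."""
    n = len(recording)
    if not 0 <= lights_off_epoch < lights_on_epoch <= n:
        raise ValueError(
            f"need 0 <= off < on <= {n}, got off={lights_off_epoch}, "
            f"on={lights_on_epoch}"
        )
    sl = slice(lights_off_epoch, lights_on_epoch)
    stages = StageSequence(
        recording.stages.labels[sl],
        vocab=recording.stages.vocab,
        epoch_sec=recording.stages.epoch_sec,
        recording_id=recording.stages.recording_id,
    )
    return Recording(
        epochs=recording.epochs[sl],
        stages=stages,
        subject_id=recording.subject_id,
        seed=recording.seed,
    )


def convert_epoch_length_20_to_30(
    signal: np.ndarray, labels: StageSequence, fs: float
) -> Tuple[List[EpochSignal], StageSequence]:
    """Convert contiguous 20-s-scored signal into 30-s epochs.

    Each 20-s epoch is extended symmetrically by 5 s on each side. Epochs
    whose margins would leave the recording (normally the first and last)
    are dropped with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = signal[None]
    n20 = int(round(20 * fs))
    margin = int(round(5 * fs))
    total = signal.shape[1]
    if total < n20 * len(labels):
        raise ValueError(
            f"signal has {total} samples but {len(labels)} 20-s epochs need "
            f"{n20 * len(labels)}"
        )
    epochs: List[EpochSignal] = []
    kept: List[str] = []
    dropped = 0
    channels = tuple(f"ch{i}" for i in range(signal.shape[0]))
    for i, lab in enumerate(labels.labels):
        start = i * n20 - margin
        stop = (i + 1) * n20 + margin
        if start < 0 or stop > total:
            dropped += 1
            continue
        epochs.append(EpochSignal(signal[:, start:stop], fs=fs, channels=channels))
        kept.append(lab)
    if dropped:
        warnings.warn(
            f"dropped {dropped} epoch(s) whose ±5 s margins leave the recording"
        )
    seq = StageSequence(
        tuple(kept), vocab=labels.vocab, epoch_sec=30.0,
        recording_id=labels.recording_id,
    )
    return epochs, seq


def read_edf(
    path, channels: Sequence[str], target_fs: float = 100.0
) -> Tuple[np.ndarray, float]:
    """Read selected channels from an EDF/EDF+ file, resampled to target_fs.

    Returns (channels x samples array, target_fs). Rational polyphase
    resampling (e.g. 256 -> 100 Hz as 25/64) with the default anti-aliasing
    low-pass. Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "EDF support requires the optional 'mne' dependency "
            "(pip install sleepmt[edf])"
        ) from exc
    from scipy.signal import resample_poly

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = raw.ch_names
    missing = [c for c in channels if c not in available]
    if missing:
        raise KeyError(
            f"channel(s) {missing} not in file; available channels: {available}"
        )
    data = raw.get_data(picks=list(channels))
    fs = float(raw.info["sfreq"])
    if fs == target_fs:
        return data, target_fs
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    out = resample_poly(data, frac.numerator, frac.denominator, axis=1)
    return out, target_fs


# ----- array containers (npz + JSON sidecar manifest) -------------------

def save_recording(recording: Recording, directory, name: str = "recording") -> Path:
    """Write a recording as <name>.npz (signals) + <name>.json (manifest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    npz = directory / f"{name}.npz"
    np.savez(npz, signals=recording.signal_matrix())
    manifest = {
        "format": "sleepmt-recording",
        "version": 1,
        "fs": recording.fs,
        "channels": list(recording.channels),
        "n_epochs": len(recording),
        "epoch_sec": recording.stages.epoch_sec,
        "subject_id": recording.subject_id,
        "seed": recording.seed,
        "vocab": list(recording.stages.vocab.labels),
        "layout": "signals: (n_epochs, n_channels, n_samples)",
    }
    (directory / f"{name}.json").write_text(json.dumps(manifest, indent=2))
    write_hypnogram(recording.stages, directory / f"{name}_hypnogram.csv")
    return npz


def load_recording(directory, name: str = "recording") -> Recording:
    directory = Path(directory)
    manifest = json.loads((directory / f"{name}.json").read_text())
    if manifest.get("format") != "sleepmt-recording":
        raise ValueError("not a recording container")
    with np.load(directory / f"{name}.npz") as data:
        signals = data["signals"]
    if signals.shape[0] != manifest["n_epochs"]:
        raise ValueError("container truncated: epoch count mismatch")
    vocab = StageVocabulary(labels=tuple(manifest["vocab"]))
    stages = read_hypnogram(
        directory / f"{name}_hypnogram.csv", vocab=vocab,
        epoch_sec=manifest["epoch_sec"],
    )
    channels = tuple(manifest["channels"])
    fs = manifest["fs"]
    epochs = [EpochSignal(s, fs=fs, channels=channels) for s in signals]
    return Recording(
        epochs=epochs, stages=stages, subject_id=manifest.get("subject_id"),
        seed=manifest.get("seed"),
    )


def save_tfimages(
    values: np.ndarray, stages: StageSequence, directory,
    name: str = "tfimages", recording_id: Optional[str] = None,
) -> Path:
    """Write featurized (n, P, M, T) tensors + an index manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    values = np.asarray(values, dtype=float)
    if len(values) != len(stages):
        raise ValueError("tensor count and stage count differ")
    npz = directory / f"{name}.npz"
    np.savez(npz, values=values)
    manifest = {
        "format": "sleepmt-tfimages",
        "version": 1,
        "recording_id": recording_id or stages.recording_id,
        "shape": list(values.shape),
        "index": [
            {"epoch_index": i, "stage": lab} for i, lab in enumerate(stages.labels)
        ],
        "vocab": list(stages.vocab.labels),
    }
    (directory / f"{name}.json").write_text(json.dumps(manifest, indent=2))
    return npz


def load_tfimages(directory, name: str = "tfimages") -> Tuple[np.ndarray, StageSequence]:
    directory = Path(directory)
    manifest = json.loads((directory / f"{name}.json").read_text())
    if manifest.get("format") != "sleepmt-tfimages":
        raise ValueError("not a tfimages container")
    with np.load(directory / f"{name}.npz") as data:
        values = data["values"]
    if list(values.shape) != manifest["shape"]:
        raise ValueError("container truncated: tensor shape mismatch")
    vocab = StageVocabulary(labels=tuple(manifest["vocab"]))
    labels = tuple(e["stage"] for e in manifest["index"])
    stages = StageSequence(
        labels, vocab=vocab, recording_id=manifest.get("recording_id")
    )
    return values, stages
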
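"""On-disk epoch container (HDF5) and small text/audio writers.

The container is self-describing: the trials x channels x samples array,
per-trial condition labels, sampling rate, epoch start time, tag
frequencies, and a JSON provenance record all live in one HDF5 file under
a versioned schema.  Round trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .signalgen import EpochSet

SCHEMA_VERSION = "1"


class ContainerError(IOError):
    """Unreadable or structurally invalid epoch container."""


class ContainerVersionError(ContainerError):
    """Container written under an incompatible schema version."""


def write_container(
    epochs: EpochSet,
    path: str | Path,
    tag_freqs: Sequence[float] = (39.0, 43.0),
) -> Path:
    """Write an EpochSet to an HDF5 epoch container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["t0"] = float(epochs.t0)
        f.attrs["tag_freqs"] = np.asarray(tag_freqs, dtype=float)
        f.attrs["provenance"] = json.dumps(epochs.meta, sort_keys=True)
        f.create_dataset("data", data=epochs.data)
        f.create_dataset(
            "labels", data=np.asarray(epochs.labels, dtype="S32")
        )
    return path


def read_container(path: str | Path) -> EpochSet:
    """Read an epoch container; raises ContainerError on corruption and
    ContainerVersionError on schema mismatch (no silent coercion)."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except (OSError, Exception) as exc:  # h5py raises OSError on bad files
        raise ContainerError(f"cannot open epoch container {path}: {exc}") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise ContainerError(f"{path} has no schema_version attribute")
        if str(version) != SCHEMA_VERSION:
            raise ContainerVersionError(
                f"{path} uses schema version {version!r}; this reader supports {SCHEMA_VERSION!r}"
            )
        try:
            data = f["data"][()]
            labels = f["labels"][()].astype(str)
            fs = float(f.attrs["fs"])
            t0 = float(f.attrs["t0"])
            meta = json.loads(f.attrs["provenance"])
            meta["tag_freqs"] = list(np.asarray(f.attrs["tag_freqs"], dtype=float))
        except KeyError as exc:
            raise ContainerError(f"{path} is missing dataset/attribute {exc}") from exc
    if data.ndim != 3 or len(labels) != data.shape[0]:
        raise ContainerError(f"{path}: shape/label mismatch")
    return EpochSet(data, fs, labels, t0, meta)


def container_tag_freqs(path: str | Path) -> list[float]:
    with h5py.File(path, "r") as f:
        return list(np.asarray(f.attrs["tag_freqs"], dtype=float))


def write_wav(waveform: np.ndarray, fs_audio: float, path: str | Path) -> Path:
    """Write a mono waveform as 16-bit PCM WAV."""
    from scipy.io import wavfile

    path = Path(path)
    peak = np.max(np.abs(waveform))
    scaled = waveform / peak if peak > 1.0 else waveform
    wavfile.write(path, int(round(fs_audio)), (scaled * 32767).astype(np.int16))
    return path
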
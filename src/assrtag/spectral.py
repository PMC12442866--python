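"""Split-averaging of epochs into evoked responses and windowed power spectra.

Single-trial steady-state responses are usually buried in sensor noise.
Randomly partitioning a condition's epochs into a few groups and averaging
within each group yields "evoked" responses whose phase-locked components
survive while noise cancels; the squared DFT magnitude of each evoked
response at integer frequencies is then the feature source for decoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import windows as _windows

from .signalgen import EpochSet

WINDOWS = ("hann", "boxcar")


@dataclass
class EvokedSet:
    """Group-averaged responses for one condition: groups x channels x samples."""

    data: np.ndarray
    fs: float
    group_sizes: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.group_sizes = np.asarray(self.group_sizes, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("EvokedSet data must be groups x channels x samples")
        if len(self.group_sizes) != self.data.shape[0]:
            raise ValueError("group_sizes length must equal group count")

    @property
    def n_groups(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class PowerSpectra:
    """Windowed Fourier power per group and channel at integer frequencies."""

    power: np.ndarray  # groups x channels x freqs, >= 0
    freqs: np.ndarray  # integer Hz grid
    window: str
    resolution: float = 1.0  # Hz, = 1 / analysis-window length

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


def _taper(window: str, n: int) -> np.ndarray:
    """Analysis taper, normalized to unit mean so that on-bin sinusoid power
    is identical across window choices (a Hann taper otherwise halves the
    spectral amplitude relative to boxcar)."""
    if window == "boxcar":
        return np.ones(n)
    if window == "hann":
        w = _windows.hann(n, sym=False)
        return w / w.mean()
    raise ValueError(f"unknown window {window!r}; expected one of {WINDOWS}")


def split_average(
    epochs: EpochSet, n_groups: int = 5, rng: np.random.Generator | int | None = None
) -> EvokedSet:
    """Randomly partition one condition's epochs into groups and average.

    The seeded partition assigns every epoch to exactly one group; group
    sizes differ by at most one.  Averaging attenuates non-phase-locked
    noise by roughly sqrt(group size) while leaving the phase-locked
    steady-state components intact.
    """
    labels = np.unique(epochs.labels)
    if len(labels) != 1:
        raise ValueError(f"split_average expects a single-condition EpochSet, got {labels}")
    if epochs.n_trials < n_groups:
        raise ValueError(
            f"cannot split {epochs.n_trials} epochs into {n_groups} groups"
        )
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    perm = gen.permutation(epochs.n_trials)
    groups = np.array_split(perm, n_groups)
    data = np.stack([epochs.data[g].mean(axis=0) for g in groups])
    sizes = np.array([len(g) for g in groups])
    return EvokedSet(data, epochs.fs, sizes, condition=str(labels[0]))


def _freq_indices(freqs: Sequence[float], n: int, fs: float) -> np.ndarray:
    """Map requested frequencies onto rfft bin indices; reject off-grid ones."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > fs / 2.0):
        raise ValueError(f"requested frequencies {freqs} outside [0, Nyquist={fs / 2}]")
    idx = freqs * n / fs
    if np.any(np.abs(idx - np.round(idx)) > 1e-6):
        off = freqs[np.abs(idx - np.round(idx)) > 1e-6]
        raise ValueError(
            f"frequencies {off} do not fall on the {fs / n:.3g}-Hz DFT grid"
        )
    return np.round(idx).astype(int)


def power_spectrum(
    evoked: EvokedSet,
    window: str = "hann",
    freq_range: tuple[float, float] = (4.0, 45.0),
) -> PowerSpectra:
    """Tapered Fourier power of each evoked response at integer frequencies.

    The analysis window spans the full evoked duration, so a 1-s evoked
    response yields exactly 1-Hz frequency resolution.  Power is the
    squared magnitude of the DFT coefficient at each integer frequency in
    ``freq_range`` (inclusive).
    """
    lo, hi = freq_range
    if hi > evoked.fs / 2.0 or lo < 0:
        raise ValueError(f"freq_range {freq_range} outside [0, Nyquist={evoked.fs / 2}]")
    n = evoked.n_samples
    freqs = np.arange(np.ceil(lo), np.floor(hi) + 1)
    idx = _freq_indices(freqs, n, evoked.fs)
    taper = _taper(window, n)
    spec = np.fft.rfft(evoked.data * taper, axis=-1)
    power = np.abs(spec[..., idx]) ** 2
    return PowerSpectra(power, freqs, window, resolution=evoked.fs / n)


@dataclass
class SlidingPower:
    """Per-trial tag-frequency power in overlapping analysis windows."""

    power: np.ndarray  # windows x trials x channels x tag_freqs
    starts: np.ndarray  # window start times, s relative to epoch start
    freqs: np.ndarray
    window: str


def window_starts(epoch_len: float, win_len: float, step: float) -> np.ndarray:
    """Start times of analysis windows fully contained in the epoch."""
    if win_len > epoch_len + 1e-9:
        raise ValueError(f"window length {win_len} s exceeds epoch length {epoch_len} s")
    if step <= 0:
        raise ValueError("step must be positive")
    n_win = int(np.floor((epoch_len - win_len) / step + 1e-9)) + 1
    return np.arange(n_win) * step


def sliding_power(
    epochs: EpochSet,
    win_len: float = 1.0,
    step: float = 0.05,
    window: str = "boxcar",
    tag_freqs: Sequence[float] = (39.0, 43.0),
) -> SlidingPower:
    """Tag-frequency power of every trial in each sliding window.

    Windows start at 0, step, 2*step, ... while they fit inside the epoch;
    the default 2-s epoch / 1-s window / 50-ms step geometry gives 21
    windows.  Windows are labeled by their start time relative to tone
    onset.
    """
    starts = window_starts(epochs.duration, win_len, step)
    n_win_samp = int(round(win_len * epochs.fs))
    idx = _freq_indices(tag_freqs, n_win_samp, epochs.fs)
    taper = _taper(window, n_win_samp)
    power = np.empty((len(starts), epochs.n_trials, epochs.n_channels, len(idx)))
    for w, s in enumerate(starts):
        i0 = int(round(s * epochs.fs))
        seg = epochs.data[:, :, i0: i0 + n_win_samp] * taper
        spec = np.fft.rfft(seg, axis=-1)
        power[w] = np.abs(spec[..., idx]) ** 2
    return SlidingPower(power, starts, np.asarray(tag_freqs, dtype=float), window)
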
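"""Stimulus synthesis and neural epoch simulation for frequency-tagging studies.

Two simultaneous melodies are distinguished by sinusoidal amplitude
modulation at distinct rates (the frequency "tags", 39 and 43 Hz by
default).  The auditory steady-state response (ASSR) phase-locks to the
modulation envelope, so each melody's neural trace is recoverable at its
tag frequency in the power spectrum.  This module synthesizes the tagged
audio, builds melody tone schedules for the two task designs
(alternating-onset and coincident-onset), and simulates multichannel
sensor epochs in which attention toward a melody multiplies the amplitude
of its tagged component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

ATTEND_LOW = "attend_low"
ATTEND_HIGH = "attend_high"
CONDITIONS = (ATTEND_LOW, ATTEND_HIGH)

#: Chance level of the three-alternative (falling / rising / constant)
#: pitch-contour report.
CHANCE_3AFC = 1.0 / 3.0

# Equal-tempered C-major pitches (rounded to the nearest Hz) inside the
# low (131-220 Hz) and high (329-523 Hz) melody registers.
DEFAULT_CARRIERS_LOW = (131.0, 147.0, 165.0, 175.0, 196.0, 220.0)
DEFAULT_CARRIERS_HIGH = (330.0, 349.0, 392.0, 440.0, 494.0, 523.0)


class SimulationError(ValueError):
    """Invalid stimulus or simulation parameters."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of the frequency-tagged two-melody stimulus.

    ``f_m_low`` / ``f_m_high`` are the sinusoidal amplitude-modulation
    rates (Hz) tagging the low- and high-pitched melodies; ``depth_m`` is
    the modulation depth m = (max - min)/(max + min) of the envelope.
    ``design`` selects the task variant: ``"I"`` staggers tone onsets so
    they alternate between melodies, ``"II"`` makes every low tone onset
    coincide with a high tone onset.
    """

    f_m_low: float = 39.0
    f_m_high: float = 43.0
    depth_m: float = 1.0
    carriers_low: tuple[float, ...] = DEFAULT_CARRIERS_LOW
    carriers_high: tuple[float, ...] = DEFAULT_CARRIERS_HIGH
    tone_dur: float = 2.0
    melody_dur_range: tuple[float, float] = (8.0, 26.0)
    design: str = "I"
    fs_audio: float = 44100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth_m <= 1.0:
            raise SimulationError(f"modulation depth must be in [0, 1], got {self.depth_m}")
        if self.design not in ("I", "II"):
            raise SimulationError(f"design must be 'I' or 'II', got {self.design!r}")
        nyq = self.fs_audio / 2.0
        for f in (self.f_m_low, self.f_m_high, *self.carriers_low, *self.carriers_high):
            if f >= nyq:
                raise SimulationError(f"frequency {f} Hz is at or above Nyquist ({nyq} Hz)")
        lo, hi = self.melody_dur_range
        if lo < self.tone_dur:
            raise SimulationError(
                f"melody_dur_range minimum ({lo} s) shorter than one tone ({self.tone_dur} s)"
            )
        if hi < lo:
            raise SimulationError("melody_dur_range must be (min, max) with min <= max")


@dataclass(frozen=True)
class ToneEvent:
    onset: float
    stream: str  # "low" | "high"
    carrier: float
    duration: float


@dataclass
class ToneSchedule:
    """Onset schedule of the two melodies within one playback block."""

    entries: list[ToneEvent]
    total_dur: float
    design: str

    def onsets(self, stream: str) -> np.ndarray:
        return np.array([e.onset for e in self.entries if e.stream == stream])

    def validate(self) -> None:
        for stream in ("low", "high"):
            on = self.onsets(stream)
            if on.size and (np.any(on < 0) or np.any(np.diff(on) < 0)):
                raise SimulationError(f"{stream}-stream onsets must be non-negative, sorted")
        for e in self.entries:
            if e.onset + e.duration > self.total_dur + 1e-9:
                raise SimulationError("tone extends past end of melody")
        if self.design == "I":
            streams = [e.stream for e in sorted(self.entries, key=lambda e: e.onset)]
            if any(a == b for a, b in zip(streams, streams[1:])):
                raise SimulationError("design I onsets must alternate between streams")
        elif self.design == "II":
            if not np.array_equal(self.onsets("low"), self.onsets("high")):
                raise SimulationError("design II requires coincident low/high onsets")


@dataclass(frozen=True)
class NeuralSimConfig:
    """Parameters of the multichannel sensor-level epoch simulator.

    Each tagged melody contributes a sinusoid at its tag frequency,
    phase-locked across trials, whose amplitude is ``assr_amp`` scaled by
    ``attention_gain`` when that melody is attended, projected to the
    sensors through a fixed per-tag spatial mixing pattern.  Background
    activity is white Gaussian noise plus 1/f^alpha ("pink") noise.
    ``gain_timecourse``, if given, is a per-sample profile multiplying the
    tagged components, used to emulate attention that waxes or wanes over
    the epoch.
    """

    n_channels: int = 306
    fs: float = 1000.0
    epoch_len: float = 1.0
    n_epochs_per_cond: int = 228
    assr_amp: float = 0.05
    attention_gain: float = 2.0
    noise_white_sd: float = 1.0
    noise_pink_sd: float = 1.0
    noise_pink_exponent: float = 1.0
    mixing_patterns: tuple | None = None
    gain_timecourse: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attention_gain <= 0:
            raise SimulationError(f"attention_gain must be > 0, got {self.attention_gain}")
        if self.n_channels < 2:
            raise SimulationError("at least 2 channels required")
        if self.noise_pink_exponent < 0:
            raise SimulationError("noise_pink_exponent must be >= 0")
        n = self.epoch_len * self.fs
        if abs(n - round(n)) > 1e-9:
            raise SimulationError(
                f"epoch_len * fs must be an integer sample count, got {n}"
            )
        if self.mixing_patterns is not None:
            for p in self.mixing_patterns:
                if len(p) != self.n_channels:
                    raise SimulationError("mixing pattern length must equal n_channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_len * self.fs))


@dataclass
class EpochSet:
    """Trials x channels x samples sensor data with per-trial condition labels."""

    data: np.ndarray
    fs: float
    labels: np.ndarray
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EpochSet data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def select(self, label: str) -> "EpochSet":
        """Subset of trials with the given condition label."""
        mask = self.labels == label
        if not np.any(mask):
            raise ValueError(f"no trials with label {label!r}")
        return EpochSet(self.data[mask], self.fs, self.labels[mask], self.t0, dict(self.meta))

    def crop(self, start: float, stop: float) -> "EpochSet":
        """Time-slice every trial to [start, stop) seconds from epoch start."""
        i0 = int(round(start * self.fs))
        i1 = int(round(stop * self.fs))
        if not 0 <= i0 < i1 <= self.n_samples:
            raise ValueError(f"crop window [{start}, {stop}) outside epoch")
        return EpochSet(self.data[:, :, i0:i1], self.fs, self.labels, self.t0 + start, dict(self.meta))


# ---------------------------------------------------------------------------
# stimulus synthesis
# ---------------------------------------------------------------------------


def generate_am_tone(
    carrier: float, f_m: float, depth_m: float, dur: float, fs_audio: float = 44100.0
) -> np.ndarray:
    """Sinusoidally amplitude-modulated tone.

    The waveform is sin(2*pi*carrier*t) scaled by the envelope
    e(t) = (1 + depth_m*sin(2*pi*f_m*t)) / 2, so the peak amplitude never
    exceeds 1 and the envelope depth (max-min)/(max+min) equals depth_m.
    """
    nyq = fs_audio / 2.0
    if carrier >= nyq:
        raise SimulationError(f"carrier {carrier} Hz is at or above Nyquist ({nyq} Hz)")
    if f_m >= nyq:
        raise SimulationError(f"modulation frequency {f_m} Hz is at or above Nyquist ({nyq} Hz)")
    if not 0.0 <= depth_m <= 1.0:
        raise SimulationError(f"modulation depth must be in [0, 1], got {depth_m}")
    if dur <= 0:
        raise SimulationError("duration must be positive")
    t = np.arange(int(round(dur * fs_audio))) / fs_audio
    envelope = (1.0 + depth_m * np.sin(2 * np.pi * f_m * t)) / 2.0
    return np.sin(2 * np.pi * carrier * t) * envelope


def am_envelope(waveform: np.ndarray, trim_frac: float = 0.05) -> np.ndarray:
    """Amplitude envelope of a narrowband waveform via the analytic signal.

    The first and last ``trim_frac`` of samples are discarded to avoid
    end effects of the finite-length Hilbert transform.
    """
    env = np.abs(hilbert(waveform))
    k = int(len(env) * trim_frac)
    return env[k: len(env) - k] if k else env


def measure_modulation_depth(waveform: np.ndarray, trim_frac: float = 0.05) -> float:
    """Envelope modulation depth (max - min)/(max + min), measured from data.

    Robust percentiles (99.5 / 0.5) stand in for the extremes so that a
    handful of edge samples cannot dominate.
    """
    env = am_envelope(waveform, trim_frac)
    hi = np.percentile(env, 99.5)
    lo = np.percentile(env, 0.5)
    return (hi - lo) / (hi + lo)


def envelope_peak_frequency(waveform: np.ndarray, fs_audio: float) -> float:
    """Frequency (Hz) of the largest non-DC line in the envelope spectrum.

    The spectrum is taken over a central whole-second segment (when the
    waveform is long enough) so integer modulation rates fall exactly on
    the frequency grid.
    """
    env = am_envelope(waveform)
    n_sec = int(len(env) / fs_audio)
    if n_sec >= 1:
        n = int(round(n_sec * fs_audio))
        start = (len(env) - n) // 2
        env = env[start: start + n]
    env = env - env.mean()
    spec = np.abs(np.fft.rfft(env))
    freqs = np.fft.rfftfreq(len(env), d=1.0 / fs_audio)
    return float(freqs[np.argmax(spec)])


def build_schedule(cfg: StimulusConfig) -> ToneSchedule:
    """Tone onset schedule for one melody block.

    Design I staggers the two streams by half a tone duration so that
    onsets strictly alternate between the low- and high-pitched melodies
    (each onset then starts a decodable epoch of one stream free of the
    other stream's onset transient).  Design II places every high tone
    exactly on a low tone onset.  Block duration is drawn uniformly from
    ``melody_dur_range`` using the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    total_dur = float(rng.uniform(*cfg.melody_dur_range))
    stagger = cfg.tone_dur / 2.0
    entries: list[ToneEvent] = []

    def _pick(stream: str) -> float:
        pool = cfg.carriers_low if stream == "low" else cfg.carriers_high
        return float(rng.choice(pool))

    if cfg.design == "I":
        first = str(rng.choice(["low", "high"]))
        second = "high" if first == "low" else "low"
        t = 0.0
        k = 0
        while t + cfg.tone_dur <= total_dur + 1e-9:
            stream = first if k % 2 == 0 else second
            entries.append(ToneEvent(t, stream, _pick(stream), cfg.tone_dur))
            t += stagger
            k += 1
    else:
        t = 0.0
        while t + cfg.tone_dur <= total_dur + 1e-9:
            entries.append(ToneEvent(t, "low", _pick("low"), cfg.tone_dur))
            entries.append(ToneEvent(t, "high", _pick("high"), cfg.tone_dur))
            t += cfg.tone_dur
    sched = ToneSchedule(entries, total_dur, cfg.design)
    sched.validate()
    return sched


def render_melodies(schedule: ToneSchedule, cfg: StimulusConfig) -> np.ndarray:
    """Mix the scheduled AM tones of both streams into one mono waveform."""
    n = int(round(schedule.total_dur * cfg.fs_audio))
    out = np.zeros(n)
    for e in schedule.entries:
        f_m = cfg.f_m_low if e.stream == "low" else cfg.f_m_high
        tone = generate_am_tone(e.carrier, f_m, cfg.depth_m, e.duration, cfg.fs_audio)
        i0 = int(round(e.onset * cfg.fs_audio))
        out[i0: i0 + len(tone)] += tone
    peak = np.max(np.abs(out))
    return out / peak if peak > 1.0 else out


# ---------------------------------------------------------------------------
# neural simulation
# ---------------------------------------------------------------------------


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], alpha: float, sd: float) -> np.ndarray:
    """Gaussian noise spectrally shaped to 1/f^alpha power, rescaled to sd."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if alpha == 0:
        return sd * white
    n = shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-alpha / 2.0)
    shaped = np.fft.irfft(spec * shaping, n=n, axis=-1)
    scale = shaped.std()
    return sd * shaped / scale if scale > 0 else shaped


def simulate_epochs(cfg: NeuralSimConfig, tag_freqs: Sequence[float] = (39.0, 43.0)) -> EpochSet:
    """Simulate a balanced two-condition epoch set with tagged components.

    ``tag_freqs[0]`` tags the low-pitched melody (its amplitude is boosted
    by ``attention_gain`` on attend-low trials) and ``tag_freqs[1]`` the
    high-pitched melody.  Tag phases and spatial mixing patterns are drawn
    once per simulation and held fixed, making the steady-state components
    phase-locked across trials; everything is reproducible from the seed.
    """
    nyq = cfg.fs / 2.0
    for f in tag_freqs:
        if f >= nyq:
            raise SimulationError(f"tag frequency {f} Hz is at or above Nyquist ({nyq} Hz)")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs

    phases = rng.uniform(0, 2 * np.pi, size=len(tag_freqs))
    if cfg.mixing_patterns is not None:
        patterns = np.asarray(cfg.mixing_patterns, dtype=float)
    else:
        patterns = rng.standard_normal((len(tag_freqs), cfg.n_channels))

    if cfg.gain_timecourse is not None:
        gt = np.asarray(cfg.gain_timecourse, dtype=float)
        if gt.shape != (n,):
            raise SimulationError(f"gain_timecourse must have {n} samples, got {gt.shape}")
    else:
        gt = np.ones(n)

    # condition templates: channels x samples, built once per condition
    templates = {}
    for cond in CONDITIONS:
        sig = np.zeros((cfg.n_channels, n))
        for k, f in enumerate(tag_freqs):
            attended = (cond == ATTEND_LOW and k == 0) or (cond == ATTEND_HIGH and k == 1)
            gain = cfg.attention_gain if attended else 1.0
            wave = cfg.assr_amp * gain * gt * np.sin(2 * np.pi * f * t + phases[k])
            sig += np.outer(patterns[k], wave)
        templates[cond] = sig

    n_tot = 2 * cfg.n_epochs_per_cond
    labels = np.array([ATTEND_LOW] * cfg.n_epochs_per_cond + [ATTEND_HIGH] * cfg.n_epochs_per_cond)
    data = np.empty((n_tot, cfg.n_channels, n))
    for i, lab in enumerate(labels):
        noise = rng.normal(0.0, cfg.noise_white_sd, size=(cfg.n_channels, n)) if cfg.noise_white_sd > 0 else 0.0
        pink = _pink_noise(rng, (cfg.n_channels, n), cfg.noise_pink_exponent, cfg.noise_pink_sd)
        data[i] = templates[lab] + noise + pink

    meta = {
        "generator": "assrtag.signalgen.simulate_epochs",
        "tag_freqs": list(map(float, tag_freqs)),
        "config": json.dumps(_jsonable(asdict(cfg))),
    }
    return EpochSet(data, cfg.fs, labels, t0=0.0, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# behavioral simulation
# ---------------------------------------------------------------------------


def simulate_responses(n_trials: int, p_correct: float, seed: int = 0) -> float:
    """Fraction correct of a simulated 3-alternative pitch-contour reporter.

    Each trial is an independent Bernoulli(p_correct) success.  A uniform
    random responder corresponds to ``p_correct = CHANCE_3AFC`` (1/3).
    """
    if n_trials <= 0:
        raise SimulationError("n_trials must be positive")
    if not 0.0 <= p_correct <= 1.0:
        raise SimulationError(f"p_correct must be in [0, 1], got {p_correct}")
    rng = np.random.default_rng(seed)
    return float(np.mean(rng.random(n_trials) < p_correct))
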
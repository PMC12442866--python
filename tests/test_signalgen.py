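"""Stimulus synthesis and neural/behavioral simulation."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from assrtag import (
    ATTEND_HIGH,
    ATTEND_LOW,
    EpochSet,
    NeuralSimConfig,
    SimulationError,
    StimulusConfig,
    build_schedule,
    envelope_peak_frequency,
    generate_am_tone,
    measure_modulation_depth,
    power_spectrum,
    render_melodies,
    simulate_epochs,
    simulate_responses,
    split_average,
)
from assrtag.signalgen import CHANCE_3AFC


class TestAmTone:
    def test_envelope_spectrum_peaks_at_modulation_frequency(self):
        for f_m in (39.0, 43.0):
            wave = generate_am_tone(131.0, f_m, 1.0, 2.0, 44100.0)
            assert envelope_peak_frequency(wave, 44100.0) == pytest.approx(f_m, abs=0.5)

    def test_zero_depth_gives_pure_carrier(self):
        wave = generate_am_tone(147.0, 39.0, 0.0, 1.0, 44100.0)
        spec = np.abs(np.fft.rfft(wave))
        freqs = np.fft.rfftfreq(len(wave), 1 / 44100.0)
        peak = freqs[np.argmax(spec)]
        assert peak == pytest.approx(147.0, abs=0.5)
        # single line: everything else is negligible
        others = spec[np.abs(freqs - 147.0) > 1.0]
        assert others.max() < 1e-6 * spec.max()

    def test_sidebands_at_carrier_plus_minus_fm_with_amplitude_m_over_2(self):
        # FFT oracle: AM with depth m puts sidebands at f_c +/- f_m, each
        # m/2 the carrier line amplitude
        fs, fc, fm, m = 44100.0, 220.0, 39.0, 0.8
        wave = generate_am_tone(fc, fm, m, 2.0, fs)
        spec = np.abs(np.fft.rfft(wave))
        freqs = np.fft.rfftfreq(len(wave), 1 / fs)

        def line(f):
            return spec[np.argmin(np.abs(freqs - f))]

        assert line(fc - fm) / line(fc) == pytest.approx(m / 2, rel=1e-6)
        assert line(fc + fm) / line(fc) == pytest.approx(m / 2, rel=1e-6)

    def test_peak_amplitude_bounded_by_one(self):
        wave = generate_am_tone(131.0, 39.0, 1.0, 1.0, 44100.0)
        assert np.max(np.abs(wave)) <= 1.0 + 1e-12

    @settings(max_examples=25, deadline=None)
    @given(m=st.floats(min_value=0.05, max_value=1.0))
    def test_measured_depth_matches_configured_depth(self, m):
        wave = generate_am_tone(131.0, 39.0, m, 2.0, 44100.0)
        assert measure_modulation_depth(wave) == pytest.approx(m, abs=0.02)

    def test_above_nyquist_rejected_with_frequency_named(self):
        with pytest.raises(SimulationError, match="30000"):
            generate_am_tone(30000.0, 39.0, 1.0, 1.0, 44100.0)
        with pytest.raises(SimulationError, match="25000"):
            generate_am_tone(131.0, 25000.0, 1.0, 1.0, 44100.0)


def _oracle_design1_onsets(total_dur, tone_dur, stagger):
    """Brute-force event enumeration: onsets every `stagger` while the tone fits."""
    onsets = []
    t = 0.0
    while t + tone_dur <= total_dur + 1e-9:
        onsets.append(t)
        t += stagger
    return onsets


class TestSchedule:
    def test_design1_onsets_alternate_and_match_enumeration_oracle(self):
        cfg = StimulusConfig(design="I", melody_dur_range=(10.0, 10.0), seed=5)
        sched = build_schedule(cfg)
        events = sorted(sched.entries, key=lambda e: e.onset)
        streams = [e.stream for e in events]
        assert all(a != b for a, b in zip(streams, streams[1:]))
        expected = _oracle_design1_onsets(10.0, 2.0, 1.0)
        assert [e.onset for e in events] == pytest.approx(expected)
        # per-stream counts from the oracle: alternating assignment
        n_first = len(expected[::2])
        assert sorted([len(sched.onsets("low")), len(sched.onsets("high"))]) == sorted(
            [n_first, len(expected) - n_first]
        )

    def test_design2_minimal_schedule_has_one_coincident_pair(self):
        cfg = StimulusConfig(design="II", melody_dur_range=(2.0, 2.0), seed=0)
        sched = build_schedule(cfg)
        assert len(sched.entries) == 2
        assert np.array_equal(sched.onsets("low"), sched.onsets("high"))
        assert sched.onsets("low").tolist() == [0.0]

    def test_design2_all_onsets_coincide(self):
        cfg = StimulusConfig(design="II", melody_dur_range=(12.0, 12.0), seed=1)
        sched = build_schedule(cfg)
        assert np.array_equal(sched.onsets("low"), sched.onsets("high"))

    def test_melody_shorter_than_tone_rejected(self):
        with pytest.raises(SimulationError):
            StimulusConfig(melody_dur_range=(1.0, 26.0))

    def test_total_duration_within_configured_range(self):
        for seed in range(5):
            sched = build_schedule(StimulusConfig(seed=seed))
            assert 8.0 <= sched.total_dur <= 26.0

    def test_rendered_melody_is_finite_and_bounded(self):
        cfg = StimulusConfig(melody_dur_range=(8.0, 8.0), seed=2)
        wave = render_melodies(build_schedule(cfg), cfg)
        assert np.all(np.isfinite(wave))
        assert np.max(np.abs(wave)) <= 1.0 + 1e-12


class TestSimulateEpochs:
    def test_default_design1_geometry(self):
        cfg = NeuralSimConfig(n_epochs_per_cond=8, n_channels=6, fs=200.0, seed=0)
        ep = simulate_epochs(cfg)
        assert ep.data.shape == (16, 6, 200)
        assert (ep.labels == ATTEND_LOW).sum() == 8
        assert (ep.labels == ATTEND_HIGH).sum() == 8

    def test_bit_reproducible_from_seed(self):
        cfg = NeuralSimConfig(n_epochs_per_cond=4, n_channels=4, fs=200.0, seed=42)
        a = simulate_epochs(cfg)
        b = simulate_epochs(cfg)
        assert np.array_equal(a.data, b.data)
        c = simulate_epochs(replace(cfg, seed=43))
        assert not np.array_equal(a.data, c.data)

    def test_noise_free_tag_power_matches_sinusoid_closed_form(self):
        # boxcar power of an on-bin sinusoid of amplitude A is (A*N/2)^2
        patterns = np.ones((2, 3))
        cfg = NeuralSimConfig(
            n_channels=3, fs=200.0, n_epochs_per_cond=5, assr_amp=0.2,
            attention_gain=1.5, noise_white_sd=0.0, noise_pink_sd=0.0,
            mixing_patterns=tuple(map(tuple, patterns)), seed=0,
        )
        ep = simulate_epochs(cfg, (39.0, 43.0))
        ev = split_average(ep.select(ATTEND_LOW), 5, rng=0)
        ps = power_spectrum(ev, window="boxcar", freq_range=(4.0, 45.0))
        n = 200
        attended = (0.2 * 1.5 * n / 2) ** 2
        unattended = (0.2 * n / 2) ** 2
        got39 = ps.power[:, :, np.flatnonzero(ps.freqs == 39)[0]]
        got43 = ps.power[:, :, np.flatnonzero(ps.freqs == 43)[0]]
        assert got39 == pytest.approx(attended, rel=1e-9)
        assert got43 == pytest.approx(unattended, rel=1e-9)

    def test_tag_power_scales_as_gain_squared(self):
        powers = []
        for gain in (1.0, 1.5, 2.0):
            cfg = NeuralSimConfig(
                n_channels=2, fs=200.0, n_epochs_per_cond=2, assr_amp=0.1,
                attention_gain=gain, noise_white_sd=0.0, noise_pink_sd=0.0,
                mixing_patterns=((1.0, 1.0), (1.0, 1.0)), seed=0,
            )
            ep = simulate_epochs(cfg)
            ev = split_average(ep.select(ATTEND_LOW), 2, rng=0)
            ps = power_spectrum(ev, "boxcar", (39.0, 39.0))
            powers.append(ps.power[0, 0, 0])
        ratios = np.array(powers) / powers[0]
        assert ratios == pytest.approx([1.0, 1.5**2, 2.0**2], rel=1e-9)

    def test_gain_timecourse_shifts_energy_to_late_half(self):
        n = 400
        gt = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        cfg = NeuralSimConfig(
            n_channels=2, fs=200.0, epoch_len=2.0, n_epochs_per_cond=2,
            noise_white_sd=0.0, noise_pink_sd=0.0, gain_timecourse=tuple(gt), seed=0,
        )
        ep = simulate_epochs(cfg)
        early = np.sum(ep.data[:, :, : n // 2] ** 2)
        late = np.sum(ep.data[:, :, n // 2:] ** 2)
        assert early == 0.0
        assert late > 0.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(SimulationError):
            NeuralSimConfig(epoch_len=0.3305, fs=1000.0)
        with pytest.raises(SimulationError):
            NeuralSimConfig(attention_gain=0.0)
        with pytest.raises(SimulationError):
            simulate_epochs(NeuralSimConfig(fs=60.0, n_channels=2, n_epochs_per_cond=2))


class TestResponses:
    def test_perfect_and_chance_responders(self):
        assert simulate_responses(100, 1.0, seed=0) == 1.0
        frac = simulate_responses(100_000, CHANCE_3AFC, seed=1)
        assert frac == pytest.approx(1 / 3, abs=0.01)

    def test_sampling_distribution_matches_binomial_oracle(self):
        n, p = 28, 0.7
        fracs = np.array([simulate_responses(n, p, seed=s) for s in range(400)])
        assert fracs.mean() == pytest.approx(p, abs=0.02)
        assert fracs.var() == pytest.approx(p * (1 - p) / n, rel=0.25)

    def test_zero_trials_rejected(self):
        with pytest.raises(SimulationError):
            simulate_responses(0, 0.5)


class TestEpochSet:
    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EpochSet(np.zeros((3, 2, 10)), 100.0, np.array(["a", "b"]))

    def test_crop_slices_time_axis(self):
        ep = EpochSet(np.arange(40, dtype=float).reshape(1, 2, 20), 10.0,
                      np.array([ATTEND_LOW]))
        half = ep.crop(0.0, 1.0)
        assert half.n_samples == 10
        assert half.duration == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ep.crop(1.0, 3.0)
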
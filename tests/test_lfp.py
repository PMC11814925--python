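"""LFP chain: downsampling, ripple detection, spectrograms, band power."""

import numpy as np
import pytest

from remapkit._rng import rng_for
from remapkit.lfp import (BANDS, RippleEvent, assign_peak_frequencies,
                          band_power, detect_ripples, downsample,
                          filter_events_to_mask, find_ripples,
                          immobility_mask, morlet_spectrogram,
                          ripple_envelope, ripple_peak_frequency, swr_rate)
from remapkit.session import Lfp, PositionTrack
from remapkit.synthetic import LfpSpec, schedule_ripples, simulate_lfp


def tone(freq, duration=10.0, fs=1200.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return Lfp(amp * np.sin(2 * np.pi * freq * t), fs)


class TestDownsample:
    def test_dc_preserved_and_length_divided(self):
        lfp = Lfp(np.full(4800 * 4, 2.5), 4800.0)
        out = downsample(lfp, 1200.0)
        assert out.sample_rate == 1200.0
        assert out.samples.size == lfp.samples.size // 4
        np.testing.assert_allclose(out.samples[50:-50], 2.5, rtol=1e-6)

    def test_in_band_sinusoid_amplitude_preserved(self):
        out = downsample(tone(100.0, duration=4.0, fs=4800.0), 1200.0)
        amp = np.percentile(np.abs(out.samples[200:-200]), 99.9)
        assert abs(amp - 1.0) < 0.02

    def test_aliasing_component_suppressed(self):
        out = downsample(tone(2000.0, duration=4.0, fs=4800.0), 1200.0)
        peak = np.abs(out.samples[200:-200]).max()
        assert 20 * np.log10(peak) < -40

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(tone(10.0, fs=1200.0), 2400.0)


class TestRippleEnvelope:
    def test_white_noise_envelope_is_zscored(self, rng):
        lfp = Lfp(rng.standard_normal(1200 * 60), 1200.0)
        env = ripple_envelope(lfp)
        assert abs(env.mean()) < 1e-9
        assert abs(env.std() - 1.0) < 1e-9

    def test_in_band_burst_pops_out(self, rng):
        x = rng.standard_normal(1200 * 60) * 0.5
        t = np.arange(x.size) / 1200.0
        win = (t > 30.0) & (t < 30.06)
        x[win] += 3.0 * np.sin(2 * np.pi * 150 * t[win])
        env = ripple_envelope(Lfp(x, 1200.0))
        assert env[win].max() > 5.0

    def test_out_of_band_burst_ignored(self, rng):
        x = rng.standard_normal(1200 * 60) * 0.5
        t = np.arange(x.size) / 1200.0
        win = (t > 30.0) & (t < 30.2)
        x[win] += 3.0 * np.sin(2 * np.pi * 60 * t[win])
        env = ripple_envelope(Lfp(x, 1200.0))
        assert np.median(env[win]) < 0.5

    def test_too_short_session_rejected(self):
        with pytest.raises(ValueError):
            ripple_envelope(Lfp(np.zeros(30), 1200.0))


class TestDetectRipples:
    FS = 1200.0

    def _env(self, spans, peaks, n=12000):
        env = np.zeros(n)
        for (a, b), p in zip(spans, peaks):
            env[a:b] = p
        return env

    def test_flat_envelope_no_events(self):
        assert detect_ripples(np.zeros(12000), self.FS) == []
        assert detect_ripples(np.empty(0), self.FS) == []

    def test_nearby_bursts_merged_within_30ms(self):
        # two 25 ms bursts separated by a 20 ms gap -> one merged event
        gap = int(0.020 * self.FS)
        b = int(0.025 * self.FS)
        s = 6000
        env = self._env([(s, s + b), (s + b + gap, s + 2 * b + gap)], [6.0, 6.0])
        events = detect_ripples(env, self.FS)
        assert len(events) == 1
        assert events[0].duration_ms == pytest.approx(70.0, abs=2.0)

    def test_distant_bursts_stay_separate(self):
        gap = int(0.040 * self.FS)
        b = int(0.025 * self.FS)
        s = 6000
        env = self._env([(s, s + b), (s + b + gap, s + 2 * b + gap)], [6.0, 6.0])
        assert len(detect_ripples(env, self.FS)) == 2

    def test_subthreshold_peak_rejected(self):
        env = self._env([(6000, 6000 + int(0.05 * self.FS))], [4.0])
        assert detect_ripples(env, self.FS) == []

    def test_duration_limits_enforced(self):
        too_short = self._env([(6000, 6000 + int(0.010 * self.FS))], [8.0])
        too_long = self._env([(2000, 2000 + int(0.300 * self.FS))], [8.0])
        assert detect_ripples(too_short, self.FS) == []
        assert detect_ripples(too_long, self.FS) == []

    def test_idempotent_on_same_envelope(self, rng):
        env = np.abs(rng.standard_normal(24000)) * 2.5
        a = detect_ripples(env, self.FS)
        b = detect_ripples(env, self.FS)
        assert [(e.start, e.stop, e.peak_power) for e in a] == \
            [(e.start, e.stop, e.peak_power) for e in b]


class TestMorletSpectrogram:
    def test_tone_localized_at_its_frequency(self):
        spec = morlet_spectrogram(tone(150.0), np.arange(100.0, 201.0, 5.0))
        assert spec.freqs[np.argmax(spec.power.mean(axis=1))] == 150.0

    def test_power_scales_with_amplitude_squared(self):
        f = np.array([150.0])
        p1 = morlet_spectrogram(tone(150.0), f).power.mean()
        p2 = morlet_spectrogram(tone(150.0, amp=2.0), f).power.mean()
        assert p2 / p1 == pytest.approx(4.0, rel=1e-6)

    def test_total_power_invariant_to_tone_phase(self):
        fs, dur = 1200.0, 5.0
        t = np.arange(int(dur * fs)) / fs
        f = np.arange(100.0, 201.0, 10.0)
        powers = [morlet_spectrogram(
            Lfp(np.sin(2 * np.pi * 150 * t + ph), fs), f).power.sum()
            for ph in (0.0, 1.0, 2.5)]
        assert np.ptp(powers) / np.mean(powers) < 0.01

    def test_chirp_ridge_increases_monotonically(self):
        fs = 1200.0
        t = np.arange(int(8 * fs)) / fs
        from scipy.signal import chirp
        x = chirp(t, f0=100.0, f1=200.0, t1=8.0)
        spec = morlet_spectrogram(Lfp(x, fs), np.arange(90.0, 211.0, 4.0))
        mid = spec.power[:, 600:-600]
        ridge = spec.freqs[np.argmax(mid, axis=0)]
        coarse = ridge.reshape(-1, 400).mean(axis=1)
        assert np.all(np.diff(coarse) > 0)

    def test_frequency_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morlet_spectrogram(tone(100.0), np.array([700.0]))


class TestPeakFrequency:
    def _event_lfp(self, freq, rng, amp=6.0):
        x = rng.standard_normal(1200 * 20) * 0.5
        t = np.arange(x.size) / 1200.0
        c = 10.0
        win = np.abs(t - c) < 0.04
        taper = 0.5 * (1 + np.cos(2 * np.pi * (t[win] - c) / 0.08))
        x[win] += amp * taper * np.sin(2 * np.pi * freq * (t[win] - c))
        return Lfp(x, 1200.0), RippleEvent(c - 0.04, c + 0.04, c, 9.0)

    def test_injected_160hz_recovered_within_10hz(self, rng):
        lfp, ev = self._event_lfp(160.0, rng)
        f, _ = ripple_peak_frequency(lfp, ev)
        assert abs(f - 160.0) <= 10.0

    def test_100hz_event_eliminated(self, rng):
        lfp, ev = self._event_lfp(100.0, rng)
        assert assign_peak_frequencies(lfp, [ev]) == []

    def test_115hz_event_retained_boundary_inclusive(self, rng):
        lfp, ev = self._event_lfp(115.0, rng, amp=8.0)
        kept = assign_peak_frequencies(lfp, [ev],
                                       freqs=np.arange(95.0, 250.0, 1.0))
        assert len(kept) == 1
        assert kept[0].peak_frequency >= 115.0


class TestImmobilityAndRate:
    def test_constant_run_has_empty_mask(self):
        t = np.arange(0, 60, 0.02)
        track = PositionTrack(t, 10.0 * t % 90, np.full_like(t, 50.0))
        assert immobility_mask(track).size == 0

    def test_stationary_session_fully_masked(self, stationary_track):
        iv = immobility_mask(stationary_track)
        total = np.sum(iv[:, 1] - iv[:, 0])
        assert total == pytest.approx(stationary_track.duration, rel=1e-3)

    def test_mask_matches_simulated_bouts(self, foraging_track):
        iv = immobility_mask(foraging_track, vmax=5.0)
        sp = foraging_track.speed()
        inside = np.zeros(foraging_track.n_samples, bool)
        for a, b in iv:
            inside |= (foraging_track.t >= a) & (foraging_track.t < b)
        # mask agrees with the thresholded speed samples up to one frame
        assert np.mean(inside == (sp <= 5.0)) > 0.999

    def test_session_with_few_ripples_flagged_excluded(self):
        iv = np.array([[0.0, 100.0]])
        events = [RippleEvent(1.0 + i, 1.05 + i, 1.02 + i, 8.0)
                  for i in range(9)]
        res = swr_rate(events, iv)
        assert res.excluded and res.n_events == 9

    def test_rate_arithmetic(self):
        iv = np.array([[0.0, 100.0]])
        events = [RippleEvent(1.0 + 3 * i, 1.05 + 3 * i, 1.02 + 3 * i, 8.0)
                  for i in range(30)]
        res = swr_rate(events, iv)
        assert res.rate == pytest.approx(0.3)
        assert not res.excluded

    def test_zero_immobile_time_undefined(self):
        res = swr_rate([], np.empty((0, 2)))
        assert np.isnan(res.rate)

    def test_injected_rate_recovered(self, stationary_track):
        inj = schedule_ripples(stationary_track, 120, rng_for(2, "rate"),
                               amp=6.0)
        lfp, _ = simulate_lfp(LfpSpec(ripple_events=inj), stationary_track,
                              rng_for(2, "lfp"))
        events, _ = find_ripples(lfp, stationary_track)
        res = swr_rate(events, immobility_mask(stationary_track))
        lam = 120
        assert abs(res.n_events - lam) < 2 * np.sqrt(lam)


class TestBandPower:
    def test_identical_epochs_ratio_one(self, stationary_track):
        lfp, _ = simulate_lfp(LfpSpec(), stationary_track, rng_for(3, "bp"))
        assert band_power(lfp, BANDS["theta"], lfp).ratio == pytest.approx(1.0)

    def test_doubling_amplitude_quadruples_ratio(self, stationary_track):
        lfp, _ = simulate_lfp(LfpSpec(), stationary_track, rng_for(4, "bp"))
        doubled = Lfp(2.0 * lfp.samples, lfp.sample_rate)
        assert band_power(doubled, BANDS["theta"], lfp).ratio == \
            pytest.approx(4.0, rel=1e-9)

    def test_doubled_theta_component_roughly_quadruples(self, stationary_track):
        base, _ = simulate_lfp(LfpSpec(theta_amp=1.0), stationary_track,
                               rng_for(5, "bp"))
        strong, _ = simulate_lfp(LfpSpec(theta_amp=2.0), stationary_track,
                                 rng_for(5, "bp"))
        ratio = band_power(strong, BANDS["theta"], base).ratio
        assert 3.0 < ratio < 5.5

    def test_band_without_oscillation_sums_near_zero(self, stationary_track):
        from remapkit.synthetic import GammaBandSpec
        quiet, _ = simulate_lfp(LfpSpec(theta_amp=0.0, gamma_bands=()),
                                stationary_track, rng_for(6, "bp"))
        strong, _ = simulate_lfp(
            LfpSpec(theta_amp=0.0,
                    gamma_bands=(GammaBandSpec(25.0, 50.0, 2.0, 2.0),)),
            stationary_track, rng_for(6, "bp"))
        bp = band_power(quiet, BANDS["slow_gamma"], strong, freq_step=5.0)
        strong_bp = band_power(strong, BANDS["slow_gamma"], quiet, freq_step=5.0)
        assert bp.session_sum < 0.15 * strong_bp.session_sum

    def test_empty_baseline_rejected(self, stationary_track):
        lfp, _ = simulate_lfp(LfpSpec(), stationary_track, rng_for(7, "bp"))
        with pytest.raises(ValueError):
            band_power(lfp, BANDS["theta"], Lfp(np.empty(0), 1200.0))


class TestEventInvariants:
    def test_every_emitted_event_satisfies_rules(self, stationary_track):
        inj = schedule_ripples(stationary_track, 40, rng_for(8, "inv"), amp=6.0)
        lfp, _ = simulate_lfp(LfpSpec(ripple_events=inj), stationary_track,
                              rng_for(8, "lfp"))
        events, _ = find_ripples(lfp, stationary_track)
        assert events, "expected detections on high-SNR injections"
        for ev in events:
            assert 15.0 <= ev.duration_ms <= 200.0
            assert ev.peak_frequency >= 115.0
            assert ev.start < ev.peak_time < ev.stop

    def test_events_outside_mask_discarded(self):
        events = [RippleEvent(1.0, 1.05, 1.02, 8.0),
                  RippleEvent(50.0, 50.05, 50.02, 8.0)]
        kept = filter_events_to_mask(events, np.array([[0.0, 10.0]]))
        assert len(kept) == 1 and kept[0].peak_time == 1.02
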
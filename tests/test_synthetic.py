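"""Simulator tests: trajectories, spikes, remapping regimes and LFP."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.signal import welch

from remapkit._rng import rng_for
from remapkit.synthetic import (ArenaSpec, GammaBandSpec, LfpSpec,
                                PlaceCellSpec, RippleInjection,
                                TrajectoryParams, apply_remapping_regime,
                                generate_spikes, schedule_ripples,
                                simulate_lfp, simulate_place_cell_rates,
                                simulate_trajectory)
from remapkit.lfp import bandpass


class TestTrajectory:
    def test_short_session_has_expected_samples_inside_arena(self, arena):
        params = TrajectoryParams(duration=0.1, sample_rate=50.0)
        track = simulate_trajectory(arena, params, rng_for(0, "t"))
        assert track.n_samples == 5
        assert arena.contains(track.x, track.y).all()

    def test_zero_speed_keeps_animal_parked(self, arena):
        params = TrajectoryParams(duration=10.0, mean_speed=0.0, speed_sd=0.0)
        track = simulate_trajectory(arena, params, rng_for(0, "t"))
        assert np.ptp(track.x) == 0.0 and np.ptp(track.y) == 0.0
        assert track.speed(smooth_window=0).max() <= 1e-9

    def test_default_600s_covers_most_pixels(self, foraging_track):
        ix = np.floor(foraging_track.x / 5).astype(int)
        iy = np.floor(foraging_track.y / 5).astype(int)
        frac = len(set(zip(ix, iy))) / 400
        assert frac > 0.9

    @pytest.mark.parametrize("shape", ["square", "circle"])
    def test_containment_and_uniform_spacing(self, shape):
        arena = ArenaSpec(shape=shape)
        track = simulate_trajectory(arena, TrajectoryParams(duration=120.0),
                                    rng_for(1, shape))
        assert arena.contains(track.x, track.y).all()
        assert np.allclose(np.diff(track.t), 0.02)

    def test_immobility_bouts_present_with_low_speed(self, foraging_track):
        frac_immobile = (foraging_track.speed() <= 1.0).mean()
        assert frac_immobile > 0.02

    def test_moving_speed_tracks_requested_mean(self, foraging_track):
        sp = foraging_track.speed()
        moving = sp[sp > 5.0]
        assert 10.0 < moving.mean() < 20.0

    @pytest.mark.parametrize("bad", [
        dict(duration=0.0), dict(duration=-5.0), dict(sample_rate=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            TrajectoryParams(**bad)

    def test_fixed_seed_is_bit_reproducible(self, arena):
        params = TrajectoryParams(duration=30.0)
        a = simulate_trajectory(arena, params, rng_for(7, "t"))
        b = simulate_trajectory(arena, params, rng_for(7, "t"))
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)


class TestPlaceCellRates:
    def test_parked_at_field_center_fires_at_peak(self, stationary_track, arena):
        center = (float(stationary_track.x[0]), float(stationary_track.y[0]))
        spec = PlaceCellSpec(field_center=center, peak_rate=12.0)
        rate = simulate_place_cell_rates(stationary_track, spec, arena)
        assert np.allclose(rate, 12.0)

    def test_far_from_field_rate_is_baseline(self, stationary_track, arena):
        x0, y0 = stationary_track.x[0], stationary_track.y[0]
        # center >= 5 sigma away but still inside the arena
        cx = x0 + 60 if x0 < 40 else x0 - 60
        spec = PlaceCellSpec(field_center=(float(np.clip(cx, 1, 99)), float(y0)),
                             field_width_sigma=10.0, baseline_rate=0.5)
        rate = simulate_place_cell_rates(stationary_track, spec, arena)
        assert np.all(np.abs(rate - 0.5) / 0.5 < 0.01)

    def test_rate_never_exceeds_peak(self, foraging_track, arena):
        spec = PlaceCellSpec(field_center=(50.0, 50.0))
        rate = simulate_place_cell_rates(foraging_track, spec, arena)
        assert rate.max() <= spec.peak_rate + 1e-12

    def test_center_outside_arena_rejected(self, foraging_track, arena):
        spec = PlaceCellSpec(field_center=(150.0, 50.0))
        with pytest.raises(ValueError, match="outside"):
            simulate_place_cell_rates(foraging_track, spec, arena)


class TestSpikeGeneration:
    def test_zero_rate_gives_empty_train(self, rng):
        t = np.arange(0, 10, 0.02)
        st = generate_spikes(np.zeros_like(t), t, rng)
        assert st.n_spikes == 0

    def test_negative_rates_rejected(self, rng):
        t = np.arange(0, 1, 0.02)
        with pytest.raises(ValueError):
            generate_spikes(np.full_like(t, -1.0), t, rng)

    def test_homogeneous_count_matches_poisson_mean(self):
        # 200 replicates of constant 5 Hz over 600 s: mean count within 3 SE
        t = np.arange(0, 600, 0.02)
        rate = np.full_like(t, 5.0)
        counts = [generate_spikes(rate, t, rng_for(3, "mc", i)).n_spikes
                  for i in range(200)]
        se = np.sqrt(3000 / 200)
        assert abs(np.mean(counts) - 3000) < 3 * se

    def test_time_rescaling_of_inhomogeneous_train(self):
        # time-rescaling theorem: ISIs of the rescaled train are Exp(1)
        t = np.arange(0, 600, 0.005)
        rate = 5.0 + 4.0 * np.sin(2 * np.pi * t / 30.0)
        st = generate_spikes(rate, t, rng_for(11, "rescale"))
        cum = np.concatenate([[0], np.cumsum((rate[1:] + rate[:-1]) / 2 * np.diff(t))])
        rescaled = np.interp(st.times, t, cum)
        isis = np.diff(rescaled)
        assert sps.kstest(isis, "expon").pvalue > 0.01

    def test_spikes_stay_within_session(self, foraging_track, arena, rng):
        spec = PlaceCellSpec(field_center=(50.0, 50.0))
        rate = simulate_place_cell_rates(foraging_track, spec, arena)
        st = generate_spikes(rate, foraging_track.t, rng, burst_prob=0.3)
        assert st.times.min() >= foraging_track.t[0]
        assert st.times.max() <= foraging_track.t[-1]

    def test_burst_mode_creates_short_isis(self, rng):
        t = np.arange(0, 600, 0.02)
        st = generate_spikes(np.full_like(t, 3.0), t, rng,
                             burst_prob=0.5, burst_isi=0.005)
        assert np.mean(np.diff(st.times) < 0.006) > 0.1


class TestRemappingRegimes:
    def _specs(self, n, arena, seed=0):
        centers = arena.sample_uniform(rng_for(seed, "c"), n)
        return [PlaceCellSpec(field_center=tuple(c), rate_scale_in_N=0.5)
                for c in centers]

    def test_stable_preserves_specs_exactly(self, arena):
        specs = self._specs(10, arena)
        out = apply_remapping_regime(specs, "stable", arena, rng_for(0, "r"))
        assert [s.field_center for s in out] == [s.field_center for s in specs]
        assert [s.peak_rate for s in out] == [s.peak_rate for s in specs]

    def test_rate_remap_halves_peaks_keeps_centers(self, arena):
        specs = self._specs(10, arena)
        out = apply_remapping_regime(specs, "rate_remap", arena, rng_for(0, "r"))
        assert [s.field_center for s in out] == [s.field_center for s in specs]
        np.testing.assert_allclose([s.peak_rate for s in out],
                                   [0.5 * s.peak_rate for s in specs])

    def test_global_remap_centers_uncorrelated(self, arena):
        specs = self._specs(100, arena, seed=5)
        out = apply_remapping_regime(specs, "global_remap", arena, rng_for(1, "r"))
        old = np.array([s.field_center for s in specs])
        new = np.array([s.field_center for s in out])
        for dim in (0, 1):
            assert abs(sps.pearsonr(old[:, dim], new[:, dim])[0]) < 0.2

    def test_global_remap_centers_uniform_chi2(self, arena):
        # chi-square goodness of fit against uniform occupancy of a 10x10 grid
        specs = [PlaceCellSpec(field_center=(50.0, 50.0))] * 10_000
        out = apply_remapping_regime(specs, "global_remap", arena,
                                     rng_for(2, "gof"))
        centers = np.array([s.field_center for s in out])
        counts, _, _ = np.histogram2d(centers[:, 0], centers[:, 1],
                                      bins=[10, 10], range=[[0, 100], [0, 100]])
        p = sps.chisquare(counts.ravel()).pvalue
        assert p > 0.01

    def test_unknown_regime_rejected(self, arena):
        with pytest.raises(ValueError):
            apply_remapping_regime(self._specs(2, arena), "teleport", arena,
                                   rng_for(0, "r"))


class TestLfpSimulation:
    def test_noise_only_ground_truth_empty(self, stationary_track):
        spec = LfpSpec(theta_amp=0.0, gamma_bands=())
        lfp, truth = simulate_lfp(spec, stationary_track, rng_for(0, "l"))
        assert truth.ripples == []
        assert lfp.duration == pytest.approx(stationary_track.duration, rel=1e-3)

    def test_injected_ripples_visible_in_band_envelope(self, stationary_track):
        inj = schedule_ripples(stationary_track, 20, rng_for(1, "sched"),
                               freq_range=(150.0, 150.0),
                               duration_range_ms=(60.0, 60.0), amp=8.0)
        spec = LfpSpec(ripple_events=inj, theta_amp=0.5)
        lfp, _ = simulate_lfp(spec, stationary_track, rng_for(1, "l"))
        filt = bandpass(lfp.samples, 90, 250, lfp.sample_rate)
        power = filt ** 2
        z = (power - power.mean()) / power.std()
        n_hot = sum(z[int((e.time - 0.05) * lfp.sample_rate):
                      int((e.time + 0.05) * lfp.sample_rate)].max() > 5
                    for e in inj)
        assert n_hot >= 20

    def test_zero_theta_matches_pink_noise_spectrum(self, stationary_track):
        spec_off = LfpSpec(theta_amp=0.0, gamma_bands=())
        spec_ctrl = LfpSpec(theta_amp=0.0, gamma_bands=())
        off, _ = simulate_lfp(spec_off, stationary_track, rng_for(3, "a"))
        ctrl, _ = simulate_lfp(spec_ctrl, stationary_track, rng_for(4, "b"))
        f, p_off = welch(off.samples, off.sample_rate, nperseg=4096)
        _, p_ctrl = welch(ctrl.samples, ctrl.sample_rate, nperseg=4096)
        band = (f >= 4) & (f <= 12)
        ratio = p_off[band].sum() / p_ctrl[band].sum()
        assert 0.8 < ratio < 1.25

    def test_theta_raises_4_12_hz_power(self, stationary_track):
        on, _ = simulate_lfp(LfpSpec(theta_amp=1.0, gamma_bands=()),
                             stationary_track, rng_for(5, "a"))
        off, _ = simulate_lfp(LfpSpec(theta_amp=0.0, gamma_bands=()),
                              stationary_track, rng_for(5, "a"))
        f, p_on = welch(on.samples, on.sample_rate, nperseg=4096)
        _, p_off = welch(off.samples, off.sample_rate, nperseg=4096)
        band = (f >= 4) & (f <= 12)
        assert p_on[band].sum() > 2 * p_off[band].sum()

    def test_ripple_during_movement_rejected(self, foraging_track):
        sp = foraging_track.speed()
        moving_t = foraging_track.t[np.argmax(sp > 10.0)]
        spec = LfpSpec(ripple_events=[RippleInjection(float(moving_t), 150.0,
                                                      60.0, 5.0)],
                       immobility_only=True)
        with pytest.raises(ValueError, match="movement"):
            simulate_lfp(spec, foraging_track, rng_for(6, "l"))

    def test_fixed_seed_reproducible(self, stationary_track):
        spec = LfpSpec()
        a, _ = simulate_lfp(spec, stationary_track, rng_for(8, "l"))
        b, _ = simulate_lfp(spec, stationary_track, rng_for(8, "l"))
        assert np.array_equal(a.samples, b.samples)

    def test_gamma_bursts_raise_band_power(self, stationary_track):
        on, _ = simulate_lfp(LfpSpec(theta_amp=0.0, gamma_bands=(
            GammaBandSpec(25.0, 50.0, 2.0, 2.0),)),
            stationary_track, rng_for(9, "g"))
        off, _ = simulate_lfp(LfpSpec(theta_amp=0.0, gamma_bands=()),
                              stationary_track, rng_for(9, "g"))
        f, p_on = welch(on.samples, on.sample_rate, nperseg=4096)
        _, p_off = welch(off.samples, off.sample_rate, nperseg=4096)
        band = (f >= 25) & (f <= 50)
        assert p_on[band].sum() > 1.5 * p_off[band].sum()
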
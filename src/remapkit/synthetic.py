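"""Synthetic foraging sessions: trajectories, place cells, remapping and LFP.

This module generates the full desk-scale analogue of an open-field CA1
recording day: a foraging trajectory with immobility bouts in a square or
circular arena, place cells with Gaussian spatial tuning driving an
inhomogeneous Poisson spike generator, three cross-environment regimes
(stable / rate remapping / global remapping), and an LFP trace assembled
from pink noise, a theta sinusoid, gamma bursts and injected ripple events.
Every stochastic element is recorded in a ground-truth structure so that
downstream detectors and statistics can be tested by parameter recovery.

All draws flow from one seed through the named-substream scheme in
``remapkit._rng``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from ._rng import rng_for
from .session import Lfp, PositionTrack, SpikeTrain

__all__ = [
    "ArenaSpec",
    "TrajectoryParams",
    "PlaceCellSpec",
    "LfpSpec",
    "GammaBandSpec",
    "RippleInjection",
    "GroundTruth",
    "simulate_trajectory",
    "simulate_place_cell_rates",
    "generate_spikes",
    "apply_remapping_regime",
    "simulate_lfp",
    "schedule_ripples",
    "immobility_intervals_from_bouts",
    "simulate_remapping_experiment",
    "RemappingExperiment",
]

Regime = Literal["stable", "rate_remap", "global_remap"]
REGIMES: tuple[str, ...] = ("stable", "rate_remap", "global_remap")


@dataclass(frozen=True)
class ArenaSpec:
    """Landmark-free open-field arena.

    ``extent`` is the square side or circle diameter in cm; the arena
    occupies the room-frame box [0, extent] x [0, extent], a circular arena
    being inscribed in that box.
    """

    shape: Literal["square", "circle"] = "square"
    extent: float = 100.0

    def __post_init__(self) -> None:
        if self.shape not in ("square", "circle"):
            raise ValueError(f"unknown arena shape {self.shape!r}")
        if self.extent <= 0:
            raise ValueError("arena extent must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.extent / 2.0, self.extent / 2.0)

    @property
    def radius(self) -> float:
        return self.extent / 2.0

    def contains(self, x: np.ndarray, y: np.ndarray, margin: float = 0.0) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "square":
            return ((x >= margin) & (x <= self.extent - margin)
                    & (y >= margin) & (y <= self.extent - margin))
        cx, cy = self.center
        return np.hypot(x - cx, y - cy) <= self.radius - margin

    def sample_uniform(self, rng: np.random.Generator, n: int,
                       margin: float = 0.0) -> np.ndarray:
        """Draw ``n`` points uniformly inside the arena (rejection sampling)."""
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            cand = rng.uniform(margin, self.extent - margin, size=(2 * (n - filled) + 8, 2))
            ok = self.contains(cand[:, 0], cand[:, 1], margin=margin)
            cand = cand[ok]
            take = min(cand.shape[0], n - filled)
            out[filled:filled + take] = cand[:take]
            filled += take
        return out


@dataclass(frozen=True)
class TrajectoryParams:
    """Foraging-trajectory parameters.

    Defaults emulate a 10 min open-field crumb-chasing trial tracked at
    50 Hz: running speed fluctuating around 15 cm/s with occasional
    multi-second immobility bouts (about two per minute).
    """

    duration: float = 600.0
    sample_rate: float = 50.0
    mean_speed: float = 15.0
    speed_sd: float = 5.0
    immobility_bout_rate: float = 2.0   # bouts per minute
    immobility_bout_mean: float = 3.0   # mean bout length, s
    speed_tau: float = 1.0              # OU relaxation time of speed, s
    heading_diffusion: float = 1.2      # heading random-walk scale, rad/sqrt(s)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.mean_speed < 0 or self.speed_sd < 0:
            raise ValueError("speed parameters must be non-negative")
        if self.immobility_bout_rate < 0 or self.immobility_bout_mean < 0:
            raise ValueError("immobility parameters must be non-negative")


@dataclass
class PlaceCellSpec:
    """Gaussian-tuned place cell.

    Instantaneous rate is ``baseline + (peak - baseline) *
    exp(-d^2 / (2 sigma^2))`` with ``d`` the distance from the field center.
    ``rate_scale_in_N`` is the peak-rate multiplier applied when the cell
    rate-remaps in the novel environment.
    """

    field_center: tuple[float, float]
    field_width_sigma: float = 10.0
    peak_rate: float = 10.0
    baseline_rate: float = 0.1
    regime: str = "stable"
    rate_scale_in_N: float = 0.4

    def __post_init__(self) -> None:
        if self.field_width_sigma <= 0:
            raise ValueError("field_width_sigma must be positive")
        if not (self.peak_rate > self.baseline_rate >= 0):
            raise ValueError("need peak_rate > baseline_rate >= 0")
        if self.rate_scale_in_N <= 0:
            raise ValueError("rate_scale_in_N must be positive")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass(frozen=True)
class GammaBandSpec:
    """Poisson-timed Hann-windowed oscillatory bursts within a band."""

    low: float
    high: float
    amp: float
    burst_rate: float = 1.0      # bursts per second
    burst_duration: float = 0.1  # s


@dataclass(frozen=True)
class RippleInjection:
    """One injected ripple: Hann-tapered sinusoid centred at ``time``."""

    time: float          # centre time, s
    freq: float          # Hz
    duration_ms: float
    amp: float

    @property
    def start(self) -> float:
        return self.time - self.duration_ms / 2000.0

    @property
    def stop(self) -> float:
        return self.time + self.duration_ms / 2000.0


@dataclass
class LfpSpec:
    """Composition recipe for a synthetic LFP trace."""

    sample_rate: float = 1200.0
    pink_noise_sd: float = 1.0
    theta_freq: float = 8.0
    theta_amp: float = 1.0
    # real theta power waxes and wanes roughly log-normally; the sinusoid's
    # amplitude is modulated by a smoothed log-normal envelope (unit mean)
    theta_mod_sigma: float = 0.8
    theta_mod_tau: float = 2.0       # s, envelope correlation time
    gamma_bands: Sequence[GammaBandSpec] = field(default_factory=lambda: (
        GammaBandSpec(25.0, 50.0, 0.5, 1.0),
        GammaBandSpec(65.0, 140.0, 0.4, 1.5),
    ))
    ripple_events: Sequence[RippleInjection] = field(default_factory=tuple)
    immobility_only: bool = True
    immobility_speed: float = 5.0   # cm/s, gate for ripple placement
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that a detector should recover."""

    field_centers: dict[str, np.ndarray] = field(default_factory=dict)
    true_mean_rates: dict[str, np.ndarray] = field(default_factory=dict)
    ripples: list[RippleInjection] = field(default_factory=list)
    immobility_intervals: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Trajectory


def _draw_immobility(params: TrajectoryParams, n: int, dt: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Boolean immobility flag per sample from a Poisson bout process."""
    immobile = np.zeros(n, dtype=bool)
    rate_hz = params.immobility_bout_rate / 60.0
    if rate_hz <= 0 or params.immobility_bout_mean <= 0:
        return immobile
    t = 0.0
    duration = n * dt
    while True:
        t += rng.exponential(1.0 / rate_hz)
        if t >= duration:
            break
        bout = rng.exponential(params.immobility_bout_mean)
        i0 = int(t / dt)
        i1 = min(n, int((t + bout) / dt) + 1)
        immobile[i0:i1] = True
    return immobile


def simulate_trajectory(arena: ArenaSpec, params: TrajectoryParams,
                        rng: np.random.Generator | None = None) -> PositionTrack:
    """Simulate a foraging trajectory inside ``arena``.

    Speed follows an Ornstein-Uhlenbeck process around ``mean_speed``
    (clipped at zero), heading performs a wrapped random walk, and steps
    that would leave the arena are reflected off the wall. Immobility bouts
    freeze the animal in place. Returns a :class:`PositionTrack` whose
    samples are all strictly inside the arena at 1/sample_rate spacing.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    dt = 1.0 / params.sample_rate
    n = max(1, int(round(params.duration * params.sample_rate)))
    t = np.arange(n) * dt

    immobile = _draw_immobility(params, n, dt, rng)

    x = np.empty(n)
    y = np.empty(n)
    start = arena.sample_uniform(rng, 1, margin=min(5.0, arena.extent / 10))[0]
    x[0], y[0] = start
    theta = rng.uniform(0, 2 * np.pi)
    speed = max(0.0, rng.normal(params.mean_speed, params.speed_sd))

    tau = params.speed_tau
    s_noise = params.speed_sd * math.sqrt(2 * dt / tau) if tau > 0 else 0.0
    h_noise = params.heading_diffusion * math.sqrt(dt)
    normals = rng.standard_normal((n, 2))

    for i in range(1, n):
        speed += (params.mean_speed - speed) * (dt / tau) + s_noise * normals[i, 0]
        speed = max(0.0, speed)
        theta += h_noise * normals[i, 1]
        if immobile[i]:
            x[i], y[i] = x[i - 1], y[i - 1]
            continue
        px = x[i - 1] + speed * dt * math.cos(theta)
        py = y[i - 1] + speed * dt * math.sin(theta)
        px, py, theta = _reflect(arena, px, py, theta)
        x[i], y[i] = px, py

    return PositionTrack(t, x, y)


def _reflect(arena: ArenaSpec, px: float, py: float, theta: float):
    """Reflect a proposed position back into the arena, updating heading."""
    if arena.shape == "square":
        e = arena.extent
        for _ in range(4):
            moved = False
            if px < 0:
                px, theta, moved = -px, math.pi - theta, True
            elif px > e:
                px, theta, moved = 2 * e - px, math.pi - theta, True
            if py < 0:
                py, theta, moved = -py, -theta, True
            elif py > e:
                py, theta, moved = 2 * e - py, -theta, True
            if not moved:
                break
        px = min(max(px, 1e-9), e - 1e-9)
        py = min(max(py, 1e-9), e - 1e-9)
        return px, py, theta
    cx, cy = arena.center
    r = math.hypot(px - cx, py - cy)
    if r > arena.radius - 1e-9:
        # fold radially back inside and bounce the heading
        r_new = max(1e-6, 2 * (arena.radius - 1e-6) - r)
        r_new = min(r_new, arena.radius - 1e-6)
        ang = math.atan2(py - cy, px - cx)
        px = cx + r_new * math.cos(ang)
        py = cy + r_new * math.sin(ang)
        theta = 2 * (ang + math.pi / 2) - theta  # reflect about tangent
    return px, py, theta


def immobility_intervals_from_bouts(track: PositionTrack,
                                    speed_threshold: float = 5.0,
                                    smooth_window: float = 0.5) -> np.ndarray:
    """(start, stop) intervals (s) where tracked speed <= threshold."""
    sp = track.speed(smooth_window=smooth_window)
    mask = sp <= speed_threshold
    return _mask_to_intervals(mask, track.t, track.dt)


def _mask_to_intervals(mask: np.ndarray, t: np.ndarray, dt: float) -> np.ndarray:
    if mask.size == 0 or not mask.any():
        return np.empty((0, 2))
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    return np.column_stack([t[starts], t[stops - 1] + dt])


# ---------------------------------------------------------------------------
# Place cells and spikes


def simulate_place_cell_rates(track: PositionTrack, spec: PlaceCellSpec,
                              arena: ArenaSpec | None = None) -> np.ndarray:
    """Instantaneous firing rate (Hz) of a Gaussian place field along a track."""
    if track.n_samples == 0:
        raise ValueError("track is empty")
    cx, cy = spec.field_center
    if arena is not None and not bool(arena.contains(np.array([cx]), np.array([cy]))[0]):
        raise ValueError(f"field center {spec.field_center} lies outside the arena")
    d2 = (track.x - cx) ** 2 + (track.y - cy) ** 2
    return spec.baseline_rate + (spec.peak_rate - spec.baseline_rate) * np.exp(
        -d2 / (2.0 * spec.field_width_sigma ** 2))


def generate_spikes(rate: np.ndarray, t: np.ndarray,
                    rng: np.random.Generator,
                    unit_id: int = 0,
                    burst_prob: float = 0.0,
                    burst_isi: float = 0.005,
                    burst_geom_p: float = 0.5) -> SpikeTrain:
    """Draw spikes from an inhomogeneous Poisson process by thinning.

    ``rate`` is the instantaneous rate (Hz) sampled at times ``t``; values
    between samples are linearly interpolated. With ``burst_prob`` > 0 each
    Poisson spike seeds, with that probability, a geometric number of extra
    spikes at ``burst_isi`` spacing, emulating complex-spike bursts with a
    known ground truth for the burst-fraction statistic.
    """
    rate = np.asarray(rate, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rates must be non-negative")
    if rate.shape != t.shape:
        raise ValueError("rate and t must be aligned")
    lam_max = float(rate.max(initial=0.0))
    t0, t1 = (float(t[0]), float(t[-1])) if t.size else (0.0, 0.0)
    if lam_max <= 0 or t1 <= t0:
        return SpikeTrain(unit_id, np.empty(0))
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    accept = rng.uniform(0.0, lam_max, n_cand) < np.interp(cand, t, rate)
    times = cand[accept]
    if burst_prob > 0 and times.size:
        extras = []
        bursty = rng.random(times.size) < burst_prob
        n_extra = rng.geometric(burst_geom_p, times.size)
        for parent, b, k in zip(times, bursty, n_extra):
            if b:
                extras.append(parent + burst_isi * np.arange(1, k + 1))
        if extras:
            times = np.sort(np.concatenate([times, *extras]))
            times = times[(times >= t0) & (times <= t1)]
    return SpikeTrain(unit_id, times)


def apply_remapping_regime(specs: Sequence[PlaceCellSpec], regime: str,
                           arena: ArenaSpec,
                           rng: np.random.Generator) -> list[PlaceCellSpec]:
    """Derive novel-environment cell specs from familiar-environment specs.

    stable
        identical specs.
    rate_remap
        field centers preserved bit-exactly; each peak rate multiplied by
        that cell's ``rate_scale_in_N``.
    global_remap
        field centers redrawn uniformly at random inside ``arena``,
        independent of the familiar-environment centers.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    if regime == "stable":
        return [replace(s) for s in specs]
    if regime == "rate_remap":
        out = []
        for s in specs:
            peak = s.peak_rate * s.rate_scale_in_N
            base = min(s.baseline_rate, peak / 2.0)
            out.append(replace(s, peak_rate=peak, baseline_rate=base))
        return out
    centers = arena.sample_uniform(rng, len(specs))
    return [replace(s, field_center=(float(c[0]), float(c[1])))
            for s, c in zip(specs, centers)]


# ---------------------------------------------------------------------------
# LFP


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise with the requested standard deviation."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    spec[1:] /= np.sqrt(f[1:])
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _hann_burst(t: np.ndarray, center: float, duration: float, freq: float,
                amp: float, phase: float) -> np.ndarray:
    """Hann-tapered sinusoid: smooth onset/offset keeps detected durations
    close to the injected ones."""
    out = np.zeros_like(t)
    in_win = np.abs(t - center) <= duration / 2.0
    tt = t[in_win]
    taper = 0.5 * (1.0 + np.cos(2.0 * np.pi * (tt - center) / duration))
    out[in_win] = amp * taper * np.sin(2.0 * np.pi * freq * (tt - center) + phase)
    return out


def schedule_ripples(track: PositionTrack, n_events: int,
                     rng: np.random.Generator,
                     freq_range: tuple[float, float] = (130.0, 190.0),
                     duration_range_ms: tuple[float, float] = (30.0, 120.0),
                     amp: float = 6.0,
                     speed_threshold: float = 5.0,
                     min_gap: float = 0.25) -> list[RippleInjection]:
    """Place ``n_events`` ripples inside immobility intervals of ``track``.

    Event centres are drawn uniformly within immobility intervals wide
    enough to contain the event plus a margin, with at least ``min_gap``
    seconds between consecutive centres.
    """
    intervals = immobility_intervals_from_bouts(track, speed_threshold)
    max_dur = duration_range_ms[1] / 1000.0
    margin = max_dur / 2.0 + 0.05
    usable = [(a + margin, b - margin) for a, b in intervals if b - a > 2 * margin]
    if not usable:
        raise ValueError("no immobility interval long enough for ripple placement")
    weights = np.array([b - a for a, b in usable])
    events: list[RippleInjection] = []
    taken: list[float] = []
    attempts = 0
    while len(events) < n_events:
        attempts += 1
        if attempts > 200 * n_events:
            raise ValueError("could not place the requested number of ripples; "
                             "not enough immobility time")
        i = rng.choice(len(usable), p=weights / weights.sum())
        a, b = usable[i]
        c = rng.uniform(a, b)
        if any(abs(c - o) < min_gap for o in taken):
            continue
        taken.append(c)
        events.append(RippleInjection(
            time=float(c),
            freq=float(rng.uniform(*freq_range)),
            duration_ms=float(rng.uniform(*duration_range_ms)),
            amp=amp,
        ))
    events.sort(key=lambda e: e.time)
    return events


def simulate_lfp(spec: LfpSpec, track: PositionTrack,
                 rng: np.random.Generator | None = None) -> tuple[Lfp, GroundTruth]:
    """Compose an LFP trace over the span of ``track``.

    Output = pink noise + theta sinusoid + Poisson-timed gamma bursts +
    injected Hann-tapered ripple oscillations. With ``immobility_only`` set,
    every scheduled ripple must fall inside an immobility interval of the
    track (speed <= ``immobility_speed``); a ripple scheduled during
    movement raises ``ValueError``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    duration = track.duration
    n = int(round(duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate

    immobility = immobility_intervals_from_bouts(track, spec.immobility_speed)
    for ev in spec.ripple_events:
        if not (0.0 <= ev.start and ev.stop <= duration):
            raise ValueError(f"ripple at {ev.time:.3f}s falls outside the session")
        if spec.immobility_only:
            inside = any(a <= ev.start and ev.stop <= b for a, b in immobility)
            if not inside:
                raise ValueError(
                    f"ripple at {ev.time:.3f}s scheduled during movement "
                    "but immobility_only is set")

    x = _pink_noise(n, spec.pink_noise_sd, rng)
    if spec.theta_amp > 0:
        env = np.ones(n)
        if spec.theta_mod_sigma > 0:
            g = rng.standard_normal(n)
            size = max(1, int(spec.theta_mod_tau * spec.sample_rate))
            from scipy.ndimage import uniform_filter1d
            g = uniform_filter1d(g, size=size, mode="wrap") * np.sqrt(size)
            env = np.exp(spec.theta_mod_sigma * g - spec.theta_mod_sigma ** 2 / 2)
        x += spec.theta_amp * env * np.sin(2 * np.pi * spec.theta_freq * t
                                           + rng.uniform(0, 2 * np.pi))
    for band in spec.gamma_bands:
        if band.amp <= 0 or band.burst_rate <= 0:
            continue
        n_bursts = rng.poisson(band.burst_rate * duration)
        centers = rng.uniform(0, duration, n_bursts)
        freqs = rng.uniform(band.low, band.high, n_bursts)
        phases = rng.uniform(0, 2 * np.pi, n_bursts)
        for c, f, ph in zip(centers, freqs, phases):
            x += _hann_burst(t, c, band.burst_duration, f, band.amp, ph)
    for ev in spec.ripple_events:
        ph = rng.uniform(0, 2 * np.pi)
        x += _hann_burst(t, ev.time, ev.duration_ms / 1000.0, ev.freq, ev.amp, ph)

    truth = GroundTruth(ripples=list(spec.ripple_events),
                        immobility_intervals=immobility)
    return Lfp(x, spec.sample_rate), truth


# ---------------------------------------------------------------------------
# Whole-experiment convenience


@dataclass
class RemappingExperiment:
    """Simulated F / N / F' day for one cell population."""

    arena: dict[str, ArenaSpec]
    tracks: dict[str, PositionTrack]
    specs: dict[str, list[PlaceCellSpec]]
    spikes: dict[str, list[SpikeTrain]]
    truth: GroundTruth
    regime: str


def _draw_population(n_cells: int, arena: ArenaSpec, rng: np.random.Generator,
                     sigma: float = 10.0,
                     peak_range: tuple[float, float] = (4.0, 16.0),
                     baseline_rate: float = 0.1,
                     rate_scale: float = 0.4) -> list[PlaceCellSpec]:
    centers = arena.sample_uniform(rng, n_cells)
    peaks = rng.uniform(*peak_range, n_cells)
    return [PlaceCellSpec(field_center=(float(c[0]), float(c[1])),
                          field_width_sigma=sigma, peak_rate=float(p),
                          baseline_rate=baseline_rate,
                          rate_scale_in_N=rate_scale)
            for c, p in zip(centers, peaks)]


def simulate_remapping_experiment(
        n_cells: int = 50,
        regime: str = "stable",
        seed: int = 0,
        arena: ArenaSpec | None = None,
        novel_arena: ArenaSpec | None = None,
        traj_params: TrajectoryParams | None = None,
        rate_scale: float = 0.4,
        field_sigma: float = 10.0,
        peak_range: tuple[float, float] = (4.0, 16.0)) -> RemappingExperiment:
    """Simulate the familiar -> novel -> familiar (F, N, F') session triplet.

    One cell population is drawn for the familiar arena; the novel-arena
    specs are derived from it under ``regime``; F' reuses the familiar
    specs (stable place fields across the two familiar sessions). Each
    session gets an independent trajectory. Ground truth records field
    centers and the empirical mean of each cell's instantaneous rate.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    arena = arena or ArenaSpec()
    novel_arena = novel_arena or arena
    traj_params = traj_params or TrajectoryParams()

    specs_f = _draw_population(n_cells, arena, rng_for(seed, "population"),
                               sigma=field_sigma, peak_range=peak_range,
                               rate_scale=rate_scale)
    specs_n = apply_remapping_regime(specs_f, regime, novel_arena,
                                     rng_for(seed, "remap"))
    session_specs = {"F": specs_f, "N": specs_n, "F2": specs_f}
    session_arena = {"F": arena, "N": novel_arena, "F2": arena}

    tracks: dict[str, PositionTrack] = {}
    spikes: dict[str, list[SpikeTrain]] = {}
    truth = GroundTruth()
    for name in ("F", "N", "F2"):
        track = simulate_trajectory(session_arena[name], traj_params,
                                    rng_for(seed, "trajectory", name))
        tracks[name] = track
        rates = np.column_stack([
            simulate_place_cell_rates(track, s) for s in session_specs[name]])
        rng_spk = rng_for(seed, "spikes", name)
        spikes[name] = [generate_spikes(rates[:, j], track.t, rng_spk, unit_id=j)
                        for j in range(n_cells)]
        truth.field_centers[name] = np.array(
            [s.field_center for s in session_specs[name]])
        truth.true_mean_rates[name] = rates.mean(axis=0)

    return RemappingExperiment(arena=session_arena, tracks=tracks,
                               specs=session_specs, spikes=spikes,
                               truth=truth, regime=regime)
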
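"""End-to-end experiment runner: simulate -> ratemaps -> remap -> lfp -> report.

A run is driven by one :class:`RunConfig` (all analysis constants appear as
named fields so deviations from the defaults are visible diffs) and one
integer seed. The runner writes a manifest with the config hash and SHA-256
digests of every output file; re-running with the same config and seed
reproduces every byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lfp as lfpmod
from . import ratemaps as rm
from . import remapping as remap
from . import stats as st
from ._rng import rng_for
from .session import Session, SpikeTrain, read_session, write_session
from .synthetic import (ArenaSpec, LfpSpec, TrajectoryParams,
                        apply_remapping_regime, _draw_population,
                        generate_spikes, schedule_ripples,
                        simulate_lfp, simulate_place_cell_rates,
                        simulate_trajectory)

__all__ = ["RunConfig", "run_experiment", "load_config"]

logger = logging.getLogger(__name__)

ARENA_SESSIONS = ("F", "N", "F2")
SESSION_SEQUENCE = ("pot1", "F", "N", "F2", "pot2")


@dataclass
class RunConfig:
    """Every tunable of a full synthetic run, defaults matching the
    familiar/novel open-field design and the standard analysis constants."""

    seed: int = 0
    out_dir: str = "remapkit_run"

    # session sequence
    session_duration: float = 600.0    # arena sessions (10 min)
    pot_duration: float = 300.0        # pot rest sessions (5 min)

    # arenas
    arena_shape: str = "square"
    arena_extent: float = 100.0
    novel_shape: str = "circle"
    novel_extent: float = 100.0

    # trajectory
    tracker_rate: float = 50.0
    mean_speed: float = 15.0
    speed_sd: float = 5.0
    immobility_bout_rate: float = 2.0
    immobility_bout_mean: float = 3.0

    # place-cell population
    n_cells: int = 30
    regime: str = "rate_remap"
    field_sigma: float = 10.0
    peak_rate_min: float = 4.0
    peak_rate_max: float = 16.0
    baseline_rate: float = 0.1
    rate_scale_in_N: float = 0.4
    burst_prob: float = 0.2
    burst_isi: float = 0.005

    # synthetic LFP
    lfp_sample_rate: float = 1200.0
    pink_noise_sd: float = 1.0
    theta_freq: float = 8.0
    theta_amp: float = 1.0
    ripple_rate: float = 0.3           # injected events per immobile second
    ripple_amp: float = 6.0

    # rate-map analysis
    bin_size: float = 5.0              # cm
    smoothing_window: float = 30.0     # cm, Blackman width
    sdf_kernel: float = 2.0            # s, Blackman width
    active_rate_threshold: float = 0.25   # Hz inclusion rule
    field_threshold_frac: float = 0.2
    field_connectivity: int = 8
    burst_isi_analysis: float = 0.010
    min_common_pixels: int = 20

    # ripple analysis
    ripple_band_low: float = 90.0
    ripple_band_high: float = 250.0
    detect_sd: float = 3.0
    peak_sd: float = 5.0
    merge_ms: float = 30.0
    min_duration_ms: float = 15.0
    max_duration_ms: float = 200.0
    min_peak_freq: float = 115.0
    immobility_speed: float = 5.0      # cm/s
    min_ripples_per_session: int = 10

    # statistics
    alpha: float = 0.05
    posthoc: str = "bonferroni"

    def __post_init__(self) -> None:
        if self.session_duration <= 0 or self.pot_duration <= 0:
            raise ValueError("session durations must be positive")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if self.regime not in ("stable", "rate_remap", "global_remap"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config file (all keys optional) and apply overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(data)


# ---------------------------------------------------------------------------
# Stages


def _traj_params(cfg: RunConfig, duration: float, stationary: bool) -> TrajectoryParams:
    if stationary:
        return TrajectoryParams(duration=duration, sample_rate=cfg.tracker_rate,
                                mean_speed=0.0, speed_sd=0.0,
                                immobility_bout_rate=0.0)
    return TrajectoryParams(duration=duration, sample_rate=cfg.tracker_rate,
                            mean_speed=cfg.mean_speed, speed_sd=cfg.speed_sd,
                            immobility_bout_rate=cfg.immobility_bout_rate,
                            immobility_bout_mean=cfg.immobility_bout_mean)


def stage_simulate(cfg: RunConfig, run_dir: Path) -> dict[str, Session]:
    """Generate and write the pot1, F, N, F2, pot2 session bundles."""
    arena = ArenaSpec(cfg.arena_shape, cfg.arena_extent)
    novel = ArenaSpec(cfg.novel_shape, cfg.novel_extent)
    seed = cfg.seed

    specs_f = _draw_population(cfg.n_cells, arena, rng_for(seed, "population"),
                               sigma=cfg.field_sigma,
                               peak_range=(cfg.peak_rate_min, cfg.peak_rate_max),
                               baseline_rate=cfg.baseline_rate,
                               rate_scale=cfg.rate_scale_in_N)
    specs_n = apply_remapping_regime(specs_f, cfg.regime, novel,
                                     rng_for(seed, "remap"))
    cell_specs = {"F": specs_f, "N": specs_n, "F2": specs_f}
    arenas = {"pot1": arena, "F": arena, "N": novel, "F2": arena, "pot2": arena}

    sessions: dict[str, Session] = {}
    for name in SESSION_SEQUENCE:
        stationary = name.startswith("pot")
        duration = cfg.pot_duration if stationary else cfg.session_duration
        track = simulate_trajectory(arenas[name],
                                    _traj_params(cfg, duration, stationary),
                                    rng_for(seed, "trajectory", name))
        spikes: list[SpikeTrain] = []
        centers = []
        if not stationary:
            rng_spk = rng_for(seed, "spikes", name)
            for j, spec in enumerate(cell_specs[name]):
                rate = simulate_place_cell_rates(track, spec)
                spikes.append(generate_spikes(rate, track.t, rng_spk, unit_id=j,
                                              burst_prob=cfg.burst_prob,
                                              burst_isi=cfg.burst_isi))
                centers.append(list(spec.field_center))

        rng_lfp = rng_for(seed, "lfp", name)
        immobile = lfpmod.immobility_mask(track, cfg.immobility_speed)
        immobile_time = float(np.sum(immobile[:, 1] - immobile[:, 0])) if immobile.size else 0.0
        n_events = int(round(cfg.ripple_rate * immobile_time))
        ripples = []
        if n_events > 0:
            ripples = schedule_ripples(track, n_events, rng_lfp,
                                       amp=cfg.ripple_amp,
                                       speed_threshold=cfg.immobility_speed)
        spec = LfpSpec(sample_rate=cfg.lfp_sample_rate,
                       pink_noise_sd=cfg.pink_noise_sd,
                       theta_freq=cfg.theta_freq,
                       theta_amp=cfg.theta_amp * (0.3 if stationary else 1.0),
                       ripple_events=ripples,
                       immobility_speed=cfg.immobility_speed)
        lfp, truth = simulate_lfp(spec, track, rng_lfp)

        meta = {
            "arena_shape": arenas[name].shape,
            "arena_extent": arenas[name].extent,
            "field_centers": centers,
            "injected_ripples": [[r.time, r.freq, r.duration_ms, r.amp]
                                 for r in ripples],
            "immobile_time": immobile_time,
        }
        sess = Session(name=name, track=track, spikes=spikes, lfp=lfp, meta=meta)
        write_session(sess, run_dir / "sessions" / name)
        sessions[name] = sess
    return sessions


def stage_ratemaps(cfg: RunConfig, run_dir: Path,
                   sessions: dict[str, Session] | None = None):
    """Rate maps and per-cell field statistics for the arena sessions."""
    sessions = sessions or _load_sessions(run_dir)
    out = run_dir / "ratemaps"
    out.mkdir(parents=True, exist_ok=True)
    maps: dict[str, list[rm.RateMap]] = {}
    rows = []
    for name in ARENA_SESSIONS:
        sess = sessions[name]
        sdf = np.column_stack([
            rm.spike_density_function(stn, sess.track.t, cfg.sdf_kernel)
            for stn in sess.spikes]) if sess.spikes else np.zeros((sess.track.n_samples, 0))
        maps[name] = rm.compute_rate_maps(sdf, sess.track, cfg.bin_size,
                                          cfg.smoothing_window, cfg.arena_extent)
        for stn, mp in zip(sess.spikes, maps[name]):
            fs = rm.compute_field_stats(stn, sess.track, mp, session=name,
                                        burst_isi=cfg.burst_isi_analysis)
            rows.append(dataclasses.asdict(fs))
        stack = np.stack([m.rate for m in maps[name]]) if maps[name] else np.zeros((0,))
        np.save(out / f"{name}_rates.npy", stack)
        if maps[name]:
            np.save(out / f"{name}_visited.npy", maps[name][0].visited)
            np.save(out / f"{name}_occupancy.npy", maps[name][0].occupancy)
    df = pd.DataFrame(rows)
    df.to_csv(out / "field_stats.csv", index=False)
    return maps, df


def stage_remap(cfg: RunConfig, run_dir: Path, maps, stats_df: pd.DataFrame):
    """Per-cell remapping metrics for F-F' and F-N and the regime contrast."""
    out = run_dir / "remap"
    out.mkdir(parents=True, exist_ok=True)
    avg = stats_df.pivot(index="unit_id", columns="session",
                         values="average_rate").sort_index()
    # inclusion rule: >= 0.25 Hz in at least one session
    active = avg.max(axis=1) >= cfg.active_rate_threshold
    idx = avg.index[active].to_numpy()
    logger.info("%d of %d cells pass the %.2f Hz inclusion rule",
                active.sum(), len(avg), cfg.active_rate_threshold)

    def metrics(a: str, b: str, label: str) -> remap.PairMetrics:
        return remap.pair_metrics(
            [maps[a][i] for i in idx], [maps[b][i] for i in idx],
            avg.loc[idx, a].to_numpy(), avg.loc[idx, b].to_numpy(),
            label=label, min_common_pixels=cfg.min_common_pixels)

    ff = metrics("F", "F2", "F-F2")
    fn = metrics("F", "N", "F-N")
    contrast = remap.remapping_contrast(ff, fn, alpha=cfg.alpha)

    percell = pd.DataFrame({
        "unit_id": idx,
        "spatial_r_FF2": ff.spatial_r, "spatial_r_FN": fn.spatial_r,
        "overlap_FF2": ff.overlap, "overlap_FN": fn.overlap,
        "rate_change_FF2": ff.rate_change, "rate_change_FN": fn.rate_change,
    })
    percell.to_csv(out / "percell_metrics.csv", index=False)
    summary = {
        "n_cells_included": int(active.sum()),
        "mean_spatial_r_FF2": ff.mean_spatial_r,
        "mean_spatial_r_FN": fn.mean_spatial_r,
        "mean_overlap_FF2": ff.mean_overlap,
        "mean_overlap_FN": fn.mean_overlap,
        "mean_rate_change_FF2": ff.mean_rate_change,
        "mean_rate_change_FN": fn.mean_rate_change,
        "overlap_test": dataclasses.asdict(contrast.overlap_test),
        "rate_change_test": dataclasses.asdict(contrast.rate_change_test),
        "spatial_r_test": dataclasses.asdict(contrast.spatial_r_test),
        "classification": contrast.label,
    }
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    return contrast, percell


def stage_lfp(cfg: RunConfig, run_dir: Path,
              sessions: dict[str, Session] | None = None):
    """Ripple detection, SWR rates and band-power summaries per session."""
    sessions = sessions or _load_sessions(run_dir)
    out = run_dir / "lfp"
    out.mkdir(parents=True, exist_ok=True)
    swr_rows, bp_rows = [], []
    baseline = sessions["pot1"].lfp
    for name in SESSION_SEQUENCE:
        sess = sessions[name]
        events, _work = lfpmod.find_ripples(
            sess.lfp, sess.track, target_rate=cfg.lfp_sample_rate,
            detect_sd=cfg.detect_sd, peak_sd=cfg.peak_sd,
            min_peak_freq=cfg.min_peak_freq)
        ev_df = pd.DataFrame([{
            "start": e.start, "stop": e.stop, "peak": e.peak_time,
            "duration_ms": e.duration_ms, "peak_freq_hz": e.peak_frequency,
            "peak_power": e.peak_power} for e in events])
        ev_df.to_csv(out / f"ripples_{name}.csv", index=False)
        res = lfpmod.swr_rate(events, lfpmod.immobility_mask(
            sess.track, cfg.immobility_speed),
            min_events=cfg.min_ripples_per_session)
        swr_rows.append({"session": name, "swr_rate_hz": res.rate,
                         "n_events": res.n_events,
                         "immobile_s": res.immobile_time,
                         "excluded": res.excluded})
        if name != "pot1":
            for band_name, (lo, hi) in lfpmod.BANDS.items():
                step = 1.0 if hi - lo < 20 else 5.0
                bp = lfpmod.band_power(sess.lfp, (lo, hi), baseline,
                                       freq_step=step, label=band_name)
                bp_rows.append({"session": name, "band": band_name,
                                "low_hz": lo, "high_hz": hi,
                                "power_over_baseline": bp.ratio})
    pd.DataFrame(swr_rows).to_csv(out / "swr_rates.csv", index=False)
    pd.DataFrame(bp_rows).to_csv(out / "band_power.csv", index=False)


def stage_report(cfg: RunConfig, run_dir: Path, stats_df: pd.DataFrame):
    """Per-metric session comparisons (F vs N vs F') and the summary table."""
    out = run_dir / "report"
    out.mkdir(parents=True, exist_ok=True)
    metrics = ["average_rate", "peak_rate", "field_size_dm2", "information",
               "sparseness", "burst_fraction"]
    comparisons: dict[tuple[str, str], st.ComparisonResult | None] = {}
    for metric in metrics:
        groups = {}
        for name in ARENA_SESSIONS:
            vals = stats_df.loc[stats_df.session == name, metric].to_numpy()
            vals = vals[np.isfinite(vals)]
            if vals.size >= 3:
                groups[name] = vals
        comparisons[(metric, "all")] = (
            st.compare_groups(groups, alpha=cfg.alpha, posthoc=cfg.posthoc)
            if len(groups) >= 2 else None)
    report = st.build_report(comparisons)
    report.to_csv(out / "report.csv", index=False)
    (out / "report.txt").write_text(report.to_string(index=False) + "\n")
    return report


def _load_sessions(run_dir: Path) -> dict[str, Session]:
    return {name: read_session(run_dir / "sessions" / name)
            for name in SESSION_SEQUENCE}


# ---------------------------------------------------------------------------
# Runner


def _write_manifest(run_dir: Path, payload: dict) -> None:
    (run_dir / "manifest.json").write_text(
        json.dumps(payload, sort_keys=True, indent=1))


def _hash_outputs(run_dir: Path) -> dict[str, str]:
    digests = {}
    for f in sorted(run_dir.rglob("*")):
        if f.is_file() and f.name not in ("manifest.json", "run.log"):
            digests[str(f.relative_to(run_dir))] = hashlib.sha256(
                f.read_bytes()).hexdigest()
    return digests


def run_experiment(cfg: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Run all stages in order; returns the run directory.

    The manifest is written with ``status: running`` before any computation
    and finalised to ``complete`` (with per-file SHA-256 digests) only when
    every stage has succeeded, so an interrupted run is detectable. A stage
    failure sets ``status: failed`` and re-raises.
    """
    run_dir = Path(out_dir or cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"status": "running", "stage": None, "seed": cfg.seed,
                "config": cfg.to_dict(), "config_hash": cfg.hash()}
    _write_manifest(run_dir, manifest)
    stage = "simulate"
    try:
        sessions = stage_simulate(cfg, run_dir)
        stage = "ratemaps"
        maps, stats_df = stage_ratemaps(cfg, run_dir, sessions)
        stage = "remap"
        stage_remap(cfg, run_dir, maps, stats_df)
        stage = "lfp"
        stage_lfp(cfg, run_dir, sessions)
        stage = "report"
        stage_report(cfg, run_dir, stats_df)
    except Exception:
        manifest.update(status="failed", stage=stage)
        _write_manifest(run_dir, manifest)
        raise
    manifest.update(status="complete", stage="done",
                    outputs=_hash_outputs(run_dir))
    _write_manifest(run_dir, manifest)
    return run_dir
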
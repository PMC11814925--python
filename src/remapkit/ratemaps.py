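"""Spike-density functions, occupancy rate maps and place-field statistics.

The firing-rate estimate follows the smoothed-SDF convention: the spike
train (a sum of Dirac deltas) is convolved with a 2 s Blackman kernel
normalised to unit gain at zero frequency and sampled synchronously with
the position tracker; each 5 x 5 cm pixel's rate is then the weighted mean
of the SDF samples, with weights given by a 30-cm-wide Blackman window of
the Euclidean distance between sample position and pixel centre. Per-cell
statistics (peak rate, field size, Skaggs information, sparseness, burst
fraction) are computed from the resulting map and the raw spike train.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .session import PositionTrack, SpikeTrain

__all__ = [
    "RateMap",
    "FieldStats",
    "spike_density_function",
    "compute_rate_map",
    "compute_rate_maps",
    "average_rate",
    "is_active_place_cell",
    "peak_rate",
    "field_size",
    "spatial_information",
    "sparseness",
    "burst_fraction",
    "compute_field_stats",
    "ACTIVE_RATE_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Minimum average firing rate (Hz), in at least one session, for a unit to
#: count as an active place cell.
ACTIVE_RATE_THRESHOLD = 0.25


@dataclass
class RateMap:
    """Occupancy-normalised 2-D firing-rate map on a fixed pixel grid.

    ``rate`` is NaN on unvisited pixels; ``occupancy`` holds the occupancy
    probabilities p_i (summing to one over visited pixels). Grid rows index
    y, columns index x; bin edges are half-open ``[k*bin, (k+1)*bin)`` with
    the origin at the arena corner.
    """

    rate: np.ndarray
    occupancy: np.ndarray
    visited: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    def __post_init__(self) -> None:
        if self.visited.any():
            tot = self.occupancy[self.visited].sum()
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"occupancy must sum to 1 over visited pixels "
                                 f"(got {tot!r})")
        vr = self.rate[self.visited]
        if vr.size and (np.any(~np.isfinite(vr)) or np.any(vr < -1e-12)):
            raise ValueError("visited-pixel rates must be finite and non-negative")

    @property
    def bin_size(self) -> float:
        return float(self.x_edges[1] - self.x_edges[0])

    @property
    def n_visited(self) -> int:
        return int(self.visited.sum())


@dataclass
class FieldStats:
    """Per-cell, per-session place-field summary."""

    unit_id: int
    session: str
    average_rate: float
    peak_rate: float
    field_size_dm2: float
    information: float
    sparseness: float
    burst_fraction: float


def spike_density_function(spikes: SpikeTrain | np.ndarray,
                           sample_times: np.ndarray,
                           kernel_width: float = 2.0) -> np.ndarray:
    """Smoothed instantaneous firing rate (Hz) on the tracker time grid.

    The spike train is binned onto the tracker frames and convolved with a
    Blackman window of length ``kernel_width`` seconds scaled to unit gain
    at zero frequency, so the SDF integrates to the spike count and a
    constant-rate train maps to its rate.
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    sample_times = np.asarray(sample_times, dtype=float)
    if sample_times.size < 2:
        raise ValueError("sample_times must cover the session")
    dt = float(np.median(np.diff(sample_times)))
    if not np.allclose(np.diff(sample_times), dt, rtol=0, atol=dt * 1e-3):
        raise ValueError("sample_times must be uniformly spaced")
    n_kernel = int(round(kernel_width / dt))
    if n_kernel > sample_times.size:
        raise ValueError("smoothing kernel is longer than the session")
    if times.size == 0:
        return np.zeros(sample_times.size)
    edges = np.concatenate([sample_times - dt / 2, [sample_times[-1] + dt / 2]])
    counts, _ = np.histogram(times, bins=edges)
    kernel = np.blackman(n_kernel)
    kernel /= kernel.sum()          # unit gain at DC
    return fftconvolve(counts.astype(float), kernel, mode="same") / dt


def _blackman_distance_weights(dist: np.ndarray, window_width: float) -> np.ndarray:
    """Blackman window evaluated at Euclidean distance; zero beyond width/2."""
    half = window_width / 2.0
    w = np.zeros_like(dist)
    inside = dist <= half
    u = dist[inside] / half
    w[inside] = 0.42 + 0.5 * np.cos(np.pi * u) + 0.08 * np.cos(2 * np.pi * u)
    return w


def compute_rate_maps(sdf_matrix: np.ndarray, track: PositionTrack,
                      bin_size: float = 5.0, window_width: float = 30.0,
                      extent: float = 100.0) -> list[RateMap]:
    """Rate maps for many cells sharing one track (vectorised).

    ``sdf_matrix`` has shape (n_samples, n_cells); the distance-weight
    matrix depends only on the track, so it is built once and applied to
    every cell's SDF. Weights are renormalised over the samples actually
    present near arena edges (no zero padding).
    """
    sdf_matrix = np.atleast_2d(np.asarray(sdf_matrix, dtype=float))
    if sdf_matrix.shape[0] != track.n_samples:
        if sdf_matrix.shape[1] == track.n_samples:   # (n_cells, n_samples)
            sdf_matrix = sdf_matrix.T
        else:
            raise ValueError("SDF and track are not sample-aligned")
    n_bins = int(np.ceil(extent / bin_size - 1e-9))
    edges = np.arange(n_bins + 1) * bin_size

    ix = np.clip(np.floor(track.x / bin_size).astype(int), 0, n_bins - 1)
    iy = np.clip(np.floor(track.y / bin_size).astype(int), 0, n_bins - 1)
    counts = np.zeros((n_bins, n_bins))
    np.add.at(counts, (iy, ix), 1.0)
    visited = counts > 0
    occupancy = counts / counts.sum()

    centers = (edges[:-1] + edges[1:]) / 2.0
    cx, cy = np.meshgrid(centers, centers)          # (ny, nx)
    px = cx.ravel()[:, None]
    py = cy.ravel()[:, None]
    num = np.empty((n_bins * n_bins, sdf_matrix.shape[1]))
    den = np.empty(n_bins * n_bins)
    chunk = max(1, int(4e6 // max(track.n_samples, 1)))
    for s in range(0, n_bins * n_bins, chunk):
        e = min(s + chunk, n_bins * n_bins)
        d = np.hypot(px[s:e] - track.x[None, :], py[s:e] - track.y[None, :])
        w = _blackman_distance_weights(d, window_width)
        den[s:e] = w.sum(axis=1)
        num[s:e] = w @ sdf_matrix
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = num / den[:, None]
    rates = rates.reshape(n_bins, n_bins, -1)

    maps = []
    for j in range(sdf_matrix.shape[1]):
        r = np.where(visited, rates[:, :, j], np.nan)
        r = np.where(visited, np.clip(r, 0.0, None), np.nan)
        maps.append(RateMap(rate=r, occupancy=np.where(visited, occupancy, 0.0),
                            visited=visited.copy(), x_edges=edges.copy(),
                            y_edges=edges.copy()))
    return maps


def compute_rate_map(sdf: np.ndarray, track: PositionTrack,
                     bin_size: float = 5.0, window_width: float = 30.0,
                     extent: float = 100.0) -> RateMap:
    """Rate map for a single cell (see :func:`compute_rate_maps`)."""
    sdf = np.asarray(sdf, dtype=float)
    if sdf.ndim != 1 or sdf.size != track.n_samples:
        raise ValueError("SDF and track are not sample-aligned")
    return compute_rate_maps(sdf[:, None], track, bin_size=bin_size,
                             window_width=window_width, extent=extent)[0]


def average_rate(spikes: SpikeTrain | np.ndarray, session_duration: float) -> float:
    """Session-average firing rate: spike count / duration (Hz)."""
    if session_duration <= 0:
        raise ValueError("session_duration must be positive")
    n = spikes.n_spikes if isinstance(spikes, SpikeTrain) else np.asarray(spikes).size
    return n / session_duration


def is_active_place_cell(session_rates) -> bool:
    """Inclusion rule: average rate of at least 0.25 Hz in >= 1 session."""
    rates = np.asarray(list(session_rates), dtype=float)
    if rates.size == 0:
        raise ValueError("need at least one session")
    return bool(np.max(rates) >= ACTIVE_RATE_THRESHOLD)


def peak_rate(rate_map: RateMap) -> float:
    """Maximum rate over visited pixels of the smoothed map."""
    if not rate_map.visited.any():
        raise ValueError("rate map has no visited pixels")
    return float(np.nanmax(rate_map.rate))


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


def field_size(rate_map: RateMap, threshold_frac: float = 0.2,
               connectivity: int = 8) -> float:
    """Place-field size in square decimetres.

    The field is the largest connected cluster of visited pixels whose rate
    exceeds ``threshold_frac`` of the peak rate; each 5 x 5 cm pixel
    contributes 0.25 dm^2. Returns NaN for an all-zero map.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    pk = peak_rate(rate_map)
    if pk <= 0:
        logger.warning("field_size undefined for an all-zero rate map")
        return float("nan")
    above = rate_map.visited & (np.nan_to_num(rate_map.rate) > threshold_frac * pk)
    labels, n_lab = ndimage.label(above, structure=_STRUCTURES[connectivity])
    if n_lab == 0:
        return 0.0
    largest = np.bincount(labels.ravel())[1:].max()
    pixel_area_dm2 = (rate_map.bin_size / 10.0) ** 2
    return float(largest * pixel_area_dm2)


def _visited_p_lambda(rate_map: RateMap) -> tuple[np.ndarray, np.ndarray]:
    p = rate_map.occupancy[rate_map.visited]
    lam = rate_map.rate[rate_map.visited]
    return p, lam


def spatial_information(rate_map: RateMap) -> float:
    """Skaggs spatial information (bits/spike).

    I = sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda), with
    lambda = sum_i p_i lambda_i the overall mean rate; zero-rate pixels
    contribute zero (x log x -> 0). NaN when the cell never fires.
    """
    p, lam = _visited_p_lambda(rate_map)
    mean = float(np.dot(p, lam))
    if mean <= 0:
        logger.warning("spatial information undefined: overall mean rate is 0")
        return float("nan")
    ratio = lam / mean
    pos = ratio > 0
    return float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))


def sparseness(rate_map: RateMap) -> float:
    """Spatial sparseness: (sum_i p_i lambda_i)^2 / sum_i p_i lambda_i^2.

    Equals 1 for spatially uniform firing and approaches 1/N when all
    firing is confined to one of N equally occupied pixels. NaN for a
    silent cell.
    """
    p, lam = _visited_p_lambda(rate_map)
    denom = float(np.dot(p, lam ** 2))
    if denom <= 0:
        logger.warning("sparseness undefined: cell fires nowhere")
        return float("nan")
    return float(np.dot(p, lam) ** 2 / denom)


def burst_fraction(spikes: SpikeTrain | np.ndarray, burst_isi: float = 0.010) -> float:
    """Fraction of firing events that are bursts.

    The train is partitioned into maximal runs of spikes whose consecutive
    inter-spike intervals are <= ``burst_isi`` (default 10 ms, the
    conventional CA1 complex-spike window). Runs of two or more spikes are
    bursts, isolated spikes are singles; the statistic is
    bursts / (bursts + singles). NaN for fewer than one spike.
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    if times.size < 1:
        logger.warning("burst fraction undefined for an empty spike train")
        return float("nan")
    if times.size == 1:
        return 0.0
    in_burst = np.diff(times) <= burst_isi
    # run boundaries: events are maximal runs of consecutive short ISIs
    n_events = 1 + int(np.sum(~in_burst))
    padded = np.concatenate([[False], in_burst, [False]])
    starts = np.flatnonzero(np.diff(padded.astype(int)) == 1)
    n_bursts = starts.size
    n_singles = n_events - n_bursts
    return float(n_bursts / (n_bursts + n_singles))


def compute_field_stats(spikes: SpikeTrain, track: PositionTrack,
                        rate_map: RateMap, session: str = "",
                        burst_isi: float = 0.010) -> FieldStats:
    """Assemble the full per-cell, per-session summary."""
    avg = average_rate(spikes, track.duration)
    pk = peak_rate(rate_map) if rate_map.visited.any() else float("nan")
    return FieldStats(
        unit_id=spikes.unit_id,
        session=session,
        average_rate=avg,
        peak_rate=pk,
        field_size_dm2=field_size(rate_map) if pk > 0 else float("nan"),
        information=spatial_information(rate_map),
        sparseness=sparseness(rate_map),
        burst_fraction=burst_fraction(spikes, burst_isi=burst_isi),
    )
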
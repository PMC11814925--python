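"""LFP analysis: ripple detection, Morlet spectrograms and band power.

The sharp-wave-ripple chain: the raw trace is downsampled to 1200 Hz,
bandpass filtered 90-250 Hz with a zero-phase IIR filter, squared and
z-scored over the session to a normalised power envelope. Candidate events
are intervals where the envelope exceeds 3 SD; candidates closer than
30 ms are merged; an event is kept if its envelope peak exceeds 5 SD, its
duration lies in [15, 200] ms, and its peak frequency — the frequency of
maximum 7-cycle Morlet wavelet power inside the event — is at least
115 Hz (lower peaks are discarded as high-gamma contamination). Ripple
analysis is restricted to immobility (speed <= 5 cm/s), the SWR rate is
events per immobile second, and sessions with fewer than 10 ripples are
flagged excluded.

Theta (4-12 Hz), slow-gamma (25-50 Hz) and fast-gamma (65-140 Hz) power
are summarised by summing time-frequency power above a
3 x (mean + SD) threshold and normalising against a baseline epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .session import Lfp, PositionTrack

__all__ = [
    "RippleEvent",
    "Spectrogram",
    "BandPowerSummary",
    "BANDS",
    "downsample",
    "ripple_envelope",
    "detect_ripples",
    "morlet_spectrogram",
    "ripple_peak_frequency",
    "assign_peak_frequencies",
    "immobility_mask",
    "filter_events_to_mask",
    "swr_rate",
    "find_ripples",
    "band_power",
]

logger = logging.getLogger(__name__)

RIPPLE_BAND = (90.0, 250.0)
MIN_PEAK_FREQ = 115.0
MIN_DURATION_MS = 15.0
MAX_DURATION_MS = 200.0
MERGE_MS = 30.0
DETECT_SD = 3.0
PEAK_SD = 5.0
IMMOBILITY_SPEED = 5.0
MIN_RIPPLES_PER_SESSION = 10

#: Oscillatory bands (Hz) used by the band-power summaries.
BANDS = {"theta": (4.0, 12.0), "slow_gamma": (25.0, 50.0),
         "fast_gamma": (65.0, 140.0)}


@dataclass
class RippleEvent:
    """One detected sharp-wave ripple."""

    start: float                 # s
    stop: float                  # s
    peak_time: float             # s
    peak_power: float            # envelope peak, z units (or V^2 from wavelet)
    peak_frequency: float = float("nan")   # Hz, filled by assign_peak_frequencies

    def __post_init__(self) -> None:
        if not (self.start < self.peak_time < self.stop):
            raise ValueError("need start < peak < stop")

    @property
    def duration_ms(self) -> float:
        return (self.stop - self.start) * 1000.0


@dataclass
class Spectrogram:
    """Time-frequency power matrix from 7-cycle complex Morlet wavelets."""

    power: np.ndarray    # (n_freqs, n_times), amplitude-squared units
    freqs: np.ndarray
    times: np.ndarray
    n_cycles: float = 7.0

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class BandPowerSummary:
    """Suprathreshold band power of an epoch relative to a baseline epoch."""

    band: str
    low: float
    high: float
    session_sum: float
    baseline_sum: float
    ratio: float
    threshold_mode: str


def downsample(lfp: Lfp, target_rate: float = 1200.0) -> Lfp:
    """Anti-alias filter and decimate to ``target_rate``.

    Integer ratios use an FIR decimator; non-integer ratios fall back to
    polyphase resampling. The target must be below the source rate.
    """
    if target_rate >= lfp.sample_rate:
        raise ValueError("target rate must be below the source rate")
    ratio = lfp.sample_rate / target_rate
    if abs(ratio - round(ratio)) < 1e-9:
        out = signal.decimate(lfp.samples, int(round(ratio)), ftype="fir",
                              zero_phase=True)
    else:
        from fractions import Fraction
        frac = Fraction(target_rate / lfp.sample_rate).limit_denominator(1000)
        out = signal.resample_poly(lfp.samples, frac.numerator, frac.denominator)
    return Lfp(out, target_rate)


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz invalid for fs={fs} Hz")
    return signal.butter(order, [low / nyq, high / nyq], btype="band",
                         output="sos")


def bandpass(x: np.ndarray, low: float, high: float, fs: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass."""
    sos = _bandpass_sos(low, high, fs, order)
    return signal.sosfiltfilt(sos, x)


def ripple_envelope(lfp: Lfp, band: tuple[float, float] = RIPPLE_BAND) -> np.ndarray:
    """Normalised ripple-band power: bandpass, square, z-score.

    The z-scoring is over the whole session, so the detection thresholds
    downstream are in session-SD units.
    """
    if lfp.sample_rate < 2.5 * band[1] * 0.96:
        raise ValueError("sample rate too low for the ripple band")
    min_len = int(3 * lfp.sample_rate / band[0]) * 2
    if lfp.samples.size < min_len:
        raise ValueError("session shorter than the filter transient")
    filtered = bandpass(lfp.samples, band[0], band[1], lfp.sample_rate)
    power = filtered ** 2
    sd = power.std()
    if sd == 0:
        return np.zeros_like(power)
    return (power - power.mean()) / sd


def detect_ripples(envelope: np.ndarray, sample_rate: float,
                   detect_sd: float = DETECT_SD, peak_sd: float = PEAK_SD,
                   merge_ms: float = MERGE_MS,
                   min_duration_ms: float = MIN_DURATION_MS,
                   max_duration_ms: float = MAX_DURATION_MS) -> list[RippleEvent]:
    """Threshold the normalised envelope into candidate ripple events.

    Candidate intervals exceed ``detect_sd``; intervals separated by less
    than ``merge_ms`` are merged; events are kept iff their envelope peak
    exceeds ``peak_sd`` and their duration lies within
    [``min_duration_ms``, ``max_duration_ms``]. Deterministic: re-running
    on the same envelope yields identical events.
    """
    env = np.asarray(envelope, dtype=float)
    if env.size == 0:
        return []
    above = env > detect_sd
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]      # stop exclusive

    merge_samples = merge_ms / 1000.0 * sample_rate
    merged = [[starts[0], stops[0]]]
    for s, e in zip(starts[1:], stops[1:]):
        if s - merged[-1][1] < merge_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        seg = env[s:e]
        dur_ms = (e - s) / sample_rate * 1000.0
        if seg.max() <= peak_sd:
            continue
        if not (min_duration_ms <= dur_ms <= max_duration_ms):
            continue
        ipk = s + int(np.argmax(seg))
        # half-sample nudges keep start < peak < stop strict at the edges
        peak_t = (ipk + 0.5) / sample_rate
        events.append(RippleEvent(start=s / sample_rate,
                                  stop=e / sample_rate,
                                  peak_time=peak_t,
                                  peak_power=float(seg.max())))
    return events


def _morlet_wavelet(freq: float, sample_rate: float, n_cycles: float) -> np.ndarray:
    """Amplitude-normalised complex Morlet wavelet (unit response to a
    unit-amplitude tone at its centre frequency)."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    wave = np.exp(2j * np.pi * freq * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    gain = np.abs(np.exp(-t ** 2 / (2 * sigma_t ** 2))).sum() / 2.0
    return wave / gain


def morlet_spectrogram(lfp: Lfp, freqs: np.ndarray,
                       n_cycles: float = 7.0) -> Spectrogram:
    """Time-varying power per frequency from complex Morlet wavelets.

    Each frequency uses a constant-Q wavelet of ``n_cycles`` cycles,
    convolved with the data by FFT. Power is squared amplitude, normalised
    so a unit-amplitude tone yields power 1 at its own frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    nyq = lfp.sample_rate / 2.0
    if np.any(freqs <= 0) or np.any(freqs >= nyq):
        raise ValueError("frequencies must lie in (0, Nyquist)")
    x = lfp.samples
    power = np.empty((freqs.size, x.size))
    for i, f in enumerate(freqs):
        w = _morlet_wavelet(f, lfp.sample_rate, n_cycles)
        conv = signal.fftconvolve(x, w, mode="same")
        power[i] = np.abs(conv) ** 2
    return Spectrogram(power=power, freqs=freqs, times=lfp.times,
                       n_cycles=n_cycles)


def ripple_peak_frequency(lfp: Lfp, event: RippleEvent,
                          freqs: np.ndarray | None = None,
                          n_cycles: float = 7.0,
                          pad: float = 0.1) -> tuple[float, float]:
    """Frequency and power of maximum wavelet power inside an event.

    Returns ``(peak_frequency_hz, peak_power)``. The wavelet transform is
    computed on the event window padded by ``pad`` seconds on each side so
    edge effects do not bias the ridge.
    """
    if freqs is None:
        freqs = np.arange(90.0, 250.0 + 1e-9, 2.0)
    fs = lfp.sample_rate
    i0 = max(0, int((event.start - pad) * fs))
    i1 = min(lfp.samples.size, int((event.stop + pad) * fs) + 1)
    if i1 - i0 < 8:
        raise ValueError("event window outside the LFP span")
    seg = Lfp(lfp.samples[i0:i1], fs)
    spec = morlet_spectrogram(seg, freqs, n_cycles=n_cycles)
    j0 = int((event.start * fs)) - i0
    j1 = int(np.ceil(event.stop * fs)) - i0
    window = spec.power[:, max(0, j0):j1]
    fi, ti = np.unravel_index(np.argmax(window), window.shape)
    return float(freqs[fi]), float(window[fi, ti])


def assign_peak_frequencies(lfp: Lfp, events: list[RippleEvent],
                            min_freq: float = MIN_PEAK_FREQ,
                            freqs: np.ndarray | None = None) -> list[RippleEvent]:
    """Attach peak frequencies and drop events peaking below ``min_freq``.

    Events with a peak frequency strictly below the cutoff (high-gamma
    contamination) are eliminated; a peak exactly at the cutoff survives.
    """
    kept = []
    for ev in events:
        f, p = ripple_peak_frequency(lfp, ev, freqs=freqs)
        if f < min_freq:
            continue
        kept.append(replace(ev, peak_frequency=f, peak_power=p))
    return kept


def immobility_mask(track: PositionTrack, vmax: float = IMMOBILITY_SPEED,
                    smooth_window: float = 0.5) -> np.ndarray:
    """(start, stop) intervals (s) where speed <= ``vmax`` cm/s."""
    sp = track.speed(smooth_window=smooth_window)
    mask = sp <= vmax
    if not mask.any():
        return np.empty((0, 2))
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    return np.column_stack([track.t[starts], track.t[stops - 1] + track.dt])


def filter_events_to_mask(events: list[RippleEvent],
                          intervals: np.ndarray) -> list[RippleEvent]:
    """Keep events whose peak time falls inside any (start, stop) interval."""
    if len(intervals) == 0:
        return []
    iv = np.asarray(intervals, dtype=float)
    out = []
    for ev in events:
        if np.any((iv[:, 0] <= ev.peak_time) & (ev.peak_time <= iv[:, 1])):
            out.append(ev)
    return out


@dataclass
class SwrRateResult:
    rate: float          # events per immobile second (NaN if undefined)
    n_events: int
    immobile_time: float
    excluded: bool       # session flagged if fewer than 10 ripples


def swr_rate(events: list[RippleEvent], intervals: np.ndarray,
             min_events: int = MIN_RIPPLES_PER_SESSION) -> SwrRateResult:
    """SWR rate: immobility-gated event count / total immobile time.

    Sessions with fewer than ``min_events`` ripples are flagged excluded
    (the rate is still reported for inspection). Zero immobile time yields
    a NaN rate with a log entry.
    """
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    immobile = float(np.sum(iv[:, 1] - iv[:, 0])) if iv.size else 0.0
    gated = filter_events_to_mask(events, iv)
    n = len(gated)
    if immobile <= 0:
        logger.warning("SWR rate undefined: no immobile time")
        return SwrRateResult(float("nan"), n, 0.0, excluded=True)
    return SwrRateResult(n / immobile, n, immobile, excluded=n < min_events)


def find_ripples(lfp: Lfp, track: PositionTrack | None = None,
                 target_rate: float = 1200.0,
                 detect_sd: float = DETECT_SD, peak_sd: float = PEAK_SD,
                 min_peak_freq: float = MIN_PEAK_FREQ) -> tuple[list[RippleEvent], Lfp]:
    """Full detection chain; returns (events, downsampled LFP).

    Downsample if needed, envelope, threshold detection, peak-frequency
    filtering, and (when a track is supplied) immobility gating.
    """
    work = downsample(lfp, target_rate) if lfp.sample_rate > target_rate else lfp
    env = ripple_envelope(work)
    events = detect_ripples(env, work.sample_rate, detect_sd=detect_sd,
                            peak_sd=peak_sd)
    events = assign_peak_frequencies(work, events, min_freq=min_peak_freq)
    if track is not None:
        events = filter_events_to_mask(events, immobility_mask(track))
    return events, work


def band_power(lfp: Lfp, band: tuple[float, float], baseline: Lfp,
               freq_step: float = 1.0,
               threshold_mode: str = "3x_mean_plus_sd",
               label: str = "") -> BandPowerSummary:
    """Suprathreshold band power of an epoch relative to a baseline epoch.

    The band-power series is the mean Morlet power across the band's
    frequency grid. Within each epoch, samples exceeding the epoch's own
    threshold are summed; the reported value is the session sum divided by
    the baseline sum ("power over baseline"). Threshold readings of the
    3 x mean +/- SD rule:

    * ``"3x_mean_plus_sd"`` (default): threshold = 3 * (mean + SD);
    * ``"3x_mean__plus_sd"``: threshold = 3 * mean + SD;
    * ``"mean_plus_3sd"``: threshold = mean + 3 * SD.

    Computing the threshold per epoch makes the selection scale-invariant,
    so doubling an oscillation's amplitude quadruples the ratio.
    """
    if baseline.samples.size == 0:
        raise ValueError("baseline epoch is empty")
    low, high = band
    freqs = np.arange(low, high + 1e-9, freq_step)

    def suprathreshold_sum(epoch: Lfp) -> float:
        spec = morlet_spectrogram(epoch, freqs)
        series = spec.power.mean(axis=0)
        if threshold_mode == "3x_mean_plus_sd":
            thr = 3.0 * (series.mean() + series.std())
        elif threshold_mode == "3x_mean__plus_sd":
            thr = 3.0 * series.mean() + series.std()
        elif threshold_mode == "mean_plus_3sd":
            thr = series.mean() + 3.0 * series.std()
        else:
            raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
        return float(series[series > thr].sum())

    s_sum = suprathreshold_sum(lfp)
    b_sum = suprathreshold_sum(baseline)
    ratio = s_sum / b_sum if b_sum > 0 else float("nan")
    if b_sum <= 0:
        logger.warning("baseline suprathreshold power is zero; ratio undefined")
    return BandPowerSummary(band=label or f"{low:g}-{high:g}Hz", low=low,
                            high=high, session_sum=s_sum, baseline_sum=b_sum,
                            ratio=ratio, threshold_mode=threshold_mode)
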
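# Methods

`remapkit` implements the standard analysis chain for CA1 place-cell
recordings in a familiar/novel open-field design — occupancy-normalised
rate maps, place-field statistics, cross-session remapping metrics,
sharp-wave-ripple (SWR) and oscillation-band analysis, and
normality-gated group statistics — together with a synthetic-session
generator that produces the same kind of data with known ground truth.
This note documents the models, the defaults and the numerical choices.

## Synthetic sessions

### Trajectory model

Foraging is modelled as a speed/heading random walk inside a square or
circular arena occupying the room-frame box `[0, extent]²` (circle
inscribed; default extent 100 cm):

* **speed** follows an Ornstein–Uhlenbeck process around `mean_speed`
  (default 15 cm/s, SD 5 cm/s, relaxation time 1 s), clipped at zero;
* **heading** performs a Gaussian random walk
  (default 1.2 rad/√s);
* **walls** are reflective: a step leaving the arena is mirrored back
  and the heading component normal to the wall is flipped (for the
  circle, reflected about the local tangent);
* **immobility bouts** arrive as a Poisson process (default 2 bouts/min,
  exponential lengths of mean 3 s) during which the animal is frozen in
  place.

These defaults were chosen once for realism: a 10 min (600 s) session
at the 50 Hz tracker rate visits ≈ 99 % of the 5 cm pixels, moving
speed fluctuates in the 10–20 cm/s range, and the session-to-session
variability they induce in a cell's average rate (SD of log-rate
≈ 0.15–0.2) reproduces the ~0.8 stable-condition rate overlap typical
of repeated familiar-arena recordings. The tracker rate itself is a
convention (the hardware analogue is not dictated by the design) and is
exposed in the config.

### Place cells and spikes

Each cell has Gaussian spatial tuning
`rate(x) = b + (p − b)·exp(−d²/2σ²)` with field width σ = 10 cm,
baseline b = 0.1 Hz and peak rates drawn uniformly from 4–16 Hz
(order-of-magnitude 1–20 Hz CA1 fields). Spikes are drawn from an
inhomogeneous Poisson process by thinning against the rate's maximum,
with linear interpolation of the rate between tracker frames; a test
validates the generator against the time-rescaling theorem. An optional
burst mode appends, with configurable probability, a geometric number
of extra spikes at 5 ms intervals after a parent spike, giving the
burst-fraction statistic a known ground truth.

Three cross-environment regimes derive the novel-arena population from
the familiar one:

* **stable** — identical specs;
* **rate remapping** — field centres preserved bit-exactly, peak rates
  multiplied by a per-cell scale (default 0.4);
* **global remapping** — centres redrawn uniformly over the arena,
  independent of the familiar map.

### LFP

The trace is a sum of pink (1/f-power) noise, a theta sinusoid
(8 Hz) whose amplitude is modulated by a smoothed log-normal envelope
(σ = 0.8, 2 s correlation time — real theta power fluctuates roughly
log-normally, and a constant-amplitude sinusoid would make episodic
power summaries degenerate), Poisson-timed Hann-windowed gamma bursts
(slow 25–50 Hz and fast 65–140 Hz bands), and injected ripples:
Hann-tapered sinusoids of configurable frequency (120–200 Hz),
duration (15–200 ms) and amplitude. The Hann taper gives smooth
onsets/offsets so detected durations track injected ones. With the
immobility flag set, scheduling a ripple outside an immobility interval
of the supplied trajectory is an error.

All randomness flows from one session-level seed through named
`numpy.random.SeedSequence` substreams (spawn keys derived from CRC32
hashes of string tags), so adding a consumer never perturbs existing
streams and every run is bit-reproducible.

## Rate maps and field statistics

* **Spike-density function (SDF).** The spike train is convolved with a
  2 s Blackman kernel normalised to unit gain at zero frequency and
  sampled synchronously with the tracker. Numerically, spikes are
  binned onto tracker frames (20 ms at 50 Hz, two orders of magnitude
  finer than the kernel) and convolved by FFT; the SDF integrates to
  the spike count to < 1e−3.
* **Rate map.** Each 5 × 5 cm pixel's rate is the weighted mean of SDF
  samples, weight = a 30 cm-wide Blackman window of the Euclidean
  distance from sample position to pixel centre (zero beyond 15 cm).
  Weights are renormalised over available samples, so rates are not
  suppressed at walls. Pixels never visited carry no rate. Bin edges
  are half-open `[5k, 5k+5)` cm with the origin at the arena corner.
  Occupancy `p_i` is time-in-pixel over total time. Whether the peak
  rate is read pre- or post-smoothing is a genuine ambiguity; the
  post-smoothing map maximum is used.
* **Field size** is the largest 8-connected cluster of pixels above
  20 % of the peak rate, in dm² (0.25 dm² per pixel); connectivity is
  switchable to 4.
* **Spatial information** `I = Σ p_i (λ_i/λ) log2(λ_i/λ)` and
  **sparseness** `S = (Σ p_i λ_i)² / Σ p_i λ_i²` over visited pixels;
  zero-rate pixels contribute zero to I (x log x → 0); both are
  invariant to rate rescaling and silent cells return NaN with a log
  entry.
* **Burst fraction** partitions the train into maximal runs of ISIs at
  or below 10 ms (a conventional complex-spike window, configurable)
  and reports bursts/(bursts + singles).
* **Inclusion rule:** a unit is an active place cell if its average
  rate (count/duration) reaches 0.25 Hz in at least one session; the
  boundary is inclusive.

## Remapping metrics

* **Spatial correlation** is the Pearson correlation of pixel rates
  over the jointly visited mask of two sessions registered on the
  common room-frame grid (the circle sits inscribed in the square
  grid); it needs ≥ 20 common pixels and nonzero variance, else NaN.
  No spatial-lag correction is applied; this plain cross-session pixel
  correlation is the standard stability statistic.
* **Rate overlap** is the per-cell min/max ratio of session-average
  rates (1 for unchanged rates, 0 for one-environment cells, cells
  silent in both excluded), averaged over cells. **Rate change** is the
  per-cell absolute rate difference.
* **Contrast and classification.** F–F′ and F–N metrics are compared
  cell-by-cell with a paired location test (paired t or Wilcoxon
  signed-rank, gated by Shapiro–Wilk on the differences). The regime
  label is read off the (spatial correlation, overlap contrast) plane:
  mean F–N correlation < 0.25 → global remapping; else a significant
  overlap drop > 0.15 → rate remapping; else stable. The 0.15 floor is
  three null-SDs of the stable-condition overlap drop under the
  generator's defaults (≈ 0.05), roughly midway to the ≈ 0.25 drop a
  0.4 peak-rate rescaling produces, and keeps small occupancy-driven
  fluctuations from reading as rate remapping.
* Regime-recovery simulations use a **square** novel arena so the
  regime signal is not confounded with square-vs-circle occupancy
  geometry (a circle's smaller floor area shifts average rates even
  for a stable population); the circular novel arena is exercised by
  the simulator tests and the default pipeline configuration.

## LFP analysis

* **Downsampling** to 1200 Hz uses an FIR anti-alias decimator
  (zero-phase); out-of-band components are suppressed by > 40 dB.
* **Ripple envelope**: zero-phase 4th-order Butterworth bandpass
  90–250 Hz, squared, z-scored over the whole session (detection
  thresholds are in session-SD units; an immobility-only normalisation
  is the obvious alternative and can be obtained by passing a cropped
  trace).
* **Detection**: envelope > 3 SD marks candidates; candidates closer
  than 30 ms merge; events must peak > 5 SD and last 15–200 ms. Peak
  frequency is the argmax of 7-cycle complex-Morlet power inside the
  event (computed on a ±100 ms padded window); events peaking below
  115 Hz are discarded as high-gamma contamination (115 Hz itself
  survives: the rule is strict "<"). Wavelets are amplitude-normalised
  (a unit tone yields unit power at its own frequency). Detection is
  deterministic and idempotent.
* **Immobility gating**: speed is computed from positions smoothed
  with a 0.5 s moving window (raw tracker jitter inflates speed);
  events whose peak falls outside speed ≤ 5 cm/s intervals are
  discarded. SWR rate is events per immobile second; sessions with
  fewer than 10 ripples are flagged excluded.
* **Band power** (theta 4–12, slow gamma 25–50, fast gamma
  65–140 Hz): the band-power series is mean Morlet power across the
  band grid; within each epoch, samples above the epoch's own
  threshold are summed and the session sum is reported relative to the
  baseline epoch (the pre-trial pot rest in the pipeline). The
  threshold default is 3 × (mean + SD); the readings 3 × mean + SD and
  mean + 3 SD are config-switchable because the rule's phrasing is
  ambiguous. Computing the threshold per epoch makes the selection
  scale-invariant, so doubling an oscillation's amplitude quadruples
  the reported ratio.

## Group statistics

Each group's sample is screened with Shapiro–Wilk at α = 0.05;
parametric tests (one-way ANOVA, t) are used only when **every** group
passes — the conservative choice for the mixed case — otherwise
Kruskal–Wallis and Mann–Whitney U. Degenerate samples (n < 3 or
constant) force the nonparametric family with a warning. Pairwise
p-values are reported uncorrected with optional Bonferroni correction
recorded alongside. Under a Gaussian null the full gated pipeline's
type-I error stays within [0.03, 0.07] (about 14 % of triples route to
the nonparametric family at n = 30, both branches holding their
nominal level). Cells are treated as independent units of analysis;
within-animal correlation is not modelled — a known limitation shared
with the tables this mirrors.

## What the simulations do and do not show

Passing the recovery suites shows the chain is self-consistent: known
Gaussian fields, Poisson spikes, scripted regimes and injected ripples
are recovered at desk scale (10 min sessions, 50-cell populations,
100-run sweeps; ripple recovery uses 50 high-SNR events in one 600 s
immobile session). The generator omits theta phase precession,
experience-dependent field drift, interneurons, spike-sorting errors,
electrode drift, movement artefacts and ripple–spike coupling, so
green tests certify the implementation, not biological conclusions
about real recordings. Real effect sizes near the detection thresholds
(low-SNR ripples, overlap drops ≲ 0.15) would need larger populations
than these defaults to resolve.

## Degenerate inputs and sentinels

Undefined statistics (silent cell, all-zero map, zero variance, too
few common pixels, zero immobile time) return NaN with a log entry
rather than raising, so population summaries can skip them; violated
preconditions (negative rates, misaligned series, out-of-range
frequencies, invalid configs) raise `ValueError` before any
computation.
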
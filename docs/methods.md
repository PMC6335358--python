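# Methods

`meanet` re-implements, as a tested pipeline, the analysis chain used to
quantify how dissociated hippocampal neurons wire themselves into a network
on a multielectrode array (MEA): spike detection from extracellular voltage,
network-burst detection and classification from the population firing rate,
delayed-synchrony functional graphs with hub metrics, and calcium-transient
detection from ROI fluorescence.  Because no recordings are distributed with
the original study, every stage is validated against a synthetic-activity
generator that plants known ground truth at the activity levels the study
reports.

## Recording model

The simulated substrate is the standard 59-electrode MEA: an 8×8 TiN grid at
200 µm pitch with the four corners absent and one electrode reserved as
internal reference.  Voltage is sampled at 20 kHz per channel in µV;
fluorescence traces are mean-ROI intensities on the 8-bit 0–255 scale at
4 Hz.

## Spike detection

Each channel is band-pass filtered at 0.3–8 kHz (2nd-order Butterworth run
forward and backward, so filtering is zero-phase and spike peaks are not
displaced).  The noise level is estimated from the median of the filtered
signal,

    σ = median(|x|) / 0.6745,        T = N_s σ,

where 0.6745 = Φ⁻¹(0.75) maps the median absolute value of Gaussian noise
onto its standard deviation.  Unlike a plain standard deviation, the median
barely moves when spikes are present (≤1% contaminated samples shift σ by
<2%), so the threshold does not climb with firing rate.  With the default
N_s = 4 and typical ~5 µV noise the threshold sits near 20 µV.  Spikes are
events where |x| exceeds T; each suprathreshold excursion is timed at its
extremal-magnitude sample, and a 1-ms minimal interspike interval suppresses
secondary crossings of one waveform.  Detection uses |x| rather than the
negative phase only — the estimator is symmetric, and the simulated biphasic
waveform makes polarity uninformative.  σ is estimated per channel (noise
differs across electrodes); a pooled-σ mode is available for comparison with
global-threshold analyses.

Operating range: with the planted biphasic 1-ms waveform, recall and
precision are ≥0.95 down to an amplitude/noise ratio of 5 (tested at planted
rates of tens of Hz; at very low firing rates the ~1/s/channel false-crossing
rate of a 4σ threshold on band-limited noise dominates precision, as it does
for any fixed-threshold detector).

## Network bursts

The total spiking rate TSR(t) counts spikes from all electrodes in 50-ms
bins aligned to t = 0 (half-open, so counts are conserved).  The burst
threshold is

    T_burst = 0.1 × σ_TSR,

with σ_TSR the standard deviation of the raw TSR series, bursts included —
the burst peaks are what give the series its variance, so one tenth of the
SD lands just above the background floor while remaining adaptive to the
recording's own activity level.  Contiguous suprathreshold runs are burst
candidates; runs separated by a single subthreshold bin are merged (gap
tolerance 1 bin, configurable) so a burst straddling a bin boundary is not
split.  A candidate qualifies as a network burst only if its peak 50-ms bin
holds ≥4 spikes on ≥4 distinct electrodes, and the peak-bin count classifies
it: 4–100 spikes → small, ≥101 → large.

Burst bounds default to the first/last spike inside the suprathreshold run
rather than the outer bin edges.  Bin-edge bounds quantize durations to
50 ms, which caps duration accuracy at ±50 ms per boundary; spike-refined
bounds recover planted burst durations with ≤10% relative error up to 5-Hz
burst frequencies (the package's duration-validation experiment,
`meanet.validation.burst_duration_recovery`, reports ~7% worst case).
Bin-edge bounds remain available via `refine_bounds=False`.

## Delayed-synchrony graphs

For an ordered electrode pair (i, j) the connectivity coefficient is the
fraction of j's spikes that are delayed-synchronous with a spike on i:

    C_ij = n_synchr,ij / n_j,

where a j-spike counts if it falls within a tolerance window of width δ
(default 2 ms) centred on t_i + τ_ij, and τ_ij is the inter-electrode
distance divided by a conduction velocity (default 300 µm/ms).  Each j-spike
can be claimed by at most one i-spike — sources are processed in time order
and claim the earliest unclaimed in-window target — which bounds C_ij by 1.
A brute-force all-pairs scan serves as the oracle for this computation in
the test suite.  Pairs whose target never fired are reported as 0 and
flagged.

The functional graph retains the largest 5% of the off-diagonal
coefficients as directed edges, i.e. ⌊0.05·n(n−1)⌋ = 171 edges for 59
electrodes, with ties at the cut broken lexicographically so the selection
is exactly reproducible.  The 5% cut is taken over ordered pairs since the
matrix is directional by construction.  Hubs are electrodes whose total
(in + out) degree reaches `min_degree` (default 10, an operating point
consistent with the ~10–13 connections per hub reported for mature
cultures); the hub coefficient of an electrode is its degree divided by the
total number of connections in the graph.  Network overlap between two
recordings of the same culture is the percentage of the earlier graph's
directed edges present in the later one.

Known limitations of the top-fraction rule, mapped by simulation and worth
keeping in mind when interpreting hubs on real data:

* the 5% quota is unconditional, so on recordings dominated by network
  bursts the retained "excess" edges concentrate on strongly co-bursting
  electrodes and can reach hub-level degrees without any underlying
  hub structure;
* when transmission jitter is small relative to δ, two targets of one hub
  inherit delay-aligned common-input synchrony whenever the three
  electrodes are nearly collinear, so co-target cliques form; channels
  relaying several hubs are indistinguishable from hubs.

Planted hubs are recovered with precision/recall ≥0.9 (10 seeds) when their
territories are disjoint, the background is desynchronized Poisson firing
and jitter is comparable to δ — the regime in which the hub is the only
systematic source of high degree.

## Calcium transients

Each ROI trace is filtered by averaging neighbouring sample pairs (output
one sample shorter, time stamps advanced half a frame), then differenced.
The detection threshold is `accuracy_coeff` (default 2.0) times the SD of
that derivative, so detection is invariant to baseline shifts and to
multiplicative rescaling of the trace.  A transient opens at the first
sample of a positive suprathreshold derivative run and closes at the last
sample of the following negative suprathreshold run (calcium influx, then
decay); an unmatched start is closed at the trace end.  Derivative sample k
spans three raw frames and is stamped at the centre of that support.

Because the threshold is relative to each trace's own derivative SD, a
trace with no transients has its threshold collapse onto the noise floor,
where noise crossings pair into arbitrary events.  Two trace-relative
guards (both scale- and shift-invariant) reject these: detected pulses
shorter than 1 s or rising less than 5 derivative-SDs above their starting
level are discarded.  Genuine transients last several seconds and rise tens
of derivative-SDs, so the guards are inactive on real events; both are
parameters and can be disabled.  The residual limitation — the effective
sensitivity depends on how active the trace is — is inherent to the
self-scaling threshold.

Population summary: a cell is active if it shows ≥1 transient; the headline
oscillation rate averages transients/min over active cells (the all-cells
mean is also reported), and mean transient duration is taken over all
detected transients.

## Synthetic activity generator

The generator's defaults reproduce the activity level of a mature
(two-week) untreated culture and are the conditions under which the
acceptance checks run:

| parameter | default | basis |
|---|---|---|
| background rate | 0.2 spikes/s/electrode | array-wide ~1 spike per 85 ms, inside the reported 10–100 ms range of basal spiking |
| large-burst rate | 27.87 / 5 min | reported mature-culture value |
| spikes per burst | 506.54 (Poisson) | reported mature-culture value |
| burst duration | 0.3 s mean (truncated normal) | produces ~130 spikes in the peak 50-ms bin, safely in the large class |
| burst span | 40 of 59 electrodes | large bursts engage most of the active network |
| conduction velocity | 300 µm/ms | configurable; delays proportional to distance |
| calcium rate | 1.55 osc/min | reported mature-culture value |
| calcium duration | 9.67 s mean (SD 1.5) | reported day-10 value |
| calcium amplitude / baseline / noise | 60 / 30 / 0.7 intensity units | clean mean-ROI traces: averaging hundreds of pixels leaves sub-unit noise |
| calcium rise/decay tau | 1.2 s / 1.2 s | transients shaped as a plateau with exponential edges |

Burst onsets are Poisson with non-overlap enforced (or regularly spaced for
controlled duration experiments); intra-burst spikes follow a truncated-
Gaussian envelope (uniform available) across a random electrode subset.
Every channel honours a 1-ms minimal interspike interval; colliding burst
spikes are resampled rather than dropped so realized burst sizes track the
configured mean.  Hub wiring copies each source spike to each target with
the configured probability at delay distance/velocity plus Gaussian jitter;
territories are disjoint when the array allows.  Voltage rendering injects
a biphasic (negative-then-positive) 1-ms sine-period waveform at each spike
time over Gaussian noise — the standard extracellular shape, spectrally
centred near 1 kHz inside the detection band.  Calcium transients are
plateaus with exponential rise/decay edges placed without overlap (2-s
clearance) and fully inside the recording, on a noisy baseline clipped to
[0, 255].

What the generator does not emulate — and hence what passing tests do not
demonstrate about real data: electrode drift and non-stationary noise,
spike-waveform diversity and overlap (no spike sorting is attempted),
developmental changes within a recording, superburst structure, calcium
indicator bleaching, and motion or segmentation artifacts (the pipeline
starts at traces; ROI selection is out of scope).

## Validation experiments and problem sizes

`meanet.validation` packages three end-to-end parameter-recovery
experiments, which `scripts/acceptance.py` re-runs from scratch:

* **Burst-duration accuracy** — planted bursts at 0.5/1/2/5 Hz on
  59 channels, 60-s recordings, 10 seeds (~5 000 bursts); maximum relative
  duration error, expected ≤10%.
* **Mature-culture electrophysiology** — 10 five-minute recordings at the
  default activity level; mean detected large bursts per 5 min and mean
  spikes per large burst, compared with the reported 27.87 ± 5.21 and
  506.54 ± 67.11.
* **Calcium activity** — 50 cells × 300 s × 10 seeds at the default rate
  and duration; recovered oscillations/min (reported 1.55 ± 0.08) and mean
  transient duration (reported 9.67 ± 0.69 s).

These sizes keep the whole validation under ten seconds on one CPU while
holding the Monte-Carlo error of each recovered mean well inside the
published uncertainty it is compared against.  The recovered transient
duration carries a small systematic offset (≈ −0.2 s) from the half-frame
stamping of the smoothed derivative and the threshold crossing the
exponential edges slightly inside the planted interval; it is well within
the published SEM and documented rather than corrected, since the original
durations were measured with the same class of algorithm.
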
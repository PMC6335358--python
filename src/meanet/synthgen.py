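"""Synthetic neuronal-culture activity with planted ground truth.

Three generators emulate what a mature hippocampal culture on a 59-electrode
array produces, each returning the planted events so every downstream stage
can be benchmarked against known truth:

* ``simulate_raster`` — homogeneous Poisson background spiking on every
  electrode plus network bursts (many spikes on many electrodes inside a
  short window) and optional hub-structured propagation: spikes from hub
  electrodes are copied to their neighbours with a configurable probability
  at a delay proportional to the inter-electrode distance.
* ``simulate_voltage`` — renders a raster into extracellular voltage traces:
  Gaussian noise plus a biphasic ~1-ms spike waveform at each spike time.
* ``simulate_calcium`` — per-ROI fluorescence (0-255 intensity units, 4 Hz)
  with Poisson-timed transients shaped as a plateau with exponential rise
  and decay edges, on a noisy baseline.

Default parameters reproduce the activity level of a mature (two-week)
untreated culture: ~28 large network bursts per 5 minutes of ~507 spikes
each on the electrophysiology side, and ~1.55 calcium oscillations per
minute of ~9.7 s on the imaging side.  All randomness flows from the
explicit ``seed`` in each config; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calcium import FluorescenceTrace
from .geometry import MEAGeometry, standard_mea
from .spikes import SpikeRaster, VoltageRecording

__all__ = [
    "RasterSimConfig",
    "CalciumSimConfig",
    "GroundTruth",
    "simulate_raster",
    "simulate_voltage",
    "simulate_calcium",
    "biphasic_waveform",
]

#: sham DIV 14 activity level: large-burst rate (bursts/s) and burst size
_DEFAULT_BURST_RATE = 27.87 / 300.0
_DEFAULT_SPIKES_PER_BURST = 506.54


@dataclass
class GroundTruth:
    """Planted events returned alongside every simulated dataset.

    ``burst_intervals`` holds ``(start_s, end_s, n_spikes)`` per planted
    network burst (realized extent and count of the spikes that survived
    per-channel refractoriness); ``edges`` holds directed
    ``(source, target, probability)`` propagation edges; ``transient_events``
    maps ROI id to ``(start_s, end_s)`` calcium transients.
    """

    burst_intervals: list[tuple[float, float, int]] = field(default_factory=list)
    edges: list[tuple[int, int, float]] = field(default_factory=list)
    transient_events: dict[int, list[tuple[float, float]]] = field(default_factory=dict)


@dataclass(frozen=True)
class RasterSimConfig:
    """Parameters of the spike-raster simulator.

    Rates are per second; ``jitter_sd`` is in milliseconds, conduction
    velocity in um/ms.  ``burst_placement`` is ``"poisson"`` (Poisson onsets
    thinned to keep planted bursts non-overlapping) or ``"regular"``
    (evenly spaced onsets with a random common phase, for controlled
    duration-recovery experiments at high burst frequencies).
    """

    duration: float = 300.0
    background_rate: float = 0.2
    burst_rate: float = _DEFAULT_BURST_RATE
    burst_duration_mean: float = 0.3
    burst_duration_sd: float | None = None  # default: 0.15 * mean
    spikes_per_burst_mean: float = _DEFAULT_SPIKES_PER_BURST
    burst_electrode_span: int = 40
    burst_envelope: str = "gaussian"
    burst_placement: str = "poisson"
    hub_ids: tuple[int, ...] = ()
    hub_out_degree: int = 12
    background_ids: tuple[int, ...] | None = None
    propagation_probability: float = 0.0
    conduction_velocity: float = 300.0
    jitter_sd: float = 0.1
    refractory_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if min(self.background_rate, self.burst_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.burst_electrode_span < 4:
            raise ValueError("burst_electrode_span must be at least 4 electrodes")
        if not 0.0 <= self.propagation_probability <= 1.0:
            raise ValueError("propagation_probability must lie in [0, 1]")
        if self.burst_duration_mean <= 0:
            raise ValueError("burst_duration_mean must be positive")
        if self.conduction_velocity <= 0:
            raise ValueError("conduction_velocity must be positive")
        if self.burst_envelope not in ("gaussian", "uniform"):
            raise ValueError("burst_envelope must be 'gaussian' or 'uniform'")
        if self.burst_placement not in ("poisson", "regular"):
            raise ValueError("burst_placement must be 'poisson' or 'regular'")


@dataclass(frozen=True)
class CalciumSimConfig:
    """Parameters of the fluorescence-trace simulator.

    ``event_rate`` is in oscillations per minute; taus shape the exponential
    rise and decay edges of each transient; intensities are on the 0-255
    scale of 8-bit mean-ROI fluorescence.
    """

    n_cells: int = 50
    duration: float = 300.0
    frame_rate: float = 4.0
    event_rate: float = 1.55
    event_duration_mean: float = 9.67
    event_duration_sd: float = 1.5
    amplitude: float = 60.0
    rise_tau: float = 1.2
    decay_tau: float = 1.2
    noise_sd: float = 0.7
    baseline: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.duration <= 0:
            raise ValueError("n_cells and duration must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.event_duration_mean <= 0:
            raise ValueError("event_duration_mean must be positive")
        if self.event_rate < 0 or self.noise_sd < 0:
            raise ValueError("event_rate and noise_sd must be non-negative")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("rise and decay taus must be positive")
        if not 0 <= self.baseline <= 255 or self.baseline + self.amplitude > 255:
            raise ValueError("baseline + amplitude must stay within [0, 255]")


# ---------------------------------------------------------------------------
# raster simulation
# ---------------------------------------------------------------------------


def _draw_burst_durations(rng, n, mean, sd):
    if sd == 0 or n == 0:
        return np.full(n, mean)
    d = rng.normal(mean, sd, n)
    return np.clip(d, 0.5 * mean, 1.5 * mean)


def _place_bursts(rng, config: RasterSimConfig) -> list[tuple[float, float]]:
    """Non-overlapping (onset, duration) pairs for planted bursts."""
    mean = config.burst_duration_mean
    sd = config.burst_duration_sd if config.burst_duration_sd is not None else 0.15 * mean
    if config.burst_rate == 0:
        return []
    if config.burst_placement == "regular":
        period = 1.0 / config.burst_rate
        dur_max = 1.5 * mean if sd else mean
        if period <= dur_max:
            raise ValueError("burst period must exceed burst duration for regular placement")
        phase = rng.uniform(0.0, period - dur_max)
        onsets = np.arange(phase, config.duration, period)
        durs = _draw_burst_durations(rng, onsets.size, mean, sd)
        out = [(o, d) for o, d in zip(onsets, durs) if o + d < config.duration]
        return out
    n = rng.poisson(config.burst_rate * config.duration)
    durs = _draw_burst_durations(rng, n, mean, sd)
    margin = 0.1  # s of clearance between planted bursts
    placed: list[tuple[float, float]] = []
    for d in durs:
        if d >= config.duration:
            continue
        for _ in range(200):
            onset = rng.uniform(0.0, config.duration - d)
            if all(
                onset > o2 + d2 + margin or onset + d + margin < o2
                for o2, d2 in placed
            ):
                placed.append((float(onset), float(d)))
                break
    placed.sort()
    return placed


def _sample_envelope(rng, n, start, dur, envelope, min_gap):
    """n spike times inside [start, start+dur) honouring a per-unit minimal gap."""

    def draw(k):
        if envelope == "uniform":
            return rng.uniform(start, start + dur, k)
        t = rng.normal(start + dur / 2.0, dur / 4.0, k)
        bad = (t < start) | (t >= start + dur)
        while np.any(bad):
            t[bad] = rng.normal(start + dur / 2.0, dur / 4.0, int(bad.sum()))
            bad = (t < start) | (t >= start + dur)
        return t

    # keep the request feasible under the refractory constraint
    n = min(n, max(1, int(0.7 * dur / min_gap))) if min_gap > 0 else n
    t = draw(n)
    for _ in range(200):
        t = np.sort(t)
        bad = np.flatnonzero(np.diff(t) < min_gap) + 1
        if bad.size == 0:
            return t
        t[bad] = draw(bad.size)
    t = np.sort(t)
    keep = np.r_[True, np.diff(t) >= min_gap]
    return t[keep]


def _hub_edges(rng, geometry: MEAGeometry, config: RasterSimConfig):
    """Directed edges from each hub to a random electrode subset.

    Targets are drawn uniformly over the array (axonal projections span the
    culture rather than stopping at grid neighbours) and, when the array is
    large enough, each hub receives its own disjoint territory.  Scattered,
    non-shared targets keep the synchrony planted by one hub from aliasing
    into spurious target-target or relay connections: for scattered targets
    the pairwise distance-derived delay rarely matches their common-input
    time offset, and no channel relays more than one hub.
    """
    edges = []
    hub_idx = {geometry.index_of(h) for h in config.hub_ids}
    pool = [j for j in range(geometry.n_electrodes) if j not in hub_idx]
    k = min(config.hub_out_degree, len(pool))
    disjoint = k * len(config.hub_ids) <= len(pool)
    if disjoint:
        shuffled = rng.permutation(pool)
    for h_num, hub in enumerate(config.hub_ids):
        if disjoint:
            targets = shuffled[h_num * k : (h_num + 1) * k]
        else:
            targets = rng.choice(pool, size=k, replace=False)
        edges.extend(
            (int(hub), int(geometry.electrode_ids[j]), config.propagation_probability)
            for j in sorted(int(j) for j in targets)
        )
    return edges


def simulate_raster(
    config: RasterSimConfig, geometry: MEAGeometry | None = None
) -> tuple[SpikeRaster, GroundTruth]:
    """Simulate a spike raster with planted bursts and propagation edges.

    Returns the raster together with ground truth: per-burst realized
    ``(start, end, count)`` intervals, the planted directed edges, and (for
    symmetry with the calcium generator) an empty transient map.  Every
    channel honours the 1-ms minimal interspike interval that detection
    assumes; burst spikes are resampled rather than discarded on collision
    so realized burst sizes track ``spikes_per_burst_mean``.
    """
    geometry = geometry if geometry is not None else standard_mea()
    if config.burst_rate > 0 and config.burst_electrode_span > geometry.n_electrodes:
        raise ValueError("burst_electrode_span exceeds the electrode count")
    if any(h not in geometry.electrode_ids for h in config.hub_ids):
        raise ValueError("hub_ids must be electrodes of the geometry")
    rng = np.random.default_rng(config.seed)
    min_gap = config.refractory_ms * 1e-3
    n_el = geometry.n_electrodes

    # per-channel (times, labels); label -1 = background, k >= 0 = burst index
    times: dict[int, list[np.ndarray]] = {ch: [] for ch in geometry.electrode_ids}
    labels: dict[int, list[np.ndarray]] = {ch: [] for ch in geometry.electrode_ids}

    # planted edges are drawn first so the hub wiring is independent of the
    # background/burst realisation for a given seed
    edges = _hub_edges(rng, geometry, config) if config.hub_ids else []

    # background: homogeneous Poisson on every electrode (optionally a subset)
    bg_ids = set(config.background_ids) if config.background_ids is not None else None
    for ch in geometry.electrode_ids:
        rate = config.background_rate if bg_ids is None or ch in bg_ids else 0.0
        n = rng.poisson(rate * config.duration)
        t = np.sort(rng.uniform(0.0, config.duration, n))
        times[ch].append(t)
        labels[ch].append(np.full(n, -1, dtype=int))

    # planted network bursts
    bursts = _place_bursts(rng, config)
    for k, (onset, dur) in enumerate(bursts):
        chosen = rng.choice(n_el, size=config.burst_electrode_span, replace=False)
        total = rng.poisson(config.spikes_per_burst_mean)
        if total < config.burst_electrode_span:
            total = config.burst_electrode_span  # every chosen electrode fires
        counts = rng.multinomial(
            total - config.burst_electrode_span,
            np.full(config.burst_electrode_span, 1.0 / config.burst_electrode_span),
        ) + 1
        for j, c in zip(chosen, counts):
            ch = geometry.electrode_ids[int(j)]
            t = _sample_envelope(rng, int(c), onset, dur, config.burst_envelope, min_gap)
            times[ch].append(t)
            labels[ch].append(np.full(t.size, k, dtype=int))

    # hub-structured propagation with distance-proportional delays
    if edges and config.propagation_probability > 0:
        dist = geometry.distance_matrix()
        pre_times = {ch: np.concatenate(times[ch]) for ch in geometry.electrode_ids}
        pre_labels = {ch: np.concatenate(labels[ch]) for ch in geometry.electrode_ids}
        for src, tgt, p in edges:
            t_src = pre_times[src]
            l_src = pre_labels[src]
            if t_src.size == 0:
                continue
            keep = rng.random(t_src.size) < p
            delay = (
                dist[geometry.index_of(src), geometry.index_of(tgt)]
                / config.conduction_velocity
                * 1e-3
            )  # um / (um/ms) -> ms -> s
            t_new = t_src[keep] + delay
            if config.jitter_sd > 0:
                t_new = t_new + rng.normal(0.0, config.jitter_sd * 1e-3, t_new.size)
            inside = (t_new >= 0) & (t_new < config.duration)
            times[tgt].append(t_new[inside])
            labels[tgt].append(l_src[keep][inside])

    # merge, sort, enforce the per-channel minimal interspike interval
    raster: dict[int, np.ndarray] = {}
    burst_members: dict[int, list[np.ndarray]] = {k: [] for k in range(len(bursts))}
    for ch in geometry.electrode_ids:
        t = np.concatenate(times[ch])
        lab = np.concatenate(labels[ch])
        order = np.argsort(t, kind="stable")
        t, lab = t[order], lab[order]
        if t.size:
            keep = np.ones(t.size, dtype=bool)
            last = -np.inf
            for i in range(t.size):
                if t[i] - last < min_gap:
                    keep[i] = False
                else:
                    last = t[i]
            t, lab = t[keep], lab[keep]
        raster[ch] = t
        for k in np.unique(lab[lab >= 0]):
            burst_members[int(k)].append(t[lab == k])

    intervals = []
    for k in range(len(bursts)):
        member = burst_members[k]
        if not member:
            continue
        allt = np.concatenate(member)
        intervals.append((float(allt.min()), float(allt.max()), int(allt.size)))
    intervals.sort()

    truth = GroundTruth(burst_intervals=intervals, edges=edges)
    return SpikeRaster(raster, duration=config.duration, geometry=geometry), truth


# ---------------------------------------------------------------------------
# voltage rendering
# ---------------------------------------------------------------------------


def biphasic_waveform(sample_rate: float = 20000.0, width_ms: float = 1.0) -> np.ndarray:
    """Unit-amplitude biphasic (negative-then-positive) spike template.

    One period of a sine, trough first — the standard extracellular shape;
    its spectral energy sits near 1 kHz, inside the 0.3-8 kHz detection band.
    """
    n = max(4, int(round(width_ms * 1e-3 * sample_rate)))
    t = np.arange(n) / n
    return -np.sin(2.0 * np.pi * t)


def simulate_voltage(
    raster: SpikeRaster,
    noise_sd: float = 5.0,
    spike_amplitude: float = 30.0,
    sample_rate: float = 20000.0,
    seed: int = 0,
    waveform: np.ndarray | None = None,
) -> VoltageRecording:
    """Render a raster as extracellular voltage (uV) at ``sample_rate``.

    Gaussian noise of ``noise_sd`` per channel plus the spike template scaled
    to ``spike_amplitude`` (peak magnitude), with the template trough aligned
    to each spike time.
    """
    if spike_amplitude <= 0:
        raise ValueError("spike_amplitude must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    wf = biphasic_waveform(sample_rate) if waveform is None else np.asarray(waveform, float)
    wf = wf / np.max(np.abs(wf))
    trough = int(np.argmin(wf))
    n_samples = int(round(raster.duration * sample_rate))
    channels = (
        raster.geometry.electrode_ids if raster.geometry is not None else raster.channels
    )
    data = (
        rng.normal(0.0, noise_sd, (len(channels), n_samples))
        if noise_sd > 0
        else np.zeros((len(channels), n_samples))
    )
    for row, ch in enumerate(channels):
        for t in raster.channel_times(ch):
            idx = int(round(t * sample_rate))
            if idx >= n_samples:
                raise ValueError(f"spike at {t:.6f}s beyond recording duration")
            start = idx - trough
            a, b = max(0, start), min(n_samples, start + wf.size)
            data[row, a:b] += spike_amplitude * wf[a - start : b - start]
    return VoltageRecording(data, sample_rate, tuple(channels), raster.geometry)


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------


def _transient_shape(t: np.ndarray, start: float, end: float, rise_tau: float,
                     decay_tau: float) -> np.ndarray:
    """Plateau pulse with exponential rise/decay edges, peak-normalized to 1."""
    g = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    ti = t[inside]
    g_in = (1.0 - np.exp(-(ti - start) / rise_tau)) * (
        1.0 - np.exp(-(end - ti) / decay_tau)
    )
    peak = g_in.max() if g_in.size else 0.0
    if peak > 0:
        g[inside] = g_in / peak
    return g


def simulate_calcium(
    config: CalciumSimConfig,
) -> tuple[list[FluorescenceTrace], GroundTruth]:
    """Simulate per-ROI fluorescence traces with planted calcium transients.

    Each cell receives a Poisson number of transients (``event_rate`` per
    minute); transients are placed without overlap (2-s clearance) and fully
    inside the recording, added to a noisy baseline and clipped to [0, 255].
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration * config.frame_rate))
    t = np.arange(n_frames) / config.frame_rate
    margin = 2.0
    traces: list[FluorescenceTrace] = []
    events: dict[int, list[tuple[float, float]]] = {}
    for roi in range(config.n_cells):
        n = rng.poisson(config.event_rate / 60.0 * config.duration)
        durs = rng.normal(config.event_duration_mean, config.event_duration_sd, n)
        lo = max(1.0, config.event_duration_mean - 3 * config.event_duration_sd)
        hi = config.event_duration_mean + 3 * config.event_duration_sd
        durs = np.clip(durs, lo, hi)
        placed: list[tuple[float, float]] = []
        for d in durs:
            if d >= config.duration:
                continue
            for _ in range(200):
                s = rng.uniform(0.0, config.duration - d)
                if all(s > e2 + margin or s + d + margin < s2 for s2, e2 in
                       ((a, a + b) for a, b in placed)):
                    placed.append((float(s), float(d)))
                    break
        placed.sort()
        f = np.full(n_frames, float(config.baseline))
        for s, d in placed:
            f += config.amplitude * _transient_shape(
                t, s, s + d, config.rise_tau, config.decay_tau
            )
        if config.noise_sd > 0:
            f += rng.normal(0.0, config.noise_sd, n_frames)
        f = np.clip(f, 0.0, 255.0)
        traces.append(FluorescenceTrace(f, frame_rate=config.frame_rate, roi_id=roi))
        events[roi] = [(s, s + d) for s, d in placed]
    return traces, GroundTruth(transient_events=events)
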
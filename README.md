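# meanet

Network-formation analysis for neuronal cultures recorded on multielectrode
arrays (MEAs) and with calcium imaging.

Dissociated hippocampal neurons grown on a planar MEA develop, over their
first weeks *in vitro*, from sparse uncorrelated spiking into a structured
network: population-wide bursts, stable functional connections, and hub
electrodes that concentrate a disproportionate share of those connections.
`meanet` provides the complete analysis chain used to quantify that process
for researchers working with 59-channel (8×8, 200 µm pitch) MEA recordings
and ROI fluorescence traces — plus a synthetic-activity generator with
planted ground truth, so every stage can be validated end to end without
access to original recordings.

The chain, stage by stage:

* **Spike detection** — band-pass 0.3–8 kHz, robust noise estimate
  σ = median(|x|)/0.6745, threshold T = N_s·σ (N_s = 4), 1-ms minimal
  interspike interval.
* **Network bursts** — total spiking rate TSR(t) in 50-ms bins; burst
  threshold T_burst = 0.1·σ_TSR; a burst needs ≥4 spikes on ≥4 electrodes
  in its peak bin, and is *small* (4–100 spikes in the peak 50-ms bin) or
  *large* (≥101).
* **Functional graphs** — delayed-synchrony coefficients
  C_ij = n_synchr,ij / n_j with distance-proportional axonal delays τ and
  tolerance δ; the largest 5% of coefficients form a directed graph; hubs,
  hub coefficients (degree / total connections) and between-recording
  network overlap.
* **Calcium transients** — two-point smoothing, first-difference
  derivative, threshold = accuracy coefficient × SD(derivative); percent
  active cells, oscillations/min, transient durations.

## Worked example

Simulate five minutes of mature-culture activity, detect and classify
network bursts, and analyse calcium traces:

```python
from meanet import (
    RasterSimConfig, CalciumSimConfig, simulate_raster, simulate_calcium,
    compute_tsr, detect_network_bursts, classify_bursts, burst_statistics,
    detect_transients, summarize_calcium,
)

raster, truth = simulate_raster(RasterSimConfig(duration=300.0, seed=1))
tsr = compute_tsr(raster)                      # spikes per 50-ms bin
bursts = classify_bursts(detect_network_bursts(tsr, raster))
stats = burst_statistics(bursts, raster.duration)
print(raster.n_spikes, len(truth.burst_intervals))
print(stats.n_large_per_5min, stats.mean_spikes_per_large_burst)

traces, _ = simulate_calcium(CalciumSimConfig(seed=1))
summary = summarize_calcium([detect_transients(t) for t in traces], 300.0)
print(summary.percent_active_cells, summary.oscillations_per_min,
      summary.mean_duration)
```

Output:

```
16171 25
25.0 509.68
100.0 1.536 9.45
```

The generator planted 25 network bursts (a Poisson draw around its default
27.87/5 min) among 16 171 spikes; the detector recovered all 25 as large
bursts averaging 509.7 spikes — the planted 506.5 plus the few background
spikes falling inside each burst window.  All 50 simulated cells were
active, with 1.54 oscillations/min recovered against the planted 1.55 and
9.45 s mean transient duration against the planted 9.67 s (the half-frame
stamping of the smoothed derivative shaves ~0.2 s; see
`docs/methods.md`).

A command-line interface wraps the same stages for shell use:

```bash
meanet simulate --seed 1 --duration 300 --out raster.csv
meanet detect-bursts raster.csv --out bursts.csv
meanet build-graph raster.csv --delta-ms 2 --velocity 300 --out graph.graphml
meanet analyze-calcium calcium.csv --coeff 2.0
meanet overlap div10.graphml div14.graphml
meanet run --config pipeline.yaml --seed 1   # full reproducible pipeline + manifest
```

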
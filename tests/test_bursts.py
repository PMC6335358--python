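"""TSR computation, network-burst detection, classification, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meanet import (
    NetworkBurst,
    RasterSimConfig,
    SpikeRaster,
    activation_profile,
    burst_statistics,
    classify_bursts,
    compute_tsr,
    detect_network_bursts,
    simulate_raster,
)
from meanet.validation import burst_duration_recovery


def _raster(spikes: dict, duration: float) -> SpikeRaster:
    return SpikeRaster({ch: np.sort(np.asarray(t, float)) for ch, t in spikes.items()},
                       duration=duration)


class TestComputeTSR:
    def test_empty_raster_zero_series(self):
        tsr = compute_tsr(_raster({1: []}, 2.0))
        assert tsr.counts.sum() == 0 and tsr.counts.size == 40

    def test_single_bin_count(self):
        # 7 spikes over 5 electrodes inside one 50-ms bin
        spikes = {10 + i: [0.51 + 0.002 * i] for i in range(5)}
        spikes[10] = [0.51, 0.52, 0.53]
        tsr = compute_tsr(_raster(spikes, 1.0))
        assert tsr.counts[10] == 7
        assert tsr.counts.sum() == 7

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        n=st.integers(0, 300),
        bin_ms=st.sampled_from([10.0, 50.0, 73.0]),
        seed=st.integers(0, 1000),
    )
    def test_conservation(self, n, bin_ms, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0.0, 9.99, n))
        tsr = compute_tsr(_raster({1: t[: n // 2], 2: t[n // 2 :]}, 10.0), bin_ms)
        assert tsr.counts.sum() == n

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            compute_tsr(_raster({1: []}, 1.0), bin_width_ms=0.0)


class TestDetectNetworkBursts:
    def test_zero_raster_no_bursts(self):
        tsr = compute_tsr(_raster({1: []}, 5.0))
        assert detect_network_bursts(tsr, _raster({1: []}, 5.0)) == []

    def test_single_planted_burst_recovered(self, rng):
        # 40 spikes over 6 electrodes within 100 ms on a sparse background
        duration = 30.0
        spikes = {ch: list(rng.uniform(0, duration, 3)) for ch in range(20, 40)}
        burst_t = np.sort(rng.uniform(10.02, 10.12, 40))
        for i, t in enumerate(burst_t):
            spikes.setdefault(50 + i % 6, []).append(t)
        raster = _raster({ch: sorted(t) for ch, t in spikes.items()}, duration)
        tsr = compute_tsr(raster)
        bursts = detect_network_bursts(tsr, raster)
        assert len(bursts) == 1
        assert bursts[0].start <= 10.02 + 1e-9 and bursts[0].end >= 10.12 - 1e-2
        assert bursts[0].n_electrodes >= 6

    def test_burst_bounds_modes(self, rng):
        duration = 20.0
        burst_t = np.sort(rng.uniform(5.01, 5.09, 60))
        raster = _raster({60 + i % 5: sorted(burst_t[i::5]) for i in range(5)},
                         duration)
        tsr = compute_tsr(raster)
        refined = detect_network_bursts(tsr, raster, refine_bounds=True)[0]
        binned = detect_network_bursts(tsr, raster, refine_bounds=False)[0]
        assert refined.start == pytest.approx(burst_t[0])
        assert refined.end == pytest.approx(burst_t[-1])
        assert binned.start == pytest.approx(5.0) and binned.end == pytest.approx(5.1)

    def test_intervals_disjoint_and_ordered(self):
        raster, _ = simulate_raster(RasterSimConfig(seed=14))
        tsr = compute_tsr(raster)
        bursts = detect_network_bursts(tsr, raster)
        assert len(bursts) > 5
        for a, b in zip(bursts, bursts[1:]):
            assert a.end < b.start

    def test_spikes_in_bursts_bounded_by_total(self):
        raster, _ = simulate_raster(RasterSimConfig(seed=15))
        tsr = compute_tsr(raster)
        bursts = detect_network_bursts(tsr, raster)
        assert sum(b.n_spikes for b in bursts) <= raster.n_spikes

    def test_count_invariant_to_time_translation(self):
        cfg = RasterSimConfig(duration=120.0, background_rate=0.0, seed=16)
        raster, _ = simulate_raster(cfg)
        n0 = len(detect_network_bursts(compute_tsr(raster), raster))
        shifted = SpikeRaster(
            {ch: raster.channel_times(ch) + 5.0 for ch in raster.channels},
            duration=cfg.duration + 5.0,
        )
        n1 = len(detect_network_bursts(compute_tsr(shifted), shifted))
        assert n0 == n1 > 0

    def test_recovery_rate_and_duration_at_five_hertz(self):
        # planted-burst recovery: count within 15%, durations within 10%
        out = burst_duration_recovery(rates_hz=(5.0,), n_seeds=10, duration=30.0)
        assert out["max_rel_error_pct"] <= 10.0
        # every planted burst matched (undetected bursts would score 100%)
        assert out["n_bursts"] >= 0.85 * 10 * (30 * 5 * 0.9)


class TestClassification:
    @pytest.mark.parametrize("peak,expected", [(100, "small"), (101, "large")])
    def test_small_large_boundary(self, peak, expected):
        # peak 50-ms bin with `peak` spikes over 8 electrodes
        times = np.linspace(1.001, 1.049, peak)
        raster = _raster(
            {30 + i % 8: times[i::8] for i in range(8)} | {50: [0.2, 5.0]}, 10.0
        )
        tsr = compute_tsr(raster)
        bursts = classify_bursts(detect_network_bursts(tsr, raster))
        assert len(bursts) == 1
        assert bursts[0].peak_bin_spikes == peak
        assert bursts[0].size_class == expected

    def test_below_four_spikes_rejected(self):
        # 3 simultaneous spikes never qualify as a network burst
        raster = _raster({41: [1.01], 42: [1.02], 43: [1.03]}, 10.0)
        tsr = compute_tsr(raster)
        assert detect_network_bursts(tsr, raster) == []


class TestBurstStatistics:
    def test_no_bursts_all_zero(self):
        stats = burst_statistics([], 300.0)
        assert stats.n_large_per_5min == 0.0
        assert stats.mean_spikes_per_large_burst == 0.0

    def test_rate_normalization(self):
        bursts = [
            NetworkBurst(start=10.0 * k, end=10.0 * k + 0.5, n_spikes=200,
                         n_electrodes=10, peak_bin_spikes=150,
                         peak_bin_electrodes=10, size_class="large")
            for k in range(10)
        ]
        stats = burst_statistics(bursts, 600.0)
        assert stats.n_large_per_5min == pytest.approx(5.0)
        assert stats.mean_spikes_per_large_burst == pytest.approx(200.0)
        assert stats.mean_burst_duration == pytest.approx(0.5)


class TestActivationProfile:
    def test_single_electrode_burst(self):
        raster = _raster({12: [1.0, 1.01, 1.02]}, 5.0)
        burst = NetworkBurst(start=1.0, end=1.05, n_spikes=3, n_electrodes=1,
                             peak_bin_spikes=3, peak_bin_electrodes=1)
        prof = activation_profile(burst, raster)
        assert prof.latencies_ms == {12: 0.0}

    def test_propagation_chain_orders_latencies(self):
        # planted chain i -> j -> k with fixed 5-ms steps
        raster = _raster(
            {1: [2.000, 2.020], 2: [2.005, 2.025], 3: [2.010, 2.030]}, 5.0
        )
        burst = NetworkBurst(start=2.0, end=2.05, n_spikes=6, n_electrodes=3,
                             peak_bin_spikes=6, peak_bin_electrodes=3)
        prof = activation_profile(burst, raster)
        assert prof.latencies_ms[1] < prof.latencies_ms[2] < prof.latencies_ms[3]

    def test_wider_conduction_delays_spread_latencies(self, geom):
        spreads = []
        for vel in (400.0, 100.0):  # slower conduction -> wider delays
            cfg = RasterSimConfig(
                duration=40.0, background_rate=1.0, burst_rate=0.0,
                hub_ids=(44,), hub_out_degree=20, propagation_probability=1.0,
                jitter_sd=0.0, conduction_velocity=vel, background_ids=(44,),
                seed=19,
            )
            raster, truth = simulate_raster(cfg)
            src = raster.channel_times(44)
            burst = NetworkBurst(start=float(src[0]), end=float(src[0]) + 0.03,
                                 n_spikes=1, n_electrodes=1,
                                 peak_bin_spikes=1, peak_bin_electrodes=1)
            prof = activation_profile(burst, raster)
            spreads.append(np.ptp(list(prof.latencies_ms.values())))
        assert spreads[1] > spreads[0]

    def test_burst_outside_raster_rejected(self):
        raster = _raster({1: [0.5]}, 1.0)
        burst = NetworkBurst(start=0.5, end=1.5, n_spikes=1, n_electrodes=1,
                             peak_bin_spikes=1, peak_bin_electrodes=1)
        with pytest.raises(ValueError):
            activation_profile(burst, raster)
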
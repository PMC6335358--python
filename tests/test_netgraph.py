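"""Delayed-synchrony matrix, edge selection, hubs, network overlap."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meanet import (
    ConnectivityMatrix,
    FunctionalGraph,
    RasterSimConfig,
    SpikeRaster,
    delayed_synchrony_matrix,
    find_hubs,
    hub_coefficient,
    network_overlap,
    pairwise_delay,
    select_significant_edges,
    simulate_raster,
    standard_mea,
)
from meanet.geometry import MEAGeometry


def _graph(vertices, edges) -> FunctionalGraph:
    g = nx.DiGraph()
    g.add_nodes_from(vertices)
    g.add_edges_from(edges, weight=1.0)
    return FunctionalGraph(g)


def _brute_force_matrix(raster, geometry, velocity, delta_ms):
    """Exhaustive pair-scan oracle with the same one-claim-per-target rule."""
    channels = geometry.electrode_ids
    n = len(channels)
    dist = geometry.distance_matrix()
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            src = raster.channel_times(channels[i])
            tgt = raster.channel_times(channels[j])
            if tgt.size == 0:
                continue
            tau = dist[i, j] / velocity * 1e-3
            half = delta_ms * 1e-3 / 2.0
            claimed = set()
            count = 0
            for s in src:
                for k in range(tgt.size):  # earliest unclaimed in-window target
                    if k in claimed:
                        continue
                    if tgt[k] < s + tau - half:
                        continue
                    if tgt[k] > s + tau + half:
                        break
                    claimed.add(k)
                    count += 1
                    break
            C[i, j] = count / tgt.size
    return C


class TestPairwiseDelay:
    def test_values_and_symmetry(self, geom):
        tau = pairwise_delay(geom, velocity=200.0)
        assert np.all(np.diag(tau) == 0.0)
        i, j = geom.index_of(22), geom.index_of(23)  # grid neighbours, 200 um
        assert tau[i, j] == pytest.approx(1.0)
        assert np.allclose(tau, tau.T)
        # triangle inequality over the full 59-electrode grid:
        # tau[i,k] + tau[k,j] >= tau[i,j]
        assert np.all(tau[:, :, None] + tau[None, :, :] >= tau[:, None, :] - 1e-9)

    def test_invalid_velocity(self, geom):
        with pytest.raises(ValueError):
            pairwise_delay(geom, velocity=0.0)


class TestDelayedSynchronyMatrix:
    def test_perfect_transmission_gives_unit_coefficient(self, geom):
        sub = MEAGeometry(geom.electrode_ids[:2], geom.positions[:2])
        rng = np.random.default_rng(0)
        src = np.sort(rng.uniform(0, 9, 40))
        tau = 200.0 / 300.0 * 1e-3
        raster = SpikeRaster(
            {sub.electrode_ids[0]: src, sub.electrode_ids[1]: src + tau},
            duration=10.0, geometry=sub,
        )
        cm = delayed_synchrony_matrix(raster)
        assert cm.C[0, 1] == pytest.approx(1.0)

    def test_silent_target_flagged(self, geom):
        sub = MEAGeometry(geom.electrode_ids[:2], geom.positions[:2])
        raster = SpikeRaster(
            {sub.electrode_ids[0]: np.array([1.0, 2.0]),
             sub.electrode_ids[1]: np.array([])},
            duration=5.0, geometry=sub,
        )
        cm = delayed_synchrony_matrix(raster)
        assert cm.C[0, 1] == 0.0
        assert sub.electrode_ids[1] in cm.undefined_targets

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n_spikes=st.integers(1, 60))
    def test_matches_brute_force_oracle(self, geom, seed, n_spikes):
        sub = MEAGeometry(geom.electrode_ids[:4], geom.positions[:4])
        rng = np.random.default_rng(seed)
        raster = SpikeRaster(
            {ch: np.sort(rng.uniform(0.0, 0.5, rng.integers(0, n_spikes)))
             for ch in sub.electrode_ids},
            duration=0.5, geometry=sub,
        )
        cm = delayed_synchrony_matrix(raster, velocity=300.0, delta_ms=5.0)
        oracle = _brute_force_matrix(raster, sub, 300.0, 5.0)
        assert np.allclose(cm.C, oracle)

    def test_coefficients_bounded(self):
        raster, _ = simulate_raster(RasterSimConfig(duration=30.0, seed=23))
        cm = delayed_synchrony_matrix(raster)
        assert np.all(cm.C >= 0.0) and np.all(cm.C <= 1.0)
        assert np.all(cm.n_synchr <= cm.n_post[None, :])


class TestEdgeSelection:
    def test_five_percent_of_admissible_pairs(self, rng):
        channels = tuple(standard_mea().electrode_ids)
        n = len(channels)
        C = rng.uniform(0.01, 1.0, (n, n))
        np.fill_diagonal(C, 0.0)
        cm = ConnectivityMatrix(channels, C, np.zeros((n, n), int),
                                np.full(n, 10), np.zeros((n, n)), 2.0)
        fg = select_significant_edges(cm, fraction=0.05)
        assert fg.n_edges == int(np.floor(0.05 * n * (n - 1)))  # 171

    def test_selection_deterministic_under_ties(self):
        channels = (1, 2, 3, 4)
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 0.0)
        cm = ConnectivityMatrix(channels, C, np.zeros((4, 4), int),
                                np.full(4, 5), np.zeros((4, 4)), 2.0)
        e1 = select_significant_edges(cm, fraction=0.3).edges
        e2 = select_significant_edges(cm, fraction=0.3).edges
        assert e1 == e2 == {(1, 2), (1, 3), (1, 4)}

    def test_zero_matrix_empty_graph(self):
        channels = (1, 2, 3)
        cm = ConnectivityMatrix(channels, np.zeros((3, 3)), np.zeros((3, 3), int),
                                np.zeros(3, int), np.zeros((3, 3)), 2.0)
        assert select_significant_edges(cm).n_edges == 0

    def test_cut_of_zero_edges(self):
        channels = (1, 2, 3)
        C = np.ones((3, 3)) - np.eye(3)
        cm = ConnectivityMatrix(channels, C, np.zeros((3, 3), int),
                                np.full(3, 5), np.zeros((3, 3)), 2.0)
        assert select_significant_edges(cm, fraction=0.1).n_edges == 0


class TestHubs:
    def test_empty_graph_no_hubs(self):
        assert find_hubs(_graph([1, 2, 3], [])).n_hubs == 0

    def test_star_graph_center(self):
        edges = [(0, k) for k in range(1, 13)]
        hubs = find_hubs(_graph(range(13), edges), min_degree=10)
        assert hubs.hub_ids == (0,)
        assert hubs.connections_per_hub[0] == 12
        assert hubs.mean_connections_per_hub == 12.0

    def test_hub_coefficient_values(self):
        edges = [(0, k) for k in range(1, 6)]
        fg = _graph(range(7), edges)
        assert hub_coefficient(fg, 0) == pytest.approx(1.0)  # star centre
        assert hub_coefficient(fg, 6) == 0.0  # isolated vertex
        assert hub_coefficient(fg, 1) == pytest.approx(1 / 5)

    def test_hub_coefficient_matches_degree_ratio_on_random_graph(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=5, directed=True)
        fg = FunctionalGraph(g)
        for v in fg.vertices:
            expected = (g.in_degree(v) + g.out_degree(v)) / g.number_of_edges()
            assert hub_coefficient(fg, v) == pytest.approx(expected)

    def test_zero_edge_graph_rejected(self):
        with pytest.raises(ValueError):
            hub_coefficient(_graph([1, 2], []), 1)

    def test_planted_hub_recovery(self):
        # desynchronized background, jittered transmission: the regime where
        # the top-5% rule separates planted hubs from chance structure
        planted = {33, 55, 77}
        tp = fp = fn = 0
        for s in range(10):
            cfg = RasterSimConfig(
                duration=300.0, background_rate=5.0, burst_rate=0.0,
                hub_ids=tuple(planted), hub_out_degree=18,
                propagation_probability=0.5, jitter_sd=2.0, seed=s,
            )
            raster, _ = simulate_raster(cfg)
            cm = delayed_synchrony_matrix(raster)
            fg = select_significant_edges(cm)
            found = set(find_hubs(fg, min_degree=15).hub_ids)
            tp += len(found & planted)
            fp += len(found - planted)
            fn += len(planted - found)
        assert tp / (tp + fn) >= 0.9  # recall
        assert tp / (tp + fp) >= 0.9  # precision


class TestNetworkOverlap:
    def test_identical_graphs_full_overlap(self):
        fg = _graph(range(5), [(0, 1), (1, 2), (3, 4)])
        assert network_overlap(fg, fg) == 100.0

    def test_disjoint_graphs_zero_overlap(self):
        g1 = _graph(range(5), [(0, 1), (1, 2)])
        g2 = _graph(range(5), [(2, 3), (3, 4)])
        assert network_overlap(g1, g2) == 0.0

    def test_known_shared_fraction(self, rng):
        pairs = [(i, j) for i in range(10) for j in range(10) if i != j]
        rng.shuffle(pairs)
        shared, only1, only2 = pairs[:30], pairs[30:50], pairs[50:70]
        g1 = _graph(range(10), shared + only1)
        g2 = _graph(range(10), shared + only2)
        assert network_overlap(g1, g2) == pytest.approx(100.0 * 30 / 50)

    def test_random_graphs_overlap_near_chance(self, rng):
        # two independent 171-edge graphs share ~5% of edges by chance
        channels = list(range(59))
        pairs = [(i, j) for i in channels for j in channels if i != j]
        overlaps = []
        for s in range(20):
            r = np.random.default_rng(s)
            e1 = [pairs[k] for k in r.choice(len(pairs), 171, replace=False)]
            e2 = [pairs[k] for k in r.choice(len(pairs), 171, replace=False)]
            overlaps.append(network_overlap(_graph(channels, e1),
                                            _graph(channels, e2)))
        assert abs(np.mean(overlaps) - 5.0) < 1.5

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            network_overlap(_graph([1, 2], []), _graph([1, 2], [(1, 2)]))

    def test_vertex_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            network_overlap(_graph([1, 2], [(1, 2)]), _graph([1, 3], [(1, 3)]))
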
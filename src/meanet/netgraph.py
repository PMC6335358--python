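"""Delayed-synchrony functional connectivity and hub analysis.

For every ordered electrode pair (i, j) the coefficient

    C_ij = n_synchr,ij / n_j

is the fraction of j's spikes that are "delayed synchronous" with a spike
on i: a j-spike counts when it falls within a tolerance window of width
delta centred on the i-spike time plus the axonal delay tau_ij, where
tau_ij is the inter-electrode distance divided by the conduction velocity.
Each j-spike can be claimed by at most one i-spike (greedy, in time order),
which bounds C_ij by 1.  The functional graph keeps the largest 5% of the
off-diagonal coefficients as directed edges; hubs are electrodes carrying
at least ``min_degree`` connections, and the hub coefficient of an
electrode is its connection count divided by the total number of
connections in the graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .geometry import MEAGeometry
from .spikes import SpikeRaster

__all__ = [
    "ConnectivityMatrix",
    "FunctionalGraph",
    "HubSet",
    "pairwise_delay",
    "delayed_synchrony_matrix",
    "select_significant_edges",
    "find_hubs",
    "hub_coefficient",
    "network_overlap",
]


@dataclass
class ConnectivityMatrix:
    """Pairwise delayed-synchrony coefficients for one recording.

    ``C[i, j]`` holds C_ij for the ordered pair (row = source, column =
    target) over ``channels``; the diagonal is excluded (zero).  Pairs whose
    target fired no spikes are reported as 0 and flagged in
    ``undefined_targets``.
    """

    channels: tuple[int, ...]
    C: np.ndarray
    n_synchr: np.ndarray
    n_post: np.ndarray
    delay_ms: np.ndarray
    delta_ms: float
    undefined_targets: tuple[int, ...] = ()

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class FunctionalGraph:
    """Directed graph of significant delayed-synchrony connections.

    Wraps a ``networkx.DiGraph`` whose nodes are all electrodes (including
    isolated ones) and whose edge weights are the retained C_ij values.
    Degrees use the total (in + out) convention throughout.
    """

    graph: nx.DiGraph

    @property
    def vertices(self) -> tuple[int, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> set[tuple[int, int]]:
        return set(self.graph.edges)

    def degree(self, electrode: int) -> int:
        return int(self.graph.in_degree(electrode) + self.graph.out_degree(electrode))


@dataclass
class HubSet:
    """Electrodes with a disproportionate number of functional connections."""

    hub_ids: tuple[int, ...]
    connections_per_hub: dict[int, int] = field(default_factory=dict)
    hub_coefficients: dict[int, float] = field(default_factory=dict)

    @property
    def n_hubs(self) -> int:
        return len(self.hub_ids)

    @property
    def mean_connections_per_hub(self) -> float:
        if not self.hub_ids:
            return 0.0
        return float(np.mean([self.connections_per_hub[h] for h in self.hub_ids]))


def pairwise_delay(geometry: MEAGeometry, velocity: float = 300.0) -> np.ndarray:
    """Axonal delay matrix tau_ij (ms) = distance(i, j) / velocity (um/ms)."""
    if velocity <= 0:
        raise ValueError("conduction velocity must be positive")
    return geometry.distance_matrix() / velocity


def _greedy_synchronous(
    source: np.ndarray, target: np.ndarray, tau_s: float, delta_s: float
) -> int:
    """Delayed-synchronous count with each target spike claimed at most once.

    Both arrays are sorted.  Sources are visited in time order and each
    claims the earliest unclaimed target spike inside
    ``[s + tau - delta/2, s + tau + delta/2]``.
    """
    if source.size == 0 or target.size == 0:
        return 0
    half = delta_s / 2.0
    lo = np.searchsorted(target, source + tau_s - half, side="left")
    hi = np.searchsorted(target, source + tau_s + half, side="right") - 1
    valid = np.flatnonzero(hi >= lo)
    count = 0
    next_free = 0  # smallest unclaimed target index
    for m in valid:
        k = max(int(lo[m]), next_free)
        if k <= hi[m]:
            count += 1
            next_free = k + 1
    return count


def delayed_synchrony_matrix(
    raster: SpikeRaster,
    geometry: MEAGeometry | None = None,
    velocity: float = 300.0,
    delta_ms: float = 2.0,
) -> ConnectivityMatrix:
    """Compute the full delayed-synchrony cross-correlation matrix.

    ``delta_ms`` is the tolerance window width and ``velocity`` (um/ms) sets
    the distance-proportional delays.  Channels absent from the raster are
    treated as silent; target channels with no spikes are flagged rather
    than raising.
    """
    if delta_ms <= 0:
        raise ValueError("tolerance delta must be positive")
    geometry = geometry if geometry is not None else raster.geometry
    if geometry is None:
        raise ValueError("a geometry is required (raster carries none)")
    channels = geometry.electrode_ids
    n = len(channels)
    delay_ms = pairwise_delay(geometry, velocity)
    delta_s = delta_ms * 1e-3
    spikes = [raster.channel_times(ch) for ch in channels]
    n_post = np.array([s.size for s in spikes])
    n_synchr = np.zeros((n, n), dtype=int)
    for i in range(n):
        if spikes[i].size == 0:
            continue
        for j in range(n):
            if i == j or n_post[j] == 0:
                continue
            n_synchr[i, j] = _greedy_synchronous(
                spikes[i], spikes[j], delay_ms[i, j] * 1e-3, delta_s
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(n_post[None, :] > 0, n_synchr / np.maximum(n_post[None, :], 1), 0.0)
    np.fill_diagonal(C, 0.0)
    undefined = tuple(ch for ch, c in zip(channels, n_post) if c == 0)
    return ConnectivityMatrix(
        channels=tuple(channels),
        C=C,
        n_synchr=n_synchr,
        n_post=n_post,
        delay_ms=delay_ms,
        delta_ms=delta_ms,
        undefined_targets=undefined,
    )


def select_significant_edges(
    cm: ConnectivityMatrix, fraction: float = 0.05
) -> FunctionalGraph:
    """Keep the largest ``fraction`` of off-diagonal coefficients as edges.

    Retains ``floor(fraction * n * (n - 1))`` ordered pairs with the highest
    C_ij; ties at the cut are broken by lexicographic (i, j) order so the
    selection is exactly reproducible.  Zero coefficients are never turned
    into edges, so an all-zero matrix yields an empty graph.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = cm.n_channels
    k = int(np.floor(fraction * n * (n - 1)))
    g = nx.DiGraph()
    g.add_nodes_from(cm.channels)
    if k > 0:
        i_idx, j_idx = np.where(~np.eye(n, dtype=bool))
        vals = cm.C[i_idx, j_idx]
        order = np.lexsort((j_idx, i_idx, -vals))
        taken = 0
        for m in order:
            if taken >= k or vals[m] <= 0.0:
                break
            g.add_edge(
                cm.channels[i_idx[m]], cm.channels[j_idx[m]], weight=float(vals[m])
            )
            taken += 1
    return FunctionalGraph(g)


def find_hubs(fg: FunctionalGraph, min_degree: int = 10) -> HubSet:
    """Electrodes whose total degree reaches ``min_degree``.

    The cutoff is a configurable operating point (the field reports hubs
    with on the order of 10-13 connections in mature cultures); hub
    coefficients are reported for every electrode of the graph.
    """
    total_edges = fg.n_edges
    degrees = {v: fg.degree(v) for v in fg.vertices}
    hubs = tuple(sorted(v for v, d in degrees.items() if d >= min_degree))
    coeffs = {
        v: (d / total_edges if total_edges else 0.0) for v, d in degrees.items()
    }
    return HubSet(
        hub_ids=hubs,
        connections_per_hub={h: degrees[h] for h in hubs},
        hub_coefficients=coeffs,
    )


def hub_coefficient(fg: FunctionalGraph, electrode: int) -> float:
    """Connections of ``electrode`` divided by all connections in the graph."""
    if fg.n_edges == 0:
        raise ValueError("hub coefficient is undefined on a graph with no edges")
    if electrode not in fg.graph:
        raise KeyError(f"electrode {electrode!r} is not a vertex of the graph")
    return fg.degree(electrode) / fg.n_edges


def network_overlap(g1: FunctionalGraph, g2: FunctionalGraph) -> float:
    """Percentage of g1's directed connections also present in g2.

    Measures how stable the functional network is between two recordings of
    the same culture; the earlier recording supplies the denominator.
    """
    if set(g1.vertices) != set(g2.vertices):
        raise ValueError("graphs must share one vertex set")
    if g1.n_edges == 0:
        raise ValueError("overlap is undefined for an empty reference graph")
    shared = g1.edges & g2.edges
    return 100.0 * len(shared) / g1.n_edges
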
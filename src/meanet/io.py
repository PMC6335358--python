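"""Readers and writers for every interchange format of the pipeline.

Small or toy data travel as CSV, voltage-scale data as HDF5, graphs as
GraphML (plus an edge-list CSV), statistics and ground truth as JSON.
Spike times are serialized as full-precision decimal text, so a write/read
round trip is bit-exact; every writer produces files its paired reader
accepts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .bursts import BurstStats, NetworkBurst
from .calcium import CalciumSummary, CalciumTransient, FluorescenceTrace
from .netgraph import ConnectivityMatrix, FunctionalGraph
from .spikes import SpikeRaster, VoltageRecording
from .synthgen import GroundTruth

__all__ = [
    "write_raster_csv",
    "read_raster_csv",
    "write_raster_hdf5",
    "read_raster_hdf5",
    "write_voltage_hdf5",
    "read_voltage_hdf5",
    "write_calcium_csv",
    "read_calcium_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_bursts_csv",
    "read_bursts_csv",
    "write_transients_csv",
    "write_stats_json",
    "write_connectivity",
    "read_connectivity",
    "write_graphml",
    "read_graphml",
    "write_edge_list_csv",
]


# ---------------------------------------------------------------------------
# spike rasters
# ---------------------------------------------------------------------------


def write_raster_csv(path: str | Path, raster: SpikeRaster) -> Path:
    """Columns ``channel_id, spike_time_s``; duration kept in a header comment."""
    path = Path(path)
    times, chans = raster.flatten()
    with open(path, "w") as fh:
        fh.write(f"# duration_s={raster.duration!r}\n")
        fh.write("channel_id,spike_time_s\n")
        for ch, t in zip(chans, times):
            fh.write(f"{int(ch)},{float(t)!r}\n")
    return path


def read_raster_csv(
    path: str | Path, duration: float | None = None, strict: bool = False
) -> SpikeRaster:
    """Read a raster CSV; malformed rows raise with their line number.

    Unsorted times are repaired with a warning, or rejected in strict mode;
    negative times always fail validation (named by line in strict mode).
    """
    path = Path(path)
    header_duration = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# duration_s="):
        header_duration = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if list(df.columns) != ["channel_id", "spike_time_s"]:
        raise ValueError(f"{path}: expected columns channel_id,spike_time_s")
    offset = 3 if header_duration is not None else 2  # 1-based first data line
    for pos, (ch, t) in enumerate(zip(df["channel_id"], df["spike_time_s"])):
        if pd.isna(ch) or pd.isna(t):
            raise ValueError(f"{path}: malformed row at line {pos + offset}")
        if strict and t < 0:
            raise ValueError(f"{path}: negative spike time at line {pos + offset}")
    dur = duration if duration is not None else header_duration
    if dur is None:
        dur = float(df["spike_time_s"].max()) + 1e-6 if len(df) else 1.0
    spikes: dict[int, np.ndarray] = {}
    for ch, group in df.groupby("channel_id"):
        t = group["spike_time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            if strict:
                raise ValueError(f"{path}: unsorted spike times on channel {ch}")
            warnings.warn(f"{path}: repairing unsorted times on channel {ch}",
                          stacklevel=2)
            t = np.sort(t)
        spikes[int(ch)] = t
    return SpikeRaster(spikes, duration=dur)


def write_raster_hdf5(path: str | Path, raster: SpikeRaster) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["duration_s"] = raster.duration
        grp = f.create_group("spikes")
        for ch, t in raster.spike_times.items():
            grp.create_dataset(str(ch), data=np.asarray(t, dtype=np.float64))
    return path


def read_raster_hdf5(path: str | Path) -> SpikeRaster:
    with h5py.File(path, "r") as f:
        duration = float(f.attrs["duration_s"])
        spikes = {int(ch): np.asarray(ds[()]) for ch, ds in f["spikes"].items()}
    return SpikeRaster(spikes, duration=duration)


# ---------------------------------------------------------------------------
# voltage
# ---------------------------------------------------------------------------


def write_voltage_hdf5(path: str | Path, recording: VoltageRecording) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage", data=recording.data.astype(np.float64))
        f.attrs["sample_rate_hz"] = recording.sample_rate
        f.attrs["channel_ids"] = np.asarray(recording.channel_ids, dtype=np.int64)
    return path


def read_voltage_hdf5(path: str | Path) -> VoltageRecording:
    with h5py.File(path, "r") as f:
        data = np.asarray(f["voltage"][()])
        rate = float(f.attrs["sample_rate_hz"])
        channels = tuple(int(c) for c in f.attrs["channel_ids"])
    return VoltageRecording(data, rate, channels)


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------


def write_calcium_csv(path: str | Path, traces: list[FluorescenceTrace]) -> Path:
    """One ``time_s`` column plus one ``roi_<id>`` column per trace."""
    if not traces:
        raise ValueError("no traces to write")
    path = Path(path)
    data = {"time_s": traces[0].times}
    for tr in traces:
        if tr.n_frames != traces[0].n_frames:
            raise ValueError("all traces must share one length")
        data[f"roi_{tr.roi_id}"] = tr.values
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_calcium_csv(path: str | Path) -> list[FluorescenceTrace]:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or len(df) < 2:
        raise ValueError(f"{path}: expected a time_s column and at least two rows")
    t = df["time_s"].to_numpy(dtype=float)
    frame_rate = 1.0 / float(np.median(np.diff(t)))
    traces = []
    for col in df.columns:
        if not col.startswith("roi_"):
            continue
        traces.append(
            FluorescenceTrace(
                df[col].to_numpy(dtype=float),
                frame_rate=frame_rate,
                roi_id=int(col[4:]),
                t0=float(t[0]),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# ground truth, bursts, transients, stats
# ---------------------------------------------------------------------------


def write_ground_truth_json(path: str | Path, truth: GroundTruth) -> Path:
    path = Path(path)
    payload = {
        "burst_intervals": [list(x) for x in truth.burst_intervals],
        "edges": [list(x) for x in truth.edges],
        "transient_events": {
            str(roi): [list(e) for e in ev] for roi, ev in truth.transient_events.items()
        },
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        burst_intervals=[(float(a), float(b), int(c))
                         for a, b, c in payload["burst_intervals"]],
        edges=[(int(a), int(b), float(p)) for a, b, p in payload["edges"]],
        transient_events={
            int(roi): [(float(a), float(b)) for a, b in ev]
            for roi, ev in payload["transient_events"].items()
        },
    )


def write_bursts_csv(path: str | Path, bursts: list[NetworkBurst]) -> Path:
    path = Path(path)
    rows = [
        {
            "start_s": b.start,
            "end_s": b.end,
            "n_spikes": b.n_spikes,
            "n_electrodes": b.n_electrodes,
            "peak_bin_spikes": b.peak_bin_spikes,
            "peak_bin_electrodes": b.peak_bin_electrodes,
            "size_class": b.size_class or "",
        }
        for b in bursts
    ]
    pd.DataFrame(rows, columns=[
        "start_s", "end_s", "n_spikes", "n_electrodes",
        "peak_bin_spikes", "peak_bin_electrodes", "size_class",
    ]).to_csv(path, index=False)
    return path


def read_bursts_csv(path: str | Path) -> list[NetworkBurst]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(
            NetworkBurst(
                start=float(r["start_s"]),
                end=float(r["end_s"]),
                n_spikes=int(r["n_spikes"]),
                n_electrodes=int(r["n_electrodes"]),
                peak_bin_spikes=int(r["peak_bin_spikes"]),
                peak_bin_electrodes=int(r["peak_bin_electrodes"]),
                size_class=(str(r["size_class"]) if pd.notna(r["size_class"]) and
                            str(r["size_class"]) else None),
            )
        )
    return out


def write_transients_csv(
    path: str | Path, transients: dict[int, list[CalciumTransient]]
) -> Path:
    path = Path(path)
    rows = [
        {"roi_id": roi, "start_s": tr.start, "end_s": tr.end,
         "duration_s": tr.duration, "peak_amplitude": tr.peak_amplitude}
        for roi, cell in sorted(transients.items())
        for tr in cell
    ]
    pd.DataFrame(rows, columns=["roi_id", "start_s", "end_s", "duration_s",
                                "peak_amplitude"]).to_csv(path, index=False)
    return path


def write_stats_json(path: str | Path, stats: BurstStats | CalciumSummary | dict) -> Path:
    path = Path(path)
    payload = dataclasses.asdict(stats) if dataclasses.is_dataclass(stats) else stats
    path.write_text(json.dumps(payload, indent=1))
    return path


# ---------------------------------------------------------------------------
# connectivity and graphs
# ---------------------------------------------------------------------------


def write_connectivity(path_csv: str | Path, cm: ConnectivityMatrix,
                       path_meta: str | Path | None = None) -> Path:
    """C matrix as a labelled CSV plus a JSON metadata sidecar."""
    path_csv = Path(path_csv)
    pd.DataFrame(cm.C, index=list(cm.channels), columns=list(cm.channels)).to_csv(
        path_csv
    )
    meta_path = Path(path_meta) if path_meta else path_csv.with_suffix(".json")
    meta = {
        "channels": list(cm.channels),
        "delta_ms": cm.delta_ms,
        "n_post": [int(x) for x in cm.n_post],
        "undefined_targets": list(cm.undefined_targets),
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return path_csv


def read_connectivity(path_csv: str | Path,
                      path_meta: str | Path | None = None) -> ConnectivityMatrix:
    path_csv = Path(path_csv)
    df = pd.read_csv(path_csv, index_col=0)
    meta_path = Path(path_meta) if path_meta else path_csv.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    channels = tuple(int(c) for c in meta["channels"])
    C = df.to_numpy(dtype=float)
    n_post = np.asarray(meta["n_post"], dtype=int)
    return ConnectivityMatrix(
        channels=channels,
        C=C,
        n_synchr=np.zeros_like(C, dtype=int),
        n_post=n_post,
        delay_ms=np.zeros_like(C),
        delta_ms=float(meta["delta_ms"]),
        undefined_targets=tuple(meta["undefined_targets"]),
    )


def write_graphml(path: str | Path, fg: FunctionalGraph) -> Path:
    path = Path(path)
    nx.write_graphml(fg.graph, path)
    return path


def read_graphml(path: str | Path) -> FunctionalGraph:
    g = nx.read_graphml(Path(path), node_type=int)
    return FunctionalGraph(nx.DiGraph(g))


def write_edge_list_csv(path: str | Path, fg: FunctionalGraph) -> Path:
    path = Path(path)
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", 1.0)}
        for u, v, d in fg.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)
    return path
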
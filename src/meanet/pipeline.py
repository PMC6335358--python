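"""End-to-end pipeline: configuration, execution, run manifest.

``run_pipeline`` chains the stages — optional simulation, spike detection,
burst detection/classification, functional-graph construction, calcium
analysis — writing every artifact plus a manifest with checksums.  The same
config and seed always produce identical outputs; no stage touches global
state, so several pipelines can run in one process.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import io as mio
from .bursts import burst_statistics, classify_bursts, compute_tsr, detect_network_bursts
from .calcium import detect_transients, summarize_calcium
from .netgraph import delayed_synchrony_matrix, find_hubs, select_significant_edges
from .spikes import detect_spikes
from .synthgen import CalciumSimConfig, RasterSimConfig, simulate_calcium, simulate_raster

__version__ = "0.1.0"

logger = logging.getLogger("meanet")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """All stage parameters of one reproducible run.

    Exactly one electrophysiology input may be given: ``simulate_raster``
    (a ``RasterSimConfig``) or ``raster_path``; likewise ``simulate_calcium``
    or ``calcium_path`` for the imaging side.  Stages without an input are
    skipped.  Round-trips losslessly through YAML; unknown keys are
    rejected on load.
    """

    seed: int = 0
    out_dir: str = "meanet_run"
    log_level: str = "INFO"
    # inputs
    simulate_raster: RasterSimConfig | None = None
    raster_path: str | None = None
    voltage_path: str | None = None
    simulate_calcium: CalciumSimConfig | None = None
    calcium_path: str | None = None
    # spike detection (applies when voltage_path is given)
    ns: float = 4.0
    refractory_ms: float = 1.0
    band: tuple[float, float] = (300.0, 8000.0)
    # bursts
    bin_width_ms: float = 50.0
    burst_threshold_coeff: float = 0.1
    min_spikes: int = 4
    min_electrodes: int = 4
    # graph
    delta_ms: float = 2.0
    velocity: float = 300.0
    edge_fraction: float = 0.05
    hub_min_degree: int = 10
    # calcium
    accuracy_coeff: float = 2.0


@dataclass
class RunManifest:
    """What a run produced: config snapshot, version, checksums, timestamps."""

    config: dict
    version: str = __version__
    started: str = ""
    finished: str = ""
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def verify(self, base: str | Path = ".") -> bool:
        base = Path(base)
        return all(
            _sha256(base / p) == digest for p, digest in self.artifacts.items()
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["band"] = list(config.band)
    return d


def save_config(path: str | Path, config: PipelineConfig) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False))
    return path


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys at every level."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw = dict(raw)
    for key, cls in (("simulate_raster", RasterSimConfig),
                     ("simulate_calcium", CalciumSimConfig)):
        sub = raw.get(key)
        if isinstance(sub, dict):
            sub_known = {f.name for f in dataclasses.fields(cls)}
            sub_unknown = set(sub) - sub_known
            if sub_unknown:
                raise ValueError(f"unknown {key} keys: {sorted(sub_unknown)}")
            if "hub_ids" in sub:
                sub = {**sub, "hub_ids": tuple(sub["hub_ids"])}
            raw[key] = cls(**sub)
    if "band" in raw and raw["band"] is not None:
        raw["band"] = tuple(raw["band"])
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every configured stage and write artifacts plus manifest.

    Raises with the failing stage named; a partial manifest listing the
    artifacts written so far is attached to the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=_config_to_dict(config),
        started=datetime.now(timezone.utc).isoformat(),
    )

    def record(path: Path) -> None:
        manifest.artifacts[str(path.relative_to(out))] = _sha256(path)

    stage = "setup"
    try:
        raster = None
        truth = None
        if config.simulate_raster is not None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.simulate_raster, seed=config.seed)
            logger.info("simulating raster (seed=%d)", config.seed)
            raster, truth = simulate_raster(sim_cfg)
            record(mio.write_raster_csv(out / "raster.csv", raster))
            record(mio.write_ground_truth_json(out / "ground_truth.json", truth))
        elif config.raster_path is not None:
            stage = "read-raster"
            raster = mio.read_raster_csv(config.raster_path)
        elif config.voltage_path is not None:
            stage = "detect-spikes"
            recording = mio.read_voltage_hdf5(config.voltage_path)
            logger.info("detecting spikes on %d channels", recording.n_channels)
            raster = detect_spikes(
                recording, ns=config.ns, refractory_ms=config.refractory_ms,
                band=config.band,
            )
            record(mio.write_raster_csv(out / "raster.csv", raster))

        if raster is not None:
            stage = "detect-bursts"
            logger.info("detecting network bursts")
            tsr = compute_tsr(raster, bin_width_ms=config.bin_width_ms)
            bursts = classify_bursts(
                detect_network_bursts(
                    tsr, raster,
                    threshold_coeff=config.burst_threshold_coeff,
                    min_spikes=config.min_spikes,
                    min_electrodes=config.min_electrodes,
                )
            )
            stats = burst_statistics(bursts, raster.duration)
            record(mio.write_bursts_csv(out / "bursts.csv", bursts))
            record(mio.write_stats_json(out / "burst_stats.json", stats))

            if raster.geometry is not None:
                stage = "build-graph"
                logger.info("building functional graph")
                cm = delayed_synchrony_matrix(
                    raster, velocity=config.velocity, delta_ms=config.delta_ms
                )
                fg = select_significant_edges(cm, fraction=config.edge_fraction)
                hubs = find_hubs(fg, min_degree=config.hub_min_degree)
                record(mio.write_connectivity(out / "connectivity.csv", cm))
                record(Path(out / "connectivity.json"))
                record(mio.write_graphml(out / "graph.graphml", fg))
                record(mio.write_edge_list_csv(out / "edges.csv", fg))
                record(mio.write_stats_json(out / "hubs.json", {
                    "hub_ids": list(hubs.hub_ids),
                    "n_hubs": hubs.n_hubs,
                    "mean_connections_per_hub": hubs.mean_connections_per_hub,
                    "connections_per_hub": {
                        str(k): v for k, v in hubs.connections_per_hub.items()
                    },
                }))

        traces = None
        if config.simulate_calcium is not None:
            stage = "simulate-calcium"
            sim_cfg = dataclasses.replace(config.simulate_calcium, seed=config.seed)
            logger.info("simulating calcium traces (seed=%d)", config.seed)
            traces, ca_truth = simulate_calcium(sim_cfg)
            record(mio.write_calcium_csv(out / "calcium.csv", traces))
            record(mio.write_ground_truth_json(out / "calcium_truth.json", ca_truth))
        elif config.calcium_path is not None:
            stage = "read-calcium"
            traces = mio.read_calcium_csv(config.calcium_path)

        if traces is not None:
            stage = "analyze-calcium"
            logger.info("detecting calcium transients on %d ROIs", len(traces))
            per_cell = {
                tr.roi_id: detect_transients(tr, accuracy_coeff=config.accuracy_coeff)
                for tr in traces
            }
            duration = traces[0].n_frames / traces[0].frame_rate
            summary = summarize_calcium(list(per_cell.values()), duration)
            record(mio.write_transients_csv(out / "transients.csv", per_cell))
            record(mio.write_stats_json(out / "calcium_summary.json", summary))
    except Exception as exc:
        manifest.finished = datetime.now(timezone.utc).isoformat()
        (out / "manifest.partial.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=1)
        )
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(dataclasses.asdict(manifest), indent=1))
    return manifest
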
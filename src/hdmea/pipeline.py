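"""End-to-end orchestration: configuration presets, stage execution,
result bundles and condition comparisons.

A :class:`PipelineConfig` fixes every tunable (preparation preset, stage
toggles, module parameters, seed); presets resolve to the per-preparation
high-pass cutoff and activity threshold used for each biological model:

=====================  ================  =====================
preset                 high-pass (Hz)    MFR threshold (Hz)
=====================  ================  =====================
cerebellum             50                0.5
cortico_hippocampal    10                0.1
pfc                    100               0.1
spheroid               (none)            0.1
organoid               (none)            0.5 (cortical)
organoid_spinal        (none)            0.1
=====================  ================  =====================

``run_pipeline`` executes simulate -> detect -> sort -> metrics -> bursts ->
connect according to the toggles, writing versioned CSV/JSON/GraphML outputs
plus a structured run log carrying the config hash and seed; identical
config and seed reproduce the outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn_mod
from . import metrics as metrics_mod
from . import spikes as spikes_mod
from . import store as store_mod
from . import synth as synth_mod
from .chip import ChipGeometry, electrode_position

__all__ = [
    "PipelineConfig",
    "PREPARATION_PRESETS",
    "run_pipeline",
    "compare_conditions",
    "trains_to_frame",
    "frame_to_trains",
]

#: preset -> (high-pass cutoff Hz or None, MFR threshold Hz)
PREPARATION_PRESETS: Dict[str, Tuple[Optional[float], float]] = {
    "cerebellum": (50.0, 0.5),
    "cortico_hippocampal": (10.0, 0.1),
    "pfc": (100.0, 0.1),
    "spheroid": (None, 0.1),
    "organoid": (None, 0.5),
    "organoid_spinal": (None, 0.1),
}

DEFAULT_STAGES = ("simulate", "detect", "sort", "metrics", "bursts", "connect")


@dataclass
class PipelineConfig:
    preparation_preset: str = "cerebellum"
    seed: int = 0
    stages: Tuple[str, ...] = DEFAULT_STAGES
    synth: Dict = field(default_factory=dict)
    detection: Dict = field(default_factory=dict)
    sorting: Dict = field(default_factory=dict)
    bursts: Dict = field(default_factory=dict)
    connectivity: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.preparation_preset not in PREPARATION_PRESETS:
            raise ValueError(
                f"unknown preparation preset {self.preparation_preset!r}; "
                f"expected one of {sorted(PREPARATION_PRESETS)}"
            )
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(DEFAULT_STAGES) - {"vsdi"}
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @property
    def highpass_cutoff_hz(self) -> Optional[float]:
        return PREPARATION_PRESETS[self.preparation_preset][0]

    @property
    def rate_threshold_hz(self) -> float:
        return PREPARATION_PRESETS[self.preparation_preset][1]

    def to_yaml(self) -> str:
        payload = asdict(self)
        payload["stages"] = list(self.stages)
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def trains_to_frame(units: Sequence[spikes_mod.UnitTrain]) -> pd.DataFrame:
    """Tidy (electrode, unit_id, spike_time_s) table of sorted trains."""
    rows = [
        (u.electrode, u.unit_id, t)
        for u in units
        for t in u.spike_times
    ]
    return pd.DataFrame(rows, columns=["electrode", "unit_id", "spike_time_s"])


def frame_to_trains(frame: pd.DataFrame) -> List[spikes_mod.UnitTrain]:
    units = []
    for (electrode, unit_id), grp in frame.groupby(["electrode", "unit_id"]):
        units.append(
            spikes_mod.UnitTrain(
                electrode=int(electrode),
                unit_id=int(unit_id),
                spike_times=np.sort(grp["spike_time_s"].to_numpy(float)),
            )
        )
    return units


def _default_scenario(config: PipelineConfig) -> synth_mod.GroundTruth:
    """Small standard scenario on an 8x8 sub-grid (fast, fully planted)."""
    params = dict(config.synth)
    n_units = int(params.get("n_units", 16))
    rate = float(params.get("rate_hz", 5.0))
    amplitude = float(params.get("amplitude_uv", 300.0))
    shape = float(params.get("isi_shape", 1.8))
    return synth_mod.GroundTruth(
        unit_rates=[rate] * n_units,
        unit_isi_shape=[shape] * n_units,
        amplitudes_uv=[amplitude] * n_units,
        electrodes=list(range(n_units)),
        seed=config.seed,
    )


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    out_dir: str,
    container_path: Optional[str] = None,
) -> Dict[str, object]:
    """Execute the configured stages and write a versioned result bundle.

    Returns a bundle dict with the unit-metrics table (``"units"``), the
    connectivity graph (``"graph"``, when the connect stage ran), summary
    counts (``"summary"``) and output paths.  Partial results are preserved
    on stage failure; the raised :class:`StageError` names the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_entries: List[dict] = []

    def log(stage: str, t0: float, **counts) -> None:
        entry = {"stage": stage, "wall_s": round(time.perf_counter() - t0, 3), **counts}
        log_entries.append(entry)
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    (out / "config.yaml").write_text(config.to_yaml())
    with open(log_path, "w") as fh:
        fh.write(
            json.dumps(
                {"config_hash": config.config_hash(), "seed": config.seed}
            )
            + "\n"
        )
    bundle: Dict[str, object] = {"paths": {"out_dir": str(out)}}
    geometry = ChipGeometry(
        n_rows=int(config.synth.get("n_rows", 8)),
        n_cols=int(config.synth.get("n_cols", 8)),
    )
    recording: Optional[store_mod.Recording] = None
    sidecar = None

    try:
        stage = "simulate"
        if container_path is not None:
            t0 = time.perf_counter()
            recording = store_mod.read_container(container_path)
            geometry = recording.geometry
            log("load", t0, channels=geometry.n_electrodes)
        elif "simulate" in config.stages:
            t0 = time.perf_counter()
            gt = _default_scenario(config)
            duration = float(config.synth.get("duration_s", 60.0))
            trains = synth_mod.generate_trains(gt, duration)
            raw = synth_mod.synthesize_raw(
                trains,
                geometry,
                gt,
                noise_sd_uv=float(config.synth.get("noise_sd_uv", 10.0)),
                duration=duration,
            )
            recording = store_mod.Recording(
                sampling_rate_hz=raw.sampling_rate_hz,
                geometry=geometry,
                voltage_uv=raw.voltage_uv,
            )
            sidecar = raw.sidecar
            store_mod.write_container(recording, str(out / "recording.h5"))
            bundle["paths"]["container"] = str(out / "recording.h5")
            log(stage, t0, units=gt.n_units, duration_s=duration)
        if recording is None:
            raise ValueError("no input: enable the simulate stage or pass a container")

        units: List[spikes_mod.UnitTrain] = []
        if recording.voltage_uv is not None and "detect" in config.stages:
            stage = "detect"
            t0 = time.perf_counter()
            voltage = recording.voltage_uv
            if config.highpass_cutoff_hz is not None:
                voltage = store_mod.highpass(
                    recording, config.highpass_cutoff_hz
                ).voltage_uv
            threshold = float(config.detection.get("threshold_uv", -100.0))
            refractory = float(config.detection.get("refractory_ms", 1.0))
            detected = {}
            for chan in range(voltage.shape[0]):
                times, snippets = spikes_mod.detect_threshold(
                    voltage[chan],
                    recording.sampling_rate_hz,
                    threshold_uv=threshold,
                    refractory_ms=refractory,
                )
                if times.size:
                    detected[chan] = (times, snippets)
            log(stage, t0, channels_with_spikes=len(detected))
            stage = "sort"
            t0 = time.perf_counter()
            for chan, (times, snippets) in detected.items():
                if "sort" in config.stages:
                    units.extend(
                        spikes_mod.sort_electrode(
                            snippets,
                            times,
                            electrode=chan,
                            seed=config.seed,
                            **config.sorting,
                        )
                    )
                else:
                    units.append(
                        spikes_mod.UnitTrain(
                            electrode=chan, unit_id=0,
                            spike_times=times, waveforms=snippets,
                        )
                    )
            if "sort" in config.stages:
                log(stage, t0, units=len(units))
        elif recording.rasters is not None:
            units = [
                spikes_mod.UnitTrain(electrode=chan, unit_id=0, spike_times=t)
                for chan, t in sorted(recording.rasters.items())
            ]

        duration = recording.duration_s
        epoch = (0.0, duration)
        active = [
            u
            for u in units
            if u.n_spikes / duration > config.rate_threshold_hz
        ]
        trains_frame = trains_to_frame(active)
        trains_frame.to_csv(out / "sorted_spikes.csv", index=False)
        bundle["paths"]["sorted_spikes"] = str(out / "sorted_spikes.csv")

        stage = "metrics"
        rows = []
        if "metrics" in config.stages or "bursts" in config.stages:
            t0 = time.perf_counter()
            for u in active:
                um = metrics_mod.unit_metrics(
                    u.spike_times, epoch, peak_to_peak_uv=u.peak_to_peak_uv
                )
                bs = metrics_mod.detect_bursts(
                    u.spike_times, duration, **config.bursts
                )
                rows.append(
                    {
                        "electrode": u.electrode,
                        "unit_id": u.unit_id,
                        "epoch": "all",
                        "mfr_hz": um.mfr_hz,
                        "cv": um.cv,
                        "cv2": um.cv2,
                        "peak_to_peak_uv": um.peak_to_peak_uv,
                        "burst_rate_per_min": bs.burst_rate_per_min,
                        "spikes_per_burst": bs.spikes_per_burst,
                        "burst_isi_iqr_ms": bs.isi_iqr_ms,
                    }
                )
            log(stage, t0, active_units=len(active))
        units_frame = pd.DataFrame(rows)
        units_frame.to_csv(out / "unit_metrics.csv", index=False, float_format="%.6f")
        bundle["units"] = units_frame
        bundle["paths"]["unit_metrics"] = str(out / "unit_metrics.csv")

        graph = None
        if "connect" in config.stages and len(active) >= 2:
            stage = "connect"
            t0 = time.perf_counter()
            positions = {
                i: electrode_position(geometry, u.electrode)
                for i, u in enumerate(active)
            }
            graph = conn_mod.call_links(
                [u.spike_times for u in active],
                positions_um=positions,
                seed=config.seed,
                **config.connectivity,
            )
            edges = pd.DataFrame(
                [
                    (l.source, l.target, l.correlation_value, l.lag_ms)
                    for l in graph.links
                ],
                columns=["source", "target", "value", "lag_ms"],
            )
            edges.to_csv(out / "links.csv", index=False, float_format="%.6f")
            graph.write_graphml(str(out / "links.graphml"))
            bundle["paths"]["links"] = str(out / "links.csv")
            log(
                stage,
                t0,
                links=graph.n_links,
                correlation_index=graph.correlation_index,
            )
        bundle["graph"] = graph

        summary = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_units_detected": len(units),
            "n_units_active": len(active),
            "correlation_index": (
                graph.correlation_index if graph is not None else None
            ),
        }
        if sidecar is not None:
            summary["n_planted_spikes"] = len(sidecar)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        bundle["summary"] = summary
        bundle["paths"]["summary"] = str(out / "summary.json")
        return bundle
    except StageError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise StageError(stage, exc) from exc


#: metrics averaged across units when comparing conditions
_COMPARE_METRICS = (
    "mfr_hz",
    "cv",
    "cv2",
    "peak_to_peak_uv",
    "burst_rate_per_min",
    "spikes_per_burst",
    "burst_isi_iqr_ms",
)


def compare_conditions(
    unit_tables: Sequence[pd.DataFrame], labels: Sequence[str]
) -> pd.DataFrame:
    """Per-metric before/after comparison across >= 2 result bundles.

    Each table is a unit-metrics frame from :func:`run_pipeline`; metrics
    are averaged over units per condition and percent changes are reported
    against the first condition.  Conditions with fewer than 3 units are
    flagged in the ``low_n`` column.
    """
    if len(unit_tables) < 2:
        raise ValueError("need at least two condition bundles to compare")
    if len(unit_tables) != len(labels):
        raise ValueError("one label per bundle required")
    for table in unit_tables:
        missing = set(_COMPARE_METRICS) - set(table.columns)
        if missing:
            raise ValueError(f"bundle schema mismatch; missing columns {sorted(missing)}")
    rows = []
    base = unit_tables[0]
    for metric in _COMPARE_METRICS:
        before = float(base[metric].mean())
        row = {"metric": metric, f"mean_{labels[0]}": before}
        for table, label in zip(unit_tables[1:], labels[1:]):
            after = float(table[metric].mean())
            row[f"mean_{label}"] = after
            if before == 0 or not np.isfinite(before) or not np.isfinite(after):
                row[f"pct_change_{label}"] = float("nan")
            else:
                row[f"pct_change_{label}"] = metrics_mod.percent_change(
                    before, after
                )
        row["low_n"] = any(len(t) < 3 for t in unit_tables)
        rows.append(row)
    return pd.DataFrame(rows)
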
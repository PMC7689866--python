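"""Reading and writing the package's on-disk formats.

Traces travel as a values CSV (``time_s,voltage_mV``) plus a JSON sidecar
(sampling rate, stimulus list, seed, ground-truth tables when synthetic).
Volumes travel as single-channel multi-page TIFF (ZYX page order) plus a
JSON sidecar with voxel sizes. Event tables are TSV, one row per event.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    CellInputs,
    ContactReport,
    EPSPEvent,
    Stimulus,
    TraceRecording,
    VoxelVolume,
)

__all__ = [
    "write_trace",
    "read_trace",
    "write_volume",
    "write_label_volume",
    "read_volume",
    "write_events_tsv",
    "read_events_tsv",
    "write_cell_json",
    "write_cohort_tsv",
    "write_contact_report",
    "jsonable",
]


def jsonable(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _sidecar_path(values_path: Path) -> Path:
    return values_path.with_suffix(".json")


def write_trace(trace: TraceRecording, csv_path) -> Path:
    """Write a trace as CSV plus JSON sidecar; returns the sidecar path."""
    csv_path = Path(csv_path)
    df = pd.DataFrame({"time_s": trace.time, "voltage_mV": trace.samples})
    df.to_csv(csv_path, index=False, float_format="%.6g")
    side = {
        "sampling_hz": trace.sampling_rate,
        "resting_potential_mV": trace.resting_potential,
        "stimuli": [{"time_s": s.time_s, "intensity_mA": s.intensity_mA} for s in trace.stimuli],
        "seed": trace.metadata.get("seed"),
        "metadata": jsonable(trace.metadata),
    }
    sidecar = _sidecar_path(csv_path)
    sidecar.write_text(json.dumps(side, indent=1))
    return sidecar


def read_trace(csv_path) -> TraceRecording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = json.loads(_sidecar_path(csv_path).read_text())
    return TraceRecording(
        samples=df["voltage_mV"].to_numpy(),
        sampling_rate=float(side["sampling_hz"]),
        stimuli=[Stimulus(s["time_s"], s["intensity_mA"]) for s in side.get("stimuli", [])],
        resting_potential=float(side.get("resting_potential_mV", -70.0)),
        metadata=side.get("metadata", {}),
    )


def write_volume(volume: VoxelVolume, tiff_path, extra: dict | None = None) -> Path:
    """Write a volume as multi-page TIFF (ZYX pages) + JSON sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(
        tiff_path,
        np.asarray(volume.intensities, dtype=np.float32),
        photometric="minisblack",
    )
    side = {
        "voxel_size_um_zyx": list(volume.voxel_size),
        "channel_name": volume.channel_name,
    }
    if extra:
        side.update(jsonable(extra))
    sidecar = _sidecar_path(tiff_path)
    sidecar.write_text(json.dumps(side, indent=1))
    return sidecar


def write_label_volume(labels: np.ndarray, voxel_size, tiff_path, extra: dict | None = None) -> Path:
    """Write a mask or label grid as compact integer TIFF (uint8 when the
    labels fit, else uint16) + JSON sidecar."""
    tiff_path = Path(tiff_path)
    labels = np.asarray(labels)
    dtype = np.uint8 if labels.max(initial=0) < 256 else np.uint16
    tifffile.imwrite(tiff_path, labels.astype(dtype), photometric="minisblack")
    side = {"voxel_size_um_zyx": list(voxel_size), "kind": "labels"}
    if extra:
        side.update(jsonable(extra))
    sidecar = _sidecar_path(tiff_path)
    sidecar.write_text(json.dumps(side, indent=1))
    return sidecar


def read_volume(tiff_path) -> VoxelVolume:
    tiff_path = Path(tiff_path)
    data = tifffile.imread(tiff_path)
    side = json.loads(_sidecar_path(tiff_path).read_text())
    return VoxelVolume(
        intensities=data,
        voxel_size=tuple(side["voxel_size_um_zyx"]),
        channel_name=side.get("channel_name", ""),
    )


_EVENT_COLS = [
    "onset_s",
    "rate_of_rise",
    "amplitude",
    "latency_ms",
    "evoked",
    "stimulus_intensity",
    "stimulus_index",
    "prespike_amplitude",
    "triggered_ap",
]


def write_events_tsv(events: list[EPSPEvent], path) -> None:
    rows = [{c: getattr(e, c) for c in _EVENT_COLS} for e in events]
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[EPSPEvent]:
    df = pd.read_csv(path, sep="\t")
    events = []
    for _, row in df.iterrows():
        kw = {}
        for c in _EVENT_COLS:
            v = row[c]
            if pd.isna(v):
                v = None
            elif c in ("evoked", "triggered_ap"):
                v = bool(v)
            elif c == "stimulus_index":
                v = int(v)
            kw[c] = v
        events.append(EPSPEvent(**kw))
    return events


def write_cell_json(cell: CellInputs, path) -> None:
    doc = {
        "cell_id": cell.cell_id,
        "age_days": cell.age,
        "competition_index": cell.competition_index,
        "inputs": [
            {
                "mean_ror_V_per_s": i.mean_ror,
                "ror_sd": i.ror_sd,
                "mean_latency_ms": i.mean_latency,
                "source": i.source,
                "strong": i.strong,
                "prespike": i.prespike,
                "prespike_amp_mV": i.prespike_amp,
                "p_ap": i.p_ap,
                "n_events": i.n_events,
                "recruitment_intensity_mA": i.recruitment_intensity,
            }
            for i in cell.inputs
        ],
    }
    Path(path).write_text(json.dumps(jsonable(doc), indent=1))


def write_cohort_tsv(records, path) -> None:
    """One row per cell (StructureFunctionRecord schema)."""
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


def write_contact_report(report: ContactReport, path) -> None:
    doc = {
        "cluster_contact_areas_um2": report.cluster_areas,
        "total_contact_area_um2": report.total_contact_area,
        "soma_surface_area_um2": report.soma_surface_area,
        "coverage_fraction": report.coverage_fraction,
        "largest_area_um2": report.largest_area,
        "second_largest_area_um2": report.second_largest_area,
        "contact_ratio": report.contact_ratio,
        "dilation_used_um": report.dilation_used,
    }
    Path(path).write_text(json.dumps(jsonable(doc), indent=1))
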
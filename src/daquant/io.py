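"""Readers and writers for the CSV/HDF5 dialects used across the pipeline.

Formats:
  spikes CSV    : neuron_id, spike_time_s
  features CSV  : neuron_id, group, triphasic, duration_ms, start_to_trough_ms, mean_rate_hz
  group CSV     : group, neuron_id, value
  trace CSV/H5  : time_s, f465, f405 (HDF5: same three datasets)
  events CSV    : event_time_s, label
  spines CSV    : dendrite_id, spine_id, head_diameter_nm[, head_volume_um3]
  segments CSV  : dendrite_id, length_um
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .photometry import PhotometryTrace
from .spikes import SpikeTrain, WaveformFeatures

__all__ = [
    "read_spikes_csv",
    "write_spikes_csv",
    "read_features_csv",
    "read_trace",
    "write_trace_csv",
    "write_trace_hdf5",
    "read_events_csv",
    "write_json_report",
]


def read_spikes_csv(path, duration_s: float) -> dict[str, SpikeTrain]:
    """Load per-neuron spike trains from a long-format CSV."""
    df = pd.read_csv(path)
    trains = {}
    for nid, sub in df.groupby("neuron_id", sort=True):
        times = np.sort(np.asarray(sub["spike_time_s"], dtype=float))
        trains[str(nid)] = SpikeTrain(str(nid), times, duration_s)
    return trains


def write_spikes_csv(path, trains: dict[str, SpikeTrain]) -> None:
    rows = [
        {"neuron_id": nid, "spike_time_s": t}
        for nid, train in trains.items()
        for t in train.spike_times_s
    ]
    pd.DataFrame(rows, columns=["neuron_id", "spike_time_s"]).to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    """Load waveform-feature rows; returns the table with parsed types."""
    df = pd.read_csv(path)
    df["triphasic"] = df["triphasic"].astype(bool)
    return df


def features_from_row(row) -> WaveformFeatures:
    return WaveformFeatures(
        triphasic=bool(row["triphasic"]),
        duration_ms=float(row["duration_ms"]),
        start_to_trough_ms=float(row["start_to_trough_ms"]),
        mean_rate_hz=float(row["mean_rate_hz"]),
    )


def read_trace(path, fs_hz: float | None = None) -> PhotometryTrace:
    """Load a dual-channel trace from CSV or HDF5 (by extension)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            t = np.asarray(f["time_s"])
            s465 = np.asarray(f["f465"])
            s405 = np.asarray(f["f405"])
    else:
        df = pd.read_csv(path)
        t = np.asarray(df["time_s"], dtype=float)
        s465 = np.asarray(df["f465"], dtype=float)
        s405 = np.asarray(df["f405"], dtype=float)
    if fs_hz is None:
        fs_hz = 1.0 / float(np.median(np.diff(t)))
    return PhotometryTrace(time_s=t, f465=s465, f405=s405, fs_hz=fs_hz)


def write_trace_csv(path, trace: PhotometryTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.time_s, "f465": trace.f465, "f405": trace.f405}
    ).to_csv(path, index=False)


def write_trace_hdf5(path, trace: PhotometryTrace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time_s", data=trace.time_s)
        f.create_dataset("f465", data=trace.f465)
        f.create_dataset("f405", data=trace.f405)


def read_events_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        df["label"] = "event"
    return df[["event_time_s", "label"]]


def write_json_report(path, report: dict) -> None:
    """Write a report deterministically (sorted keys, fixed separators)."""
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
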
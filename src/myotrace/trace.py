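"""The paced intracellular recording container and its on-disk dialect.

A recording is stored as a two-column CSV (``time_s``, ``voltage_mV``) plus a
JSON sidecar carrying ``patient_id``, ``location_id``, ``pacing_freq_hz``,
``stim_times_s`` and the generator ``seed`` (when synthetic).  Times are in
seconds from recording start with 0-based sample indexing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TraceRecording", "read_trace", "write_trace", "sidecar_path"]


@dataclass
class TraceRecording:
    """Sampled membrane potential with stimulation timestamps and pacing metadata."""

    samples: np.ndarray          # voltage, mV
    sampling_rate: float         # Hz
    stim_times: np.ndarray       # seconds from recording start
    pacing_freq: float           # Hz
    patient_id: str = ""
    location_id: str = ""
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.stim_times.size:
            if np.any(np.diff(self.stim_times) <= 0):
                raise ValueError("stim_times must be strictly increasing")
            if self.stim_times[0] < 0 or self.stim_times[-1] > self.duration_s:
                raise ValueError("stim_times must fall within the recording")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def index_of(self, t_s: float) -> int:
        """Nearest sample index for a time in seconds."""
        return int(round(t_s * self.sampling_rate))


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_trace(rec: TraceRecording, csv_path: str | Path) -> Path:
    """Write the two-column CSV and its JSON sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    df = pd.DataFrame({"time_s": rec.times_s, "voltage_mV": rec.samples})
    df.to_csv(csv_path, index=False, float_format="%.6f")
    sidecar = {
        "patient_id": rec.patient_id,
        "location_id": rec.location_id,
        "pacing_freq_hz": rec.pacing_freq,
        "stim_times_s": [float(t) for t in rec.stim_times],
        "seed": rec.seed,
        "sampling_rate_hz": rec.sampling_rate,
    }
    sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_trace(csv_path: str | Path) -> TraceRecording:
    """Read a trace CSV + JSON sidecar back into a :class:`TraceRecording`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if list(df.columns[:2]) != ["time_s", "voltage_mV"]:
        raise ValueError(
            f"{csv_path}: expected columns time_s,voltage_mV, got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{csv_path}: trace too short")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{csv_path}: time column is not strictly increasing")
    meta = json.loads(sidecar_path(csv_path).read_text())
    fs = meta.get("sampling_rate_hz") or 1.0 / float(np.median(dt))
    return TraceRecording(
        samples=df["voltage_mV"].to_numpy(),
        sampling_rate=float(fs),
        stim_times=np.asarray(meta["stim_times_s"], dtype=float),
        pacing_freq=float(meta["pacing_freq_hz"]),
        patient_id=str(meta.get("patient_id", "")),
        location_id=str(meta.get("location_id", "")),
        seed=meta.get("seed"),
    )
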
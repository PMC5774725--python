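"""In-memory containers and plain-text IO for MCG time series.

A recording is stored as a delimited text matrix (column 1 = time in
seconds, remaining columns = channels in pT) with a JSON sidecar carrying
the sampling rate, sensor coordinates and provenance.  An averaged beat
uses the same layout with time in ms relative to the R peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import SensorGeometry


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


@dataclass
class McgRecording:
    """Multichannel magnetic time series in pT.

    ``channels`` is (n_channels, n_samples); channel order matches
    ``geometry.positions``.
    """

    sampling_rate: float
    channels: np.ndarray
    geometry: SensorGeometry
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2:
            raise ValueError("channels must be a 2D (n_channels, n_samples) array")
        if self.channels.shape[0] != self.geometry.n_channels:
            raise ValueError(
                f"channel count {self.channels.shape[0]} does not match geometry "
                f"({self.geometry.n_channels} sensors)"
            )

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, channels: np.ndarray) -> "McgRecording":
        return McgRecording(self.sampling_rate, channels, self.geometry, dict(self.metadata))


@dataclass
class AveragedBeat:
    """Beat-ensemble-averaged waveform on a time axis relative to the R peak.

    ``time_ms`` must contain 0 (the R peak sample); ``snr`` is the ratio of
    the R amplitude on the maximal channel to the pre-Q baseline SD and may
    be ``inf`` for noiseless input.
    """

    time_ms: np.ndarray
    channels: np.ndarray
    geometry: SensorGeometry
    n_beats_averaged: int = 1
    snr: float = float("inf")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.shape != (self.geometry.n_channels, self.time_ms.size):
            raise ValueError("channels must be (n_channels, n_times) matching geometry/time axis")
        if self.n_beats_averaged < 1:
            raise ValueError("n_beats_averaged must be >= 1")
        if np.min(np.abs(self.time_ms)) > 1e-9:
            raise ValueError("time axis must contain 0 (the R peak)")

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / float(np.median(np.diff(self.time_ms)))

    @property
    def r_index(self) -> int:
        return int(np.argmin(np.abs(self.time_ms)))

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        return int(np.argmin(np.abs(self.time_ms - t_ms)))


def write_recording(recording: McgRecording, path: str | Path) -> None:
    """Write a recording as delimited text plus a JSON sidecar."""
    path = Path(path)
    data = np.column_stack([recording.time_s, recording.channels.T])
    header = "time_s," + ",".join(f"ch{i:02d}" for i in range(recording.n_channels))
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.6g")
    sidecar = {
        "sampling_rate_hz": recording.sampling_rate,
        "sensor_positions_m": recording.geometry.positions.tolist(),
        "metadata": recording.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_recording(path: str | Path, geometry: SensorGeometry | None = None) -> McgRecording:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    sidecar = json.loads(_sidecar_path(path).read_text())
    if geometry is None:
        geometry = SensorGeometry(np.asarray(sidecar["sensor_positions_m"], dtype=float))
    return McgRecording(
        sampling_rate=float(sidecar["sampling_rate_hz"]),
        channels=data[:, 1:].T,
        geometry=geometry,
        metadata=sidecar.get("metadata", {}),
    )


def write_beat(beat: AveragedBeat, path: str | Path) -> None:
    path = Path(path)
    data = np.column_stack([beat.time_ms, beat.channels.T])
    header = "time_ms," + ",".join(f"ch{i:02d}" for i in range(beat.channels.shape[0]))
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.8g")
    sidecar = {
        "n_beats_averaged": beat.n_beats_averaged,
        "snr": None if np.isinf(beat.snr) else beat.snr,
        "sensor_positions_m": beat.geometry.positions.tolist(),
        "metadata": beat.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_beat(path: str | Path, geometry: SensorGeometry | None = None) -> AveragedBeat:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    sidecar = json.loads(_sidecar_path(path).read_text())
    if geometry is None:
        geometry = SensorGeometry(np.asarray(sidecar["sensor_positions_m"], dtype=float))
    snr = sidecar.get("snr")
    return AveragedBeat(
        time_ms=data[:, 0],
        channels=data[:, 1:].T,
        geometry=geometry,
        n_beats_averaged=int(sidecar.get("n_beats_averaged", 1)),
        snr=float("inf") if snr is None else float(snr),
        metadata=sidecar.get("metadata", {}),
    )
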
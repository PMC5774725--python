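"""Sensor-array geometry for planar MCG measurements.

The measurement plane is parallel to the chest wall: x runs from the
subject's right to left, y from feet to head, z points away from the chest
(sources sit at negative z).  Positions are in meters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class SensorGeometry:
    """Positions of the sensing channels of a planar magnetometer array.

    Parameters
    ----------
    positions : (n_channels, 3) array
        Sensor coordinates in meters.  All default factories place sensors
        on the z = 0 plane.
    """

    positions: np.ndarray
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if pos.shape[0] < 1:
            raise ValueError("geometry needs at least one sensor")
        # distinctness: any coincident pair makes interpolation singular
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.any(d < 1e-9):
            raise ValueError("sensor positions must be distinct")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def xy(self) -> np.ndarray:
        """In-plane sensor coordinates, shape (n, 2), meters."""
        return self.positions[:, :2]

    def rotated(self, angle_deg: float) -> "SensorGeometry":
        """Geometry rotated counterclockwise about the z axis."""
        a = np.radians(angle_deg)
        rot = np.array(
            [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
        )
        return SensorGeometry(self.positions @ rot.T, dict(self.metadata))

    def to_json(self, path: str | Path) -> None:
        payload = {"positions_m": self.positions.tolist(), "metadata": self.metadata}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SensorGeometry":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["positions_m"], dtype=float), payload.get("metadata", {}))


def planar_grid(
    n_side: int = 8, pitch_m: float = 0.025, center: tuple[float, float] = (0.0, 0.0)
) -> SensorGeometry:
    """Square planar sensor grid centered over the chest.

    The default (8 x 8 at 2.5 cm pitch, 17.5 cm span) matches the footprint
    of 64-channel clinical MCG arrays and is wide enough that both field
    poles of a ventricular source at 6-9 cm depth fall inside the sensor
    hull, where interpolation is reliable.
    """
    if n_side < 2:
        raise ValueError("grid needs at least 2 sensors per side")
    coords = (np.arange(n_side) - (n_side - 1) / 2.0) * pitch_m
    gx, gy = np.meshgrid(coords + center[0], coords + center[1])
    pos = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n_side * n_side)])
    return SensorGeometry(pos, {"layout": f"{n_side}x{n_side}", "pitch_m": pitch_m})
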
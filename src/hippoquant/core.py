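"""Shared containers for the open-field / spike-train analyses.

The arena geometry, position tracking and spike-time containers are used by
both the synthetic-data generators and the rate-map analysis, so they live
here rather than in either module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ArenaConfig",
    "Trajectory",
    "SpikeTrain",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_spikes_csv",
    "write_spikes_csv",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Square open-field arena discretized into an n x n bin grid.

    Parameters
    ----------
    side_length : float
        Arena side in cm.  The default of 50 cm makes the default 15 x 15
        grid produce bins of (50/15)^2 ~ 11.1 cm^2.
    n_bins_per_side : int
        Number of spatial bins along each side.
    dt : float
        Position-tracking sample interval in seconds.
    """

    side_length: float = 50.0
    n_bins_per_side: int = 15
    dt: float = 0.025

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.n_bins_per_side < 2:
            raise ValueError("n_bins_per_side must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def bin_width(self) -> float:
        """Bin side length in cm."""
        return self.side_length / self.n_bins_per_side

    @property
    def bin_area(self) -> float:
        """Bin area in cm^2."""
        return self.bin_width**2

    @property
    def bin_edges(self) -> np.ndarray:
        """Bin edges in cm, length ``n_bins_per_side + 1``."""
        return np.linspace(0.0, self.side_length, self.n_bins_per_side + 1)


@dataclass
class Trajectory:
    """Time-stamped 2-D position track.

    ``t`` must be strictly increasing; ``x``/``y`` are in cm.  When an
    :class:`ArenaConfig` is attached, positions are validated to lie within
    ``[0, side_length]``.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena: ArenaConfig | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shapes")
        if self.t.ndim != 1:
            raise ValueError("trajectory arrays must be 1-D")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if self.arena is not None:
            side = self.arena.side_length
            if self.x.size and (
                self.x.min() < 0 or self.x.max() > side
                or self.y.min() < 0 or self.y.max() > side
            ):
                raise ValueError("positions outside the arena")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Time span covered, in seconds."""
        return float(self.t[-1] - self.t[0]) if self.t.size >= 2 else 0.0


@dataclass
class SpikeTrain:
    """Sorted spike times (s) for one unit."""

    unit_id: str
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size >= 2 and not np.all(
            np.diff(self.spike_times) > 0
        ):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.spike_times.size


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": traj.t, "x_cm": traj.x, "y_cm": traj.y}
    ).to_csv(path, index=False)


def read_trajectory_csv(
    path: str | Path, arena: ArenaConfig | None = None
) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        t=df["time_s"].to_numpy(),
        x=df["x_cm"].to_numpy(),
        y=df["y_cm"].to_numpy(),
        arena=arena,
    )


def write_spikes_csv(trains: list[SpikeTrain], path: str | Path) -> None:
    rows = [
        {"unit_id": tr.unit_id, "spike_time_s": s}
        for tr in trains
        for s in tr.spike_times
    ]
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(
        path, index=False
    )


def read_spikes_csv(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        trains.append(
            SpikeTrain(
                unit_id=str(uid),
                spike_times=np.sort(grp["spike_time_s"].to_numpy()),
            )
        )
    return trains
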
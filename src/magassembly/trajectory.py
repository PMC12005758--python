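"""Time-stamped simulation snapshots and their CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SpheroidPopulation

__all__ = ["Snapshot", "Trajectory", "write_trajectory", "read_trajectory"]

_COLUMNS = [
    "time", "id", "x", "y", "z", "r", "vx", "vy", "vz", "n_np",
    "fmag_x", "fmag_y", "fmag_z",
    "fgrav_x", "fgrav_y", "fgrav_z",
    "fhertz_x", "fhertz_y", "fhertz_z",
]


@dataclass
class Snapshot:
    """State of every spheroid at one output time, with the body-force
    decomposition evaluated at that state."""

    time: float
    positions: np.ndarray
    velocities: np.ndarray
    radii: np.ndarray
    np_counts: np.ndarray
    F_mag: np.ndarray = None
    F_grav: np.ndarray = None
    F_hertz: np.ndarray = None

    def __post_init__(self) -> None:
        n = self.radii.shape[0]
        for name in ("F_mag", "F_grav", "F_hertz"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros((n, 3)))

    @property
    def n(self) -> int:
        return self.radii.shape[0]

    def as_population(self) -> SpheroidPopulation:
        return SpheroidPopulation(
            self.positions.copy(), self.radii.copy(),
            self.np_counts.copy(), self.velocities.copy(),
        )


@dataclass
class Trajectory:
    """Ordered snapshots at multiples of the output interval."""

    snapshots: list[Snapshot] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        times = self.times
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    def __len__(self) -> int:
        return len(self.snapshots)

    def __getitem__(self, k) -> Snapshot:
        return self.snapshots[k]

    def append(self, snap: Snapshot) -> None:
        if self.snapshots and snap.time <= self.snapshots[-1].time:
            raise ValueError("snapshot times must be strictly increasing")
        self.snapshots.append(snap)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """One CSV row per spheroid per snapshot, full float precision."""
    traj.validate()
    frames = []
    for s in traj.snapshots:
        n = s.n
        frames.append(
            pd.DataFrame(
                {
                    "time": np.full(n, s.time),
                    "id": np.arange(n),
                    "x": s.positions[:, 0], "y": s.positions[:, 1], "z": s.positions[:, 2],
                    "r": s.radii,
                    "vx": s.velocities[:, 0], "vy": s.velocities[:, 1], "vz": s.velocities[:, 2],
                    "n_np": s.np_counts,
                    "fmag_x": s.F_mag[:, 0], "fmag_y": s.F_mag[:, 1], "fmag_z": s.F_mag[:, 2],
                    "fgrav_x": s.F_grav[:, 0], "fgrav_y": s.F_grav[:, 1], "fgrav_z": s.F_grav[:, 2],
                    "fhertz_x": s.F_hertz[:, 0], "fhertz_y": s.F_hertz[:, 1], "fhertz_z": s.F_hertz[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_trajectory(path: str | Path) -> Trajectory:
    """Inverse of :func:`write_trajectory`; validates columns and times."""
    # the default pandas float parser is fast but lossy; exact parsing keeps
    # the write/read cycle an identity at full float64 precision
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    times = df["time"].to_numpy()
    # rows must arrive grouped by snapshot in time order
    boundaries = np.flatnonzero(np.diff(times) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    snap_times = times[starts]
    if np.any(np.diff(snap_times) <= 0):
        raise ValueError("snapshot times must be strictly increasing")
    snaps = []
    for t, grp in df.groupby("time", sort=True):
        grp = grp.sort_values("id")
        snaps.append(
            Snapshot(
                time=float(t),
                positions=grp[["x", "y", "z"]].to_numpy(),
                velocities=grp[["vx", "vy", "vz"]].to_numpy(),
                radii=grp["r"].to_numpy(),
                np_counts=grp["n_np"].to_numpy(),
                F_mag=grp[["fmag_x", "fmag_y", "fmag_z"]].to_numpy(),
                F_grav=grp[["fgrav_x", "fgrav_y", "fgrav_z"]].to_numpy(),
                F_hertz=grp[["fhertz_x", "fhertz_y", "fhertz_z"]].to_numpy(),
            )
        )
    return Trajectory(snaps)
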
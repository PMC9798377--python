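"""Trajectory containers and table I/O.

Trajectories are time-ordered 2D positions produced by particle-tracking
software (one row per detected spot). Internally every quantity is carried in
micrometers and seconds; unit conversion (pixels -> μm) happens only when a
file is read or written. Frame indices are 0-based integers, the time of frame
j is j·dt, and the duration of a trajectory of N positions is (N−1)·dt.

Two table dialects are supported:

* ``tracker_csv`` — header columns ``TRACK_ID, FRAME, POSITION_X, POSITION_Y``
  (extra columns are ignored), as exported by common spot-linking tools.
* ``xy_table`` — minimal ``id,frame,x,y`` CSV.

Gaps (missing frames inside a track, e.g. from gap-closing during linking)
are preserved as missing frames, never interpolated; downstream MSD code uses
true frame differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectoryEnsemble",
    "AcquisitionMetadata",
    "TrajectoryFormatError",
    "TrajectoryDataError",
    "read_trajectories",
    "write_trajectories",
    "subsample",
    "filter_min_duration",
    "estimate_drift",
    "subtract_drift",
]

TRACKER_COLUMNS = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"]
XY_COLUMNS = ["id", "frame", "x", "y"]


class TrajectoryFormatError(ValueError):
    """A trajectory table is missing required columns or uses an unknown format."""


class TrajectoryDataError(ValueError):
    """A trajectory table contains inconsistent rows (e.g. duplicate frames)."""


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Acquisition parameters of a tracking video.

    Parameters
    ----------
    fps
        Recording rate, frames per second.
    pixel_size
        Camera resolution, μm per pixel.
    source
        Free-text provenance (file name, video id, ...).
    """

    fps: float
    pixel_size: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")


@dataclass(frozen=True)
class Trajectory:
    """One particle trajectory: 2D positions at strictly increasing frames.

    Positions are in μm, ``dt`` (the frame interval, 1/fps) in seconds.
    Frames need not be contiguous — linking gaps stay as missing frames.
    """

    id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (len(frames) == len(x) == len(y)):
            raise ValueError("frames, x, y must have equal length")
        if len(frames) < 2:
            raise ValueError(f"trajectory {self.id!r} needs >= 2 positions")
        if np.any(np.diff(frames) <= 0):
            raise TrajectoryDataError(
                f"trajectory {self.id!r} has non-increasing frame indices"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError(f"trajectory {self.id!r} has non-finite positions")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_positions(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Trajectory duration (N−1)·dt in seconds, counting internal gaps."""
        return float(self.frames[-1] - self.frames[0]) * self.dt

    @property
    def times(self) -> np.ndarray:
        """Absolute times j·dt of each retained frame, seconds."""
        return self.frames * self.dt

    def positions(self) -> np.ndarray:
        """(N, 2) array of positions in μm."""
        return np.column_stack([self.x, self.y])

    def shifted(self, dx: float, dy: float) -> "Trajectory":
        return replace(self, x=self.x + dx, y=self.y + dy)


@dataclass
class TrajectoryEnsemble:
    """A set of trajectories sharing one acquisition (one video)."""

    trajectories: list[Trajectory]
    metadata: AcquisitionMetadata

    def __post_init__(self) -> None:
        ids = [t.id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate trajectory ids: {dupes}")
        dts = {t.dt for t in self.trajectories}
        if len(dts) > 1:
            raise ValueError(f"trajectories mix frame intervals: {sorted(dts)}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, key: int) -> Trajectory:
        return self.trajectories[key]

    @property
    def dt(self) -> float:
        if self.trajectories:
            return self.trajectories[0].dt
        return 1.0 / self.metadata.fps

    def map(self, fn) -> "TrajectoryEnsemble":
        return TrajectoryEnsemble([fn(t) for t in self.trajectories], self.metadata)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def _ensemble_from_table(
    df: pd.DataFrame, pixel_size: float, fps: float, units: str, source: str
) -> TrajectoryEnsemble:
    scale = pixel_size if units == "px" else 1.0
    dt = 1.0 / fps
    trajectories = []
    for track_id, group in df.groupby("id", sort=True):
        group = group.sort_values("frame")
        frames = group["frame"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) == 0):
            raise TrajectoryDataError(
                f"track {track_id!r} has duplicate frame indices"
            )
        if len(frames) < 2:
            continue  # singleton detections carry no displacement information
        trajectories.append(
            Trajectory(
                id=str(track_id),
                frames=frames,
                x=group["x"].to_numpy(dtype=float) * scale,
                y=group["y"].to_numpy(dtype=float) * scale,
                dt=dt,
            )
        )
    meta = AcquisitionMetadata(fps=fps, pixel_size=pixel_size, source=source)
    return TrajectoryEnsemble(trajectories, meta)


def read_trajectories(
    path: str | Path,
    format: str = "tracker_csv",
    *,
    pixel_size: float = 1.0,
    fps: float,
    units: str = "um",
) -> TrajectoryEnsemble:
    """Read a trajectory table into an ensemble.

    Parameters
    ----------
    path
        CSV file to read.
    format
        ``"tracker_csv"`` (TRACK_ID/FRAME/POSITION_X/POSITION_Y) or
        ``"xy_table"`` (id/frame/x/y).
    pixel_size
        μm per pixel; applied only when ``units="px"``.
    fps
        Recording rate (frames per second) of the video the table came from.
    units
        ``"um"`` if positions are already in μm, ``"px"`` if in pixels.
    """
    if units not in ("um", "px"):
        raise ValueError(f"units must be 'um' or 'px', got {units!r}")
    df = pd.read_csv(path)
    if format == "tracker_csv":
        missing = [c for c in TRACKER_COLUMNS if c not in df.columns]
        if missing:
            raise TrajectoryFormatError(
                f"{path}: missing tracker_csv columns {missing}"
            )
        df = df.rename(
            columns={
                "TRACK_ID": "id",
                "FRAME": "frame",
                "POSITION_X": "x",
                "POSITION_Y": "y",
            }
        )
    elif format == "xy_table":
        missing = [c for c in XY_COLUMNS if c not in df.columns]
        if missing:
            raise TrajectoryFormatError(f"{path}: missing xy_table columns {missing}")
    else:
        raise TrajectoryFormatError(f"unknown format {format!r}")
    return _ensemble_from_table(
        df[XY_COLUMNS], pixel_size, fps, units, source=str(path)
    )


def write_trajectories(
    ensemble: TrajectoryEnsemble, path: str | Path, format: str = "tracker_csv"
) -> None:
    """Write an ensemble as a trajectory table (always in μm)."""
    rows = {
        "id": np.concatenate([[t.id] * len(t) for t in ensemble])
        if len(ensemble)
        else np.array([], dtype=object),
        "frame": np.concatenate([t.frames for t in ensemble])
        if len(ensemble)
        else np.array([], dtype=np.int64),
        "x": np.concatenate([t.x for t in ensemble])
        if len(ensemble)
        else np.array([]),
        "y": np.concatenate([t.y for t in ensemble])
        if len(ensemble)
        else np.array([]),
    }
    df = pd.DataFrame(rows)
    if format == "tracker_csv":
        df = df.rename(
            columns={
                "id": "TRACK_ID",
                "frame": "FRAME",
                "x": "POSITION_X",
                "y": "POSITION_Y",
            }
        )
    elif format != "xy_table":
        raise TrajectoryFormatError(f"unknown format {format!r}")
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Ensemble transforms
# ---------------------------------------------------------------------------


def subsample(traj: Trajectory, factor: int) -> Trajectory:
    """Keep every ``factor``-th frame (starting at the first); dt grows by factor.

    Emulates recording the same motion at a lower frame rate.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return traj
    keep = (traj.frames - traj.frames[0]) % factor == 0
    if keep.sum() < 2:
        raise ValueError(
            f"subsampling by {factor} leaves {int(keep.sum())} positions "
            f"in trajectory {traj.id!r}"
        )
    return Trajectory(
        id=traj.id,
        frames=(traj.frames[keep] - traj.frames[0]) // factor,
        x=traj.x[keep],
        y=traj.y[keep],
        dt=traj.dt * factor,
    )


def subsample_ensemble(ensemble: TrajectoryEnsemble, factor: int) -> TrajectoryEnsemble:
    """Subsample every trajectory; drops tracks left with < 2 positions."""
    kept = []
    for t in ensemble:
        try:
            kept.append(subsample(t, factor))
        except ValueError:
            continue
    meta = replace(ensemble.metadata, fps=ensemble.metadata.fps / factor)
    return TrajectoryEnsemble(kept, meta)


def filter_min_duration(
    ensemble: TrajectoryEnsemble, min_s: float
) -> TrajectoryEnsemble:
    """Keep trajectories with duration (N−1)·dt ≥ ``min_s`` (boundary inclusive).

    Short trajectories give unreliable time-averaged MSDs; the analysis keeps
    only tracks at least as long as the analysis window.
    """
    if min_s < 0:
        raise ValueError(f"min_s must be >= 0, got {min_s}")
    kept = [t for t in ensemble if t.duration >= min_s or np.isclose(t.duration, min_s)]
    return TrajectoryEnsemble(kept, ensemble.metadata)


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------


def estimate_drift(ensemble: TrajectoryEnsemble) -> tuple[float, float]:
    """Estimate a constant stage-drift velocity (μm/s) for a whole video.

    The drift is the ensemble-mean single-frame displacement divided by dt,
    pooled over all consecutive position pairs of all trajectories (pairs
    spanning linking gaps are normalized by their true time separation).
    Particle diffusion averages out over the ensemble; a coherent drift of the
    stage or the cell does not.
    """
    if len(ensemble) == 0:
        raise ValueError("cannot estimate drift from an empty ensemble")
    vx_num = vy_num = t_den = 0.0
    n_steps = 0
    for t in ensemble:
        vx_num += t.x[-1] - t.x[0]
        vy_num += t.y[-1] - t.y[0]
        t_den += t.duration
        n_steps += len(t) - 1
    if len(ensemble) == 1 and n_steps < 50:
        warnings.warn(
            "drift estimated from a single short trajectory is ill-conditioned",
            stacklevel=2,
        )
    if t_den == 0:
        return (0.0, 0.0)
    return (vx_num / t_den, vy_num / t_den)


def subtract_drift(
    ensemble: TrajectoryEnsemble, drift: tuple[float, float] | None = None
) -> TrajectoryEnsemble:
    """Remove constant-velocity drift from every trajectory.

    If ``drift`` is None it is estimated with :func:`estimate_drift`. Position
    j is shifted by −drift·(t_j − t_0) so each trajectory keeps its starting
    point.
    """
    if drift is None:
        drift = estimate_drift(ensemble)
    vx, vy = drift

    def _correct(t: Trajectory) -> Trajectory:
        rel_t = (t.frames - t.frames[0]) * t.dt
        return replace(t, x=t.x - vx * rel_t, y=t.y - vy * rel_t)

    return ensemble.map(_correct)


def apply_drift(traj: Trajectory, drift: tuple[float, float]) -> Trajectory:
    """Shift position j by drift·(t_j − t_0); inverse of drift subtraction."""
    vx, vy = drift
    rel_t = (traj.frames - traj.frames[0]) * traj.dt
    return replace(traj, x=traj.x + vx * rel_t, y=traj.y + vy * rel_t)
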
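"""Nest-centred ant trajectories and tracking-table I/O.

Digitized video tracking yields per-frame pixel coordinates of the head tip
and the thorax midpoint.  This module calibrates those tables into
:class:`Trajectory` objects — nest at the origin, coordinates in cm, +x East,
+y North — and derives the step series (lengths and turning angles) that all
path metrics build on.

Frame gaps are rejected rather than interpolated: every downstream metric
assumes a constant inter-frame interval of 1/frame_rate seconds.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .angles import wrap_signed_rad
from .errors import DataError, FormatError, InsufficientDataError

TRACKING_COLUMNS = ["frame", "head_x", "head_y", "thorax_x", "thorax_y"]
CANONICAL_COLUMNS = ["t", "head_x_cm", "head_y_cm", "thorax_x_cm", "thorax_y_cm"]

DEFAULT_FRAME_RATE = 25.0


@dataclass(frozen=True)
class Trajectory:
    """One walk: per-frame head and thorax positions in nest-centred cm.

    Attributes
    ----------
    frame_index : (n,) int array, strictly increasing, contiguous.
    head, thorax : (n, 2) float arrays, cm; nest entrance is (0, 0),
        +x = East, +y = North.
    frame_rate : frames per second (video default 25).
    label : walk kind, one of {"learning", "excavation", "test", "unknown"}.
    ant_id : opaque identifier.
    """

    frame_index: np.ndarray
    head: np.ndarray
    thorax: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    label: str = "unknown"
    ant_id: str = ""
    nest: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        fi = np.asarray(self.frame_index, dtype=np.int64)
        head = np.asarray(self.head, dtype=float)
        thorax = np.asarray(self.thorax, dtype=float)
        object.__setattr__(self, "frame_index", fi)
        object.__setattr__(self, "head", head)
        object.__setattr__(self, "thorax", thorax)
        n = len(fi)
        if n < 2:
            raise InsufficientDataError(f"trajectory needs >= 2 frames, got {n}")
        if head.shape != (n, 2) or thorax.shape != (n, 2):
            raise DataError("head/thorax must be (n, 2) arrays matching frame_index")
        if not (np.diff(fi) > 0).all():
            raise DataError("frame_index must be strictly increasing")
        if not (np.diff(fi) == 1).all():
            raise DataError("frame_index has gaps; gaps are rejected, not interpolated")
        if not (np.isfinite(head).all() and np.isfinite(thorax).all()):
            raise DataError("non-finite coordinates")
        if self.frame_rate <= 0:
            raise DataError("frame_rate must be positive")
        axis = head - thorax
        if (np.hypot(axis[:, 0], axis[:, 1]) == 0).any():
            raise DataError("head coincides with thorax on some frame (zero body axis)")
        if self.label not in ("learning", "excavation", "test", "unknown"):
            raise DataError(f"unknown walk label {self.label!r}")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    @property
    def t(self) -> np.ndarray:
        """Time stamps in seconds, t = frame_index / frame_rate."""
        return self.frame_index / self.frame_rate

    def with_label(self, label: str, ant_id: str | None = None) -> "Trajectory":
        return replace(self, label=label, ant_id=self.ant_id if ant_id is None else ant_id)


class Steps(NamedTuple):
    """Step decomposition of a thorax path.

    lengths : (n-1,) cm, Euclidean distance between consecutive thorax positions.
    turning_angles : (n-2,) radians in (-pi, pi], signed direction change
        between consecutive steps (positive = left turn).
    """

    lengths: np.ndarray
    turning_angles: np.ndarray


def steps(traj: Trajectory) -> Steps:
    """Step lengths and turning angles of the thorax path."""
    if traj.n_frames < 3:
        raise InsufficientDataError("need >= 3 frames for turning angles")
    d = np.diff(traj.thorax, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    # turning angle between successive step vectors via atan2(cross, dot):
    # well-defined even across zero-length steps only when both steps move
    v1, v2 = d[:-1], d[1:]
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = (v1 * v2).sum(axis=1)
    turning = wrap_signed_rad(np.arctan2(cross, dot))
    # reversal maps to +pi by convention
    turning = np.where(np.isclose(turning, -np.pi), np.pi, turning)
    return Steps(lengths=lengths, turning_angles=turning)


def _read_delimited(path) -> pd.DataFrame:
    if isinstance(path, (str, os.PathLike)) and os.path.getsize(path) == 0:
        raise FormatError(f"empty tracking file: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"cannot parse tracking table {path}: {exc}") from exc
    if df.empty and df.columns.size == 0:
        raise FormatError(f"empty tracking file: {path}")
    return df


def read_tracking_table(
    path,
    frame_rate: float = DEFAULT_FRAME_RATE,
    scale: float = 1.0,
    nest_pixel: tuple[float, float] = (0.0, 0.0),
    flip_y: bool = True,
    label: str = "unknown",
    ant_id: str = "",
) -> Trajectory:
    """Read a digitized tracking table (pixels) into a nest-centred Trajectory.

    Parameters
    ----------
    path : delimited text with header ``frame,head_x,head_y,thorax_x,thorax_y``
        in pixel units (comma or tab separated).
    frame_rate : video frame rate in frames/s.
    scale : cm per pixel (> 0).
    nest_pixel : pixel coordinates of the nest entrance; maps to (0, 0).
    flip_y : video rows increase downward; flipping makes +y = North
        (map convention).  Set False if the table is already map-oriented.

    Raises
    ------
    FormatError : missing columns or empty file.
    DataError : non-monotone or gapped frames, < 2 rows.
    """
    if scale <= 0:
        raise FormatError("scale (cm per pixel) must be > 0")
    df = _read_delimited(path)
    missing = [c for c in TRACKING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"tracking table {path} missing columns {missing}")
    if len(df) < 2:
        raise InsufficientDataError(f"tracking table {path} has {len(df)} rows; need >= 2")
    sy = -1.0 if flip_y else 1.0
    hx = (df["head_x"].to_numpy(float) - nest_pixel[0]) * scale
    hy = (df["head_y"].to_numpy(float) - nest_pixel[1]) * scale * sy
    tx = (df["thorax_x"].to_numpy(float) - nest_pixel[0]) * scale
    ty = (df["thorax_y"].to_numpy(float) - nest_pixel[1]) * scale * sy
    return Trajectory(
        frame_index=df["frame"].to_numpy(np.int64),
        head=np.column_stack([hx, hy]),
        thorax=np.column_stack([tx, ty]),
        frame_rate=frame_rate,
        label=label,
        ant_id=ant_id,
    )


def write_tracking_table(
    traj: Trajectory,
    path,
    scale: float = 1.0,
    nest_pixel: tuple[float, float] = (0.0, 0.0),
    flip_y: bool = True,
) -> None:
    """Write a Trajectory back to the pixel tracking-table format.

    Exact inverse of :func:`read_tracking_table` with the same calibration:
    re-reading reproduces the coordinates to full float precision.
    """
    if scale <= 0:
        raise FormatError("scale (cm per pixel) must be > 0")
    sy = -1.0 if flip_y else 1.0
    df = pd.DataFrame(
        {
            "frame": traj.frame_index,
            "head_x": traj.head[:, 0] / scale + nest_pixel[0],
            "head_y": traj.head[:, 1] * sy / scale + nest_pixel[1],
            "thorax_x": traj.thorax[:, 0] / scale + nest_pixel[0],
            "thorax_y": traj.thorax[:, 1] * sy / scale + nest_pixel[1],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write the canonical calibrated form: ``t,head_x_cm,head_y_cm,thorax_x_cm,thorax_y_cm``."""
    df = pd.DataFrame(
        {
            "t": traj.t,
            "head_x_cm": traj.head[:, 0],
            "head_y_cm": traj.head[:, 1],
            "thorax_x_cm": traj.thorax[:, 0],
            "thorax_y_cm": traj.thorax[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectory_csv(
    path, frame_rate: float = DEFAULT_FRAME_RATE, label: str = "unknown", ant_id: str = ""
) -> Trajectory:
    """Read the canonical calibrated CSV written by :func:`write_trajectory_csv`."""
    df = _read_delimited(path)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trajectory CSV {path} missing columns {missing}")
    t = df["t"].to_numpy(float)
    frame_index = np.rint(t * frame_rate).astype(np.int64)
    return Trajectory(
        frame_index=frame_index,
        head=df[["head_x_cm", "head_y_cm"]].to_numpy(float),
        thorax=df[["thorax_x_cm", "thorax_y_cm"]].to_numpy(float),
        frame_rate=frame_rate,
        label=label,
        ant_id=ant_id,
    )
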
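"""Per-walk path metrics: extent, kinematics and straightness indices.

Everything here is computed from thorax positions at consecutive video
frames (the "step" unit), except orientation measures, which use the
thorax->head body-axis vector.

Straightness indices
--------------------
straightness : net displacement / path length, in [0, 1].
sinuosity    : S = 2 [ p ((1+c)/(1-c) + b^2) ]^(-1/2), with p the mean step
               length (cm), c the mean cosine of turning angles and b the
               coefficient of variation of step length.  Note S is not
               bounded by 1 for short steps; we evaluate the formula as
               printed.
emax         : maximum expected displacement beta/(1-beta), beta the mean
               cosine of turning angles; infinite for a perfectly straight
               path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .angles import azimuth_deg, unwrap_deg
from .errors import DataError, InsufficientDataError, UndefinedMetricError
from .trajectory import Trajectory, steps

# stop exclusion defaults: speed below 0.5 cm/s sustained for >= 0.2 s counts
# as a stop (the protocol excludes stopping durations from mean speed but
# states no thresholds)
DEFAULT_STOP_SPEED_THRESH = 0.5
DEFAULT_STOP_MIN_DUR = 0.2

_STRAIGHT_EPS = 1e-12


@dataclass(frozen=True)
class PathMetrics:
    """One row of the per-walk summary table."""

    convex_hull_area: float  # cm^2
    max_displacement: float  # cm from nest
    duration: float  # s
    mean_speed: float  # cm/s, stops excluded
    mean_orient_angular_velocity: float  # deg/s, magnitude of head-direction change
    straightness: float  # [0, 1]
    sinuosity: float  # >= 0
    emax: float  # beta/(1-beta), may be inf
    n_scan_bouts: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def convex_hull_area(traj: Trajectory) -> float:
    """Area (cm^2) of the convex hull of all thorax positions; 0 if collinear."""
    pts = traj.thorax
    if len(pts) < 3:
        raise InsufficientDataError("convex hull needs >= 3 points")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0  # collinear / coincident points enclose no area
    return float(hull.volume)  # in 2-D, .volume is the area


def max_displacement(traj: Trajectory) -> float:
    """Maximum thorax distance (cm) from the nest at (0, 0)."""
    return float(np.hypot(traj.thorax[:, 0], traj.thorax[:, 1]).max())


def duration(traj: Trajectory) -> float:
    """Walk duration in seconds, t_last - t_first."""
    t = traj.t
    return float(t[-1] - t[0])


def stop_mask(
    traj: Trajectory,
    stop_speed_thresh: float = DEFAULT_STOP_SPEED_THRESH,
    stop_min_dur: float = DEFAULT_STOP_MIN_DUR,
) -> np.ndarray:
    """Boolean mask over the n-1 steps: True where the step belongs to a stop.

    A stop is a maximal run of consecutive steps with speed below
    ``stop_speed_thresh`` lasting at least ``stop_min_dur`` seconds.
    """
    if stop_speed_thresh < 0 or stop_min_dur < 0:
        raise ValueError("stop thresholds must be >= 0")
    d = np.diff(traj.thorax, axis=0)
    speed = np.hypot(d[:, 0], d[:, 1]) * traj.frame_rate
    slow = speed < stop_speed_thresh
    mask = np.zeros_like(slow)
    min_steps = int(np.ceil(stop_min_dur * traj.frame_rate))
    i = 0
    n = len(slow)
    while i < n:
        if slow[i]:
            j = i
            while j < n and slow[j]:
                j += 1
            if j - i >= max(min_steps, 1):
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def mean_speed(
    traj: Trajectory,
    stop_speed_thresh: float = DEFAULT_STOP_SPEED_THRESH,
    stop_min_dur: float = DEFAULT_STOP_MIN_DUR,
) -> float:
    """Mean thorax speed (cm/s) over the walk with stopping durations excluded."""
    d = np.diff(traj.thorax, axis=0)
    speed = np.hypot(d[:, 0], d[:, 1]) * traj.frame_rate
    moving = ~stop_mask(traj, stop_speed_thresh, stop_min_dur)
    if not moving.any():
        warnings.warn("all frames are stopped; mean_speed = 0", stacklevel=2)
        return 0.0
    return float(speed[moving].mean())


def orientation_series(traj: Trajectory) -> np.ndarray:
    """Per-frame body-axis azimuth (deg, 0 = North, unwrapped over time).

    The orientation is the thorax->head vector; unwrapping removes the
    +-180° jumps so consecutive differences are true angular changes.
    """
    axis = traj.head - traj.thorax
    norm = np.hypot(axis[:, 0], axis[:, 1])
    if (norm == 0).any():
        raise DataError("zero-length body axis")
    az = azimuth_deg(axis[:, 0], axis[:, 1])
    return unwrap_deg(az)


def mean_orient_angular_velocity(traj: Trajectory) -> float:
    """Mean magnitude of head-direction change rate, deg/s."""
    orient = orientation_series(traj)
    return float(np.abs(np.diff(orient)).mean() * traj.frame_rate)


def straightness(traj: Trajectory) -> float:
    """Net displacement over path length, in [0, 1]."""
    d = np.diff(traj.thorax, axis=0)
    path_len = np.hypot(d[:, 0], d[:, 1]).sum()
    if path_len <= 0:
        raise UndefinedMetricError("zero path length: straightness undefined")
    net = float(np.hypot(*(traj.thorax[-1] - traj.thorax[0])))
    return float(min(net / path_len, 1.0))


def sinuosity(traj: Trajectory) -> float:
    """Tortuosity index S = 2 [ p ((1+c)/(1-c) + b^2) ]^(-1/2).

    p: mean step length (cm); c: mean cosine of turning angles; b: CV of
    step length.  Returns 0 in the perfectly-straight limit c -> 1.
    """
    st = steps(traj)
    p = float(st.lengths.mean())
    if p <= 0:
        raise UndefinedMetricError("zero mean step length: sinuosity undefined")
    c = float(np.cos(st.turning_angles).mean())
    b = float(st.lengths.std(ddof=0) / p)
    if 1.0 - c < _STRAIGHT_EPS:
        return 0.0  # straight-path limit of the formula
    return float(2.0 / np.sqrt(p * ((1.0 + c) / (1.0 - c) + b**2)))


def emax(traj: Trajectory) -> float:
    """Maximum expected displacement beta/(1-beta); inf for a straight path."""
    st = steps(traj)
    beta = float(np.cos(st.turning_angles).mean())
    if beta >= 1.0 - _STRAIGHT_EPS:
        return float("inf")
    return float(beta / (1.0 - beta))


def compute_path_metrics(
    traj: Trajectory,
    stop_speed_thresh: float = DEFAULT_STOP_SPEED_THRESH,
    stop_min_dur: float = DEFAULT_STOP_MIN_DUR,
    n_scan_bouts: int = 0,
) -> PathMetrics:
    """All per-walk metrics in one pass (scan-bout count supplied by the caller)."""
    return PathMetrics(
        convex_hull_area=convex_hull_area(traj),
        max_displacement=max_displacement(traj),
        duration=duration(traj),
        mean_speed=mean_speed(traj, stop_speed_thresh, stop_min_dur),
        mean_orient_angular_velocity=mean_orient_angular_velocity(traj),
        straightness=straightness(traj),
        sinuosity=sinuosity(traj),
        emax=emax(traj),
        n_scan_bouts=n_scan_bouts,
    )
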
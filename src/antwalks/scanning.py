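"""Scanning-bout detection.

During learning walks ants pause and rotate on the spot, holding a series of
stationary head directions ("fixations") before walking on.  A scanning bout
is detected as a maximal interval in which

  (i)   the thorax stays within ``on_spot_radius`` of the interval centroid,
  (ii)  the interval lasts at least ``min_bout_dur`` seconds, and
  (iii) it contains at least two fixations — sub-intervals of duration
        >= ``fixation_min_dur`` with head-rotation rate below
        ``fixation_max_rot_rate`` — whose mean orientations differ by at
        least ``min_fixation_separation`` degrees.

Candidate intervals separated by less than ``merge_gap`` seconds are merged
before the fixation criterion is applied.  All thresholds are explicit
parameters recorded in the output; the behaviour is defined qualitatively in
the field literature, so the defaults are calibrated on the synthetic
generator and must travel with any reported count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .metrics import orientation_series
from .trajectory import Trajectory


@dataclass(frozen=True)
class ScanParams:
    """Detection thresholds (units in docstrings; all configurable)."""

    on_spot_radius: float = 0.5  # cm: max thorax distance from bout centroid
    min_bout_dur: float = 0.5  # s: minimum bout duration
    fixation_min_dur: float = 0.08  # s: minimum fixation duration (2 frames at 25 fps)
    fixation_max_rot_rate: float = 50.0  # deg/s: head counts as still below this
    min_fixation_separation: float = 45.0  # deg: distinct fixation directions
    merge_gap: float = 0.3  # s: stationary intervals closer than this merge
    pos_smooth_s: float = 0.28  # s: boxcar smoothing of tracked points before
    # the body-axis angle is taken (digitization jitter on a ~0.4 cm axis is
    # tens of degrees per frame otherwise)
    orient_smooth_s: float = 0.2  # s: boxcar smoothing of orientation before rate test

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ScanningBout:
    start_t: float
    end_t: float
    location: tuple[float, float]  # mean thorax position, cm
    n_fixations: int
    angular_span: float  # deg, max - min unwrapped orientation within bout

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


def _stationary_candidates(
    thorax: np.ndarray, radius: float, min_frames: int
) -> list[tuple[int, int]]:
    """Maximal on-the-spot windows of at least ``min_frames`` frames.

    A window [i, j) is on-the-spot when its bounding-box diagonal is at most
    2*radius (so all pairwise thorax displacements stay within the on-spot
    diameter).  For each start i the furthest end j(i) is found with a
    two-pointer sweep — the criterion is monotone under point removal — and
    only windows not contained in an earlier one are kept.
    """
    n = len(thorax)
    out: list[tuple[int, int]] = []
    j = 0
    prev_j = -1
    diam = 2.0 * radius
    for i in range(n):
        if j < i + 1:
            j = i + 1
        # recompute bbox for current [i, j), then extend
        seg = thorax[i:j]
        xmin, ymin = seg.min(axis=0)
        xmax, ymax = seg.max(axis=0)
        while j < n:
            x, y = thorax[j]
            nxmin, nxmax = min(xmin, x), max(xmax, x)
            nymin, nymax = min(ymin, y), max(ymax, y)
            if np.hypot(nxmax - nxmin, nymax - nymin) <= diam:
                xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
                j += 1
            else:
                break
        if j - i >= min_frames and j > prev_j:
            out.append((i, j))
            prev_j = j
    return out


def _select_intervals(
    candidates: list[tuple[int, int]], max_gap_frames: int
) -> list[tuple[int, int]]:
    """Greedy selection of disjoint bout intervals, longest first.

    A true bout produces a long stationary window flanked by many slightly
    shifted copies and brief slow-walking windows; taking the longest
    candidate and suppressing everything overlapping or within the merge
    gap of it leaves one representative interval per on-the-spot episode.
    """
    chosen: list[tuple[int, int]] = []
    for s, e in sorted(candidates, key=lambda c: (c[0] - c[1], c[0])):
        if all(s >= ce + max_gap_frames or e <= cs - max_gap_frames for cs, ce in chosen):
            chosen.append((s, e))
    return sorted(chosen)


def _denoised_orientation(traj: Trajectory, params: ScanParams) -> np.ndarray:
    """Unwrapped body-axis azimuth from boxcar-smoothed head/thorax tracks."""
    w = int(round(params.pos_smooth_s * traj.frame_rate))
    if w < 2 or traj.n_frames < w:
        return orientation_series(traj)
    axis = np.column_stack([
        _smooth(traj.head[:, 0] - traj.thorax[:, 0], traj.frame_rate, params.pos_smooth_s),
        _smooth(traj.head[:, 1] - traj.thorax[:, 1], traj.frame_rate, params.pos_smooth_s),
    ])
    az = np.degrees(np.arctan2(axis[:, 0], axis[:, 1]))
    return np.degrees(np.unwrap(np.radians(az)))


def _smooth(orient: np.ndarray, frame_rate: float, window_s: float) -> np.ndarray:
    w = int(round(window_s * frame_rate))
    if w < 2 or len(orient) < w:
        return orient
    pad = np.concatenate([orient[w - 1 :: -1], orient, orient[: -w - 1 : -1]])
    kernel = np.ones(w) / w
    sm = np.convolve(pad, kernel, mode="same")
    return sm[w : w + len(orient)]


def _fixations(
    orient: np.ndarray, frame_rate: float, params: ScanParams
) -> list[tuple[int, int, float]]:
    """Fixation segments (start, stop, mean orientation) inside one bout.

    The orientation is boxcar-smoothed before the rate test so per-frame
    digitization jitter does not mask true stillness; consecutive still
    segments whose mean directions differ by less than the separation
    threshold are treated as one fixation.
    """
    orient = _smooth(orient, frame_rate, params.orient_smooth_s)
    rate = np.abs(np.diff(orient)) * frame_rate
    still = rate < params.fixation_max_rot_rate
    min_steps = max(int(np.ceil(params.fixation_min_dur * frame_rate)), 1)
    segs: list[tuple[int, int, float]] = []
    i = 0
    n = len(still)
    while i < n:
        if still[i]:
            j = i
            while j < n and still[j]:
                j += 1
            if j - i >= min_steps:
                mean_o = float(orient[i : j + 1].mean())
                if segs and abs(segs[-1][2] - mean_o) < params.min_fixation_separation:
                    # same head direction resumed after a noisy wobble: one fixation
                    ps = segs[-1][0]
                    segs[-1] = (ps, j + 1, float(orient[ps : j + 1].mean()))
                else:
                    segs.append((i, j + 1, mean_o))
            i = j
        else:
            i += 1
    return segs


def detect_scanning_bouts(traj: Trajectory, params: ScanParams | None = None) -> list[ScanningBout]:
    """Detect scanning bouts; returns disjoint, time-ordered bouts.

    A trajectory shorter than ``min_bout_dur`` yields an empty list.
    Deterministic: identical input and parameters give identical bouts.
    """
    params = params or ScanParams()
    t = traj.t
    if t[-1] - t[0] < params.min_bout_dur:
        return []
    orient = _denoised_orientation(traj, params)
    min_frames = int(np.ceil(params.min_bout_dur * traj.frame_rate))
    candidates = _stationary_candidates(traj.thorax, params.on_spot_radius, min_frames)
    gap_frames = int(round(params.merge_gap * traj.frame_rate))
    stationary = _select_intervals(candidates, gap_frames)

    bouts: list[ScanningBout] = []
    for s, e in stationary:
        seg_orient = orient[s:e]
        fixes = _fixations(seg_orient, traj.frame_rate, params)
        if len(fixes) < 2:
            continue
        means = [f[2] for f in fixes]
        if max(means) - min(means) < params.min_fixation_separation:
            continue
        loc = traj.thorax[s:e].mean(axis=0)
        bouts.append(
            ScanningBout(
                start_t=float(t[s]),
                end_t=float(t[e - 1]),
                location=(float(loc[0]), float(loc[1])),
                n_fixations=len(fixes),
                angular_span=float(seg_orient.max() - seg_orient.min()),
            )
        )
    return bouts


def bout_table(bouts: list[ScanningBout]):
    """Bout list as a DataFrame (start_t, end_t, x, y, n_fixations, angular_span)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "start_t": b.start_t,
                "end_t": b.end_t,
                "x": b.location[0],
                "y": b.location[1],
                "n_fixations": b.n_fixations,
                "angular_span": b.angular_span,
            }
            for b in bouts
        ],
        columns=["start_t", "end_t", "x", "y", "n_fixations", "angular_span"],
    )
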
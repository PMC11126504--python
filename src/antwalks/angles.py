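"""Angle helpers shared across modules.

Azimuths are compass-style: degrees clockwise from North (+y), so North = 0°,
East = 90°, South = 180°, West = 270°.  Headings relative to a target bearing
are ``(azimuth - bearing) % 360`` and live in [0, 360).  Turning angles are
signed, positive for a left (counterclockwise) turn, wrapped to (-pi, pi].
"""

from __future__ import annotations

import numpy as np


def azimuth_deg(dx, dy):
    """Compass azimuth (deg in [0, 360)) of vector(s) (dx, dy) in map coordinates."""
    return np.mod(np.degrees(np.arctan2(dx, dy)), 360.0)


def wrap_deg(a):
    """Wrap angle(s) in degrees to [0, 360)."""
    return np.mod(a, 360.0)


def wrap_signed_rad(a):
    """Wrap radians to (-pi, pi]."""
    a = np.mod(a, 2.0 * np.pi)
    return np.where(a > np.pi, a - 2.0 * np.pi, a)


def ang_diff_deg(a, b):
    """Signed smallest difference a - b in degrees, in (-180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - b, 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def angle_in_arc(angle_deg: float, lo_deg: float, hi_deg: float) -> bool:
    """True if ``angle_deg`` lies on the counterclockwise-closed arc lo -> hi.

    Wrap-aware: the arc from 350° to 10° contains 0° and 5° but not 180°.
    A zero-width arc contains only its endpoint.
    """
    a = wrap_deg(angle_deg)
    lo = wrap_deg(lo_deg)
    span = wrap_deg(hi_deg - lo_deg)
    rel = wrap_deg(a - lo)
    return bool(rel <= span + 1e-12)


def unwrap_deg(series):
    """Unwrap a degree series so consecutive jumps never exceed 180° in magnitude."""
    return np.degrees(np.unwrap(np.radians(np.asarray(series, dtype=float))))
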
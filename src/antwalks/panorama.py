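"""Equirectangular panoramas and rotational image difference functions.

A panorama is a 2-D intensity grid whose columns map linearly to azimuth
(360° across the width).  The rotational image difference function (rotIDF)
between a reference panorama (taken at the nest) and a test panorama slides
the test image through all 360 one-degree yaw rotations and records the
pixel discrepancy at each shift.  A deep minimum near the nest-ward azimuth
means the remembered nest view can steer an ant from the test location.

The discrepancy metric is the root-mean-square pixel intensity difference
(the convention of the rotIDF literature); mean absolute difference is
available via ``metric="mad"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .angles import wrap_deg
from .errors import DataError, ParameterError

_LUMA = (0.299, 0.587, 0.114)  # RGB -> grayscale weights


@dataclass(frozen=True)
class Panorama:
    """Equirectangular grayscale panorama.

    intensity : (n_rows, n_cols) float grid in [0, 1]; rows are elevation
        (top = up), columns are azimuth.
    heading_of_col0 : world azimuth (deg) that column 0 faces.
    """

    intensity: np.ndarray
    heading_of_col0: float = 0.0

    def __post_init__(self):
        img = np.asarray(self.intensity, dtype=float)
        if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
            raise ParameterError("panorama intensity must be a non-empty 2-D grid")
        if not np.isfinite(img).all():
            raise DataError("non-finite panorama intensity")
        if img.min() < -1e-9 or img.max() > 1.0 + 1e-9:
            raise DataError("panorama intensity must lie in [0, 1]")
        if 360 % img.shape[1] != 0 and img.shape[1] % 360 != 0:
            raise ParameterError(
                "panorama width must divide 360 evenly or be a multiple of 360 columns"
            )
        object.__setattr__(self, "intensity", np.clip(img, 0.0, 1.0))

    @property
    def n_rows(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensity.shape[1]

    @property
    def azimuth_deg_per_col(self) -> float:
        return 360.0 / self.n_cols


@dataclass(frozen=True)
class RotIDFResult:
    """360-valued discrepancy curve with its summaries.

    depth = mean - min: larger depth means a sharper, more usable minimum.
    """

    discrepancy: np.ndarray  # (360,) one value per 1° shift
    min_value: float
    argmin_deg: int
    mean_value: float
    median_value: float
    depth: float

    def summary(self) -> dict:
        return {
            "min": self.min_value,
            "argmin_deg": self.argmin_deg,
            "median": self.median_value,
            "mean": self.mean_value,
            "depth": self.depth,
        }


def load_panorama(path, heading_of_col0: float = 0.0) -> Panorama:
    """Load a PNG/JPEG equirectangular image as a [0,1] grayscale panorama.

    Colour images are converted with luminance weights 0.299/0.587/0.114;
    intensities are scaled by the dtype maximum (255 for 8-bit).
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array(_LUMA)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return Panorama(intensity=np.clip(arr, 0.0, 1.0), heading_of_col0=heading_of_col0)


def save_panorama(p: Panorama, path) -> None:
    """Write a panorama as an 8-bit grayscale PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, np.rint(p.intensity * 255).astype(np.uint8))


def downsample(p: Panorama, az_res: float = 1.0, el_rows: int | None = None) -> Panorama:
    """Block-mean downsample to ``360/az_res`` columns and ``el_rows`` rows.

    ``az_res`` must divide 360 evenly and the existing grid must be an
    integer multiple of the target in both dimensions.
    """
    if az_res <= 0 or 360.0 % az_res != 0:
        raise ParameterError(f"az_res {az_res} must divide 360 evenly")
    n_cols = int(round(360.0 / az_res))
    el_rows = el_rows or p.n_rows
    if p.n_cols % n_cols != 0 or p.n_rows % el_rows != 0:
        raise ParameterError(
            f"grid {p.intensity.shape} is not an integer multiple of ({el_rows}, {n_cols})"
        )
    fr, fc = p.n_rows // el_rows, p.n_cols // n_cols
    img = p.intensity.reshape(el_rows, fr, n_cols, fc).mean(axis=(1, 3))
    return Panorama(intensity=img, heading_of_col0=p.heading_of_col0)


def rotate_panorama(p: Panorama, new_heading: float) -> Panorama:
    """Roll columns so column 0 faces ``new_heading`` (world azimuth, deg).

    Used to align the nest reference with a test site's nest-ward bearing
    before computing the rotIDF, so the best-match shift is interpretable
    as a heading relative to the nest direction.  The rotation must be a
    whole number of columns.
    """
    delta = wrap_deg(new_heading - p.heading_of_col0)
    cols = delta / p.azimuth_deg_per_col
    if abs(cols - round(cols)) > 1e-9:
        raise ParameterError(
            f"rotation by {delta}° is not a whole number of columns "
            f"(azimuth resolution {p.azimuth_deg_per_col}°)"
        )
    return Panorama(
        intensity=np.roll(p.intensity, -int(round(cols)), axis=1),
        heading_of_col0=float(wrap_deg(new_heading)),
    )


def rotidf(reference: Panorama, test: Panorama, metric: str = "rms") -> RotIDFResult:
    """Rotational image difference function between two same-shape panoramas.

    For each integer shift s in 0..359°, the test image is yaw-rotated by s
    (columns rolled so its column 0 faces ``heading_of_col0 + s``) and
    compared pixel-wise with the reference.  No implicit resampling: a
    shape mismatch is an error.
    """
    if reference.intensity.shape != test.intensity.shape:
        raise DataError(
            f"panorama shapes differ: {reference.intensity.shape} vs {test.intensity.shape}"
        )
    n_cols = reference.n_cols
    if n_cols % 360 != 0:
        raise ParameterError("1° shifts need a column count that is a multiple of 360")
    cols_per_deg = n_cols // 360
    ref, tst = reference.intensity, test.intensity
    disc = np.empty(360)
    for s in range(360):
        rolled = np.roll(tst, -s * cols_per_deg, axis=1)
        d = ref - rolled
        if metric == "rms":
            disc[s] = np.sqrt(np.mean(d * d))
        elif metric == "mad":
            disc[s] = np.mean(np.abs(d))
        else:
            raise ParameterError(f"unknown rotIDF metric {metric!r}")
    amin = int(np.argmin(disc))
    mean_v = float(disc.mean())
    return RotIDFResult(
        discrepancy=disc,
        min_value=float(disc[amin]),
        argmin_deg=amin,
        mean_value=mean_v,
        median_value=float(np.median(disc)),
        depth=mean_v - float(disc[amin]),
    )


def best_nest_bearing(result: RotIDFResult, heading_of_col0: float, tol: float = 1e-12) -> float:
    """World bearing of the best-matching yaw: heading_of_col0 + argmin shift.

    Multiple global minima (within ``tol``) return the smallest shift and
    emit a warning; a flat discrepancy curve (depth ~ 0) also warns.
    """
    near_min = np.nonzero(result.discrepancy <= result.min_value + tol)[0]
    if near_min.size > 1:
        warnings.warn(
            f"{near_min.size} global minima in rotIDF; returning smallest shift",
            stacklevel=2,
        )
    if result.depth <= tol:
        warnings.warn("flat rotIDF (depth ~ 0): best bearing is unreliable", stacklevel=2)
    return float(wrap_deg(heading_of_col0 + result.argmin_deg))


def write_rotidf_report(result: RotIDFResult, csv_path, json_path=None) -> None:
    """Write the discrepancy curve as CSV (shift_deg, discrepancy) and the
    summaries (min, argmin, median, mean, depth) as JSON."""
    import pandas as pd

    pd.DataFrame(
        {"shift_deg": np.arange(360), "discrepancy": result.discrepancy}
    ).to_csv(csv_path, index=False, float_format="%.12g")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(result.summary(), fh, indent=2)
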
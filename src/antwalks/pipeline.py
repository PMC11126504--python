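"""Pipeline orchestration: ingest -> metrics -> scans -> statistics -> reports.

Consumes the file tree written by :func:`antwalks.synthetic.gen_experiment`
(or equivalently organized field exports): a ``walks/`` directory of pixel
tracking tables named ``<ant>_<condition>.csv``, a ``headings.csv`` with
columns ``ant_id, condition, angle_deg``, and a ``panoramas/`` directory of
equirectangular images with a designated reference (nest) panorama.

Every report directory gets a ``run_metadata.json`` embedding the full
parameter set, so no default is hidden from the output.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circular import HeadingSet, condition_summary, wedge_histogram
from .errors import AntwalksError, DataError, InsufficientDataError
from .groupstats import (
    ALPHA_CIRCULAR,
    ALPHA_WALKS,
    WALK_CONDITIONS,
    helmert_table,
    results_table,
    welch_anova,
)
from .metrics import DEFAULT_STOP_MIN_DUR, DEFAULT_STOP_SPEED_THRESH, compute_path_metrics
from .panorama import load_panorama, rotate_panorama, rotidf, write_rotidf_report
from .scanning import ScanParams, bout_table, detect_scanning_bouts
from .trajectory import read_tracking_table

log = logging.getLogger("antwalks")

HELMERT_METRICS = [
    "convex_hull_area", "max_displacement", "duration", "mean_speed",
    "mean_orient_angular_velocity", "straightness", "sinuosity",
]


@dataclass
class RunConfig:
    """Everything a run needs; `from_yaml` fills it from a config file."""

    input_dir: str = "."
    out_dir: str = "reports"
    walks_dir: str = "walks"
    headings_csv: str = "headings.csv"
    panoramas_dir: str = "panoramas"
    reference_panorama: str = "nest.png"
    frame_rate: float = 25.0
    scale_cm_per_px: float = 1.0
    nest_pixel: tuple = (0.0, 0.0)
    flip_y: bool = True
    stop_speed_thresh: float = DEFAULT_STOP_SPEED_THRESH
    stop_min_dur: float = DEFAULT_STOP_MIN_DUR
    scan: ScanParams = field(default_factory=ScanParams)
    rotidf_metric: str = "rms"
    # per-panorama metadata: name -> {"position_m": [x, y], "heading_of_col0": deg};
    # lets the reference be aligned to each test site's nest-ward bearing
    panorama_info: dict = field(default_factory=dict)
    alpha_walks: float = ALPHA_WALKS
    alpha_circular: float = ALPHA_CIRCULAR
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("walks", None)
        scan_raw = raw.pop("scan", None)
        pano_raw = raw.pop("panoramas", None)
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        known.update(overrides)
        cfg = cls(**known)
        if scan_raw:
            cfg.scan = ScanParams(**scan_raw)
        if pano_raw:
            cfg.panorama_info = dict(pano_raw)
        if not (0 < cfg.alpha_walks < 1 and 0 < cfg.alpha_circular < 1):
            raise AntwalksError("alpha levels must lie in (0, 1)")
        cfg.input_dir = str(Path(path).parent)
        return cfg

    def metadata(self) -> dict:
        d = asdict(self)
        d["scan"] = self.scan.as_dict()
        d["antwalks_version"] = __version__
        return d


def _write_metadata(out: Path, cfg: RunConfig, extra: dict | None = None) -> None:
    meta = cfg.metadata()
    if extra:
        meta.update(extra)
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)


def load_walks(cfg: RunConfig):
    """Read every ``<ant>_<cond>.csv`` under walks_dir; log and skip bad files."""
    walks_dir = Path(cfg.input_dir) / cfg.walks_dir
    out, errors = [], []
    for path in sorted(walks_dir.glob("*.csv")):
        stem = path.stem
        ant_id, _, cond = stem.rpartition("_")
        label = "learning" if cond == "LW" else "excavation" if cond.startswith("E") else "unknown"
        try:
            traj = read_tracking_table(
                path, frame_rate=cfg.frame_rate, scale=cfg.scale_cm_per_px,
                nest_pixel=tuple(cfg.nest_pixel), flip_y=cfg.flip_y,
                label=label, ant_id=ant_id,
            )
        except AntwalksError as exc:
            log.error("skipping %s: %s", path.name, exc)
            errors.append({"file": path.name, "error": str(exc)})
            continue
        out.append((ant_id, cond, traj))
    if not out:
        raise DataError(f"no readable walk files in {walks_dir}")
    return out, errors


def run_walk_analysis(cfg: RunConfig) -> Path:
    """Per-walk metrics, scan-bout tables, and the Helmert/Welch comparisons."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    walks, errors = load_walks(cfg)

    rows, bout_rows = [], []
    for ant_id, cond, traj in walks:
        bouts = detect_scanning_bouts(traj, cfg.scan) if traj.label == "learning" else []
        m = compute_path_metrics(
            traj, cfg.stop_speed_thresh, cfg.stop_min_dur, n_scan_bouts=len(bouts)
        )
        rows.append({"ant_id": ant_id, "condition": cond, **m.as_dict()})
        for b in bouts:
            bout_rows.append({
                "ant_id": ant_id, "condition": cond, "start_t": b.start_t,
                "end_t": b.end_t, "x": b.location[0], "y": b.location[1],
                "n_fixations": b.n_fixations, "angular_span": b.angular_span,
            })
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "walk_metrics.csv", index=False, float_format="%.12g")
    pd.DataFrame(bout_rows, columns=[
        "ant_id", "condition", "start_t", "end_t", "x", "y", "n_fixations", "angular_span",
    ]).to_csv(out / "scan_bouts.csv", index=False, float_format="%.12g")

    stats_frames = []
    n_ants = metrics["ant_id"].nunique()
    have_design = set(WALK_CONDITIONS) <= set(metrics["condition"].unique())
    if n_ants >= 3 and have_design:
        for metric in HELMERT_METRICS:
            try:
                res = helmert_table(metrics, metric)
            except InsufficientDataError as exc:
                log.warning("Helmert contrasts skipped for %s: %s", metric, exc)
                continue
            stats_frames.append(results_table(res, metric, cfg.alpha_walks))
            groups = [
                metrics.loc[metrics.condition == c, metric].to_numpy(float)
                for c in WALK_CONDITIONS
            ]
            w = welch_anova(groups)
            stats_frames.append(results_table([w], metric, cfg.alpha_walks))
    else:
        warnings.warn(
            "group statistics skipped: need >= 3 ants with the full LW/E1/E2/E3 design",
            stacklevel=2,
        )
    if stats_frames:
        pd.concat(stats_frames, ignore_index=True).to_csv(
            out / "walk_group_stats.csv", index=False, float_format="%.12g"
        )
    _write_metadata(out, cfg, {"analysis": "walks", "n_walks": len(walks),
                               "file_errors": errors})
    return out


def run_displacement_analysis(cfg: RunConfig) -> Path:
    """Table-1-style circular statistics and 24-wedge histograms per condition."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(Path(cfg.input_dir) / cfg.headings_csv)
    for col in ("condition", "angle_deg"):
        if col not in df.columns:
            raise DataError(f"headings CSV lacks column {col!r}")
    summaries, wedge_rows = [], []
    for cond, grp in df.groupby("condition", sort=True):
        h = HeadingSet(angles=grp["angle_deg"].to_numpy(float), condition=str(cond))
        wedge_rows.append({"condition": cond, **{
            f"wedge_{k:02d}": int(c) for k, c in enumerate(wedge_histogram(h))
        }})
        if h.n < 5:
            log.warning("condition %s has n=%d < 5: circular tests flagged, not run", cond, h.n)
            summaries.append({"condition": cond, "n": h.n, "flag": "too_few_headings"})
            continue
        summaries.append(condition_summary(h, target=0.0, seed=cfg.seed))
    pd.DataFrame(summaries).to_csv(out / "displacement_stats.csv", index=False,
                                   float_format="%.12g")
    pd.DataFrame(wedge_rows).to_csv(out / "wedge_histograms.csv", index=False)
    _write_metadata(out, cfg, {"analysis": "displacement"})
    return out


def run_rotidf_analysis(cfg: RunConfig) -> Path:
    """rotIDF of every test panorama against the nest reference."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pano_dir = Path(cfg.input_dir) / cfg.panoramas_dir
    ref_path = pano_dir / cfg.reference_panorama
    if not ref_path.exists():
        raise DataError(f"reference panorama missing: {ref_path}")
    ref_name = Path(cfg.reference_panorama).stem
    ref_info = cfg.panorama_info.get(ref_name, {})
    reference = load_panorama(ref_path, heading_of_col0=ref_info.get("heading_of_col0", 0.0))
    summaries = {}
    for path in sorted(pano_dir.glob("*.png")):
        name = path.stem
        info = cfg.panorama_info.get(name, {})
        h0 = info.get("heading_of_col0", 0.0)
        test = load_panorama(path, heading_of_col0=h0)
        # align the reference with this site's facing so the best-match
        # shift reads as a heading relative to the nest-ward direction
        ref = rotate_panorama(reference, h0) if h0 != reference.heading_of_col0 else reference
        res = rotidf(ref, test, metric=cfg.rotidf_metric)
        write_rotidf_report(res, out / f"rotidf_{name}.csv")
        summaries[name] = res.summary()
        summaries[name]["best_bearing_deg"] = (h0 + res.argmin_deg) % 360.0
    with open(out / "rotidf_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True)
    _write_metadata(out, cfg, {"analysis": "rotidf", "reference": cfg.reference_panorama})
    return out


def run_all(cfg: RunConfig) -> Path:
    run_walk_analysis(cfg)
    run_displacement_analysis(cfg)
    run_rotidf_analysis(cfg)
    return Path(cfg.out_dir)
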
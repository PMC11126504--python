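"""Synthetic generators emulating the study's inputs, with known ground truth.

Three families of inputs are emulated so the whole pipeline runs end to end
without any field data:

* **Walks** — a naive learning walk is a single loop confined to within
  ~30 cm of the nest with 1–3 on-the-spot scanning bouts; an excavation
  trip is a straight out-and-back run depositing sand 5–10 cm from the
  entrance, faster than the learning walk, with no stops and no scans.
  Every generated walk carries a :class:`GroundTruth` record (inserted
  bouts, commanded speed, true maximum excursion).
* **Headings** — von Mises draws (kappa = 0 gives the uniform null) for
  the displacement-test conditions.
* **Panoramas** — equirectangular renders of a parametric landmark scene
  (dark tussocks/bushes/trees on a bright sky), used as stand-ins for the
  field camera panoramas.  These scenes are synthetic by construction.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .angles import azimuth_deg, wrap_deg
from .circular import HeadingSet
from .errors import ParameterError
from .panorama import Panorama
from .trajectory import Trajectory

BODY_LENGTH_CM = 0.4  # thorax-to-head-tip distance used for the body axis


def _unit(az_deg):
    """Compass unit vector(s): North = (0,1), East = (1,0)."""
    a = np.radians(az_deg)
    return np.stack([np.sin(a), np.cos(a)], axis=-1)


@dataclass(frozen=True)
class WalkGenParams:
    """Generator knobs for one walk; defaults are the study-like conditions."""

    kind: str = "learning"  # "learning" | "excavation"
    loop_radius: float = 8.5  # cm: learning-walk loop size (max excursion of the loop)
    loop_aspect: float = 0.55  # lateral width of the loop relative to its length
    max_excursion: float = 30.0  # cm: hard cap on distance from the nest
    excavation_range: tuple[float, float] = (5.0, 10.0)  # cm: sand-drop distance
    speed_mean: float = 2.5  # cm/s (excavation default overrides to 5.0)
    speed_cv: float = 0.15  # per-frame speed variability
    turn_kappa: float = 500.0  # heading-jitter concentration (higher = straighter)
    n_scan_bouts: int = 2  # learning walks only
    head_osc_amp: float = 8.0  # deg: gaze oscillation amplitude about travel direction
    head_osc_freq: float = 0.8  # Hz
    path_wobble: float = 0.15  # cm: smooth perpendicular wobble of the loop
    noise_sd_pos: float = 0.0  # cm: digitization noise on each tracked point
    noise_sd_orient: float = 0.0  # deg: digitization noise on the body axis
    frame_rate: float = 25.0
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("learning", "excavation"):
            raise ParameterError(f"unknown walk kind {self.kind!r}")
        if self.kind == "excavation" and self.n_scan_bouts != 0:
            raise ParameterError("excavation trips have no scanning bouts")
        for name in ("loop_radius", "max_excursion", "speed_mean", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.loop_radius > self.max_excursion:
            raise ParameterError("loop_radius exceeds max_excursion")
        if self.excavation_range[0] > self.excavation_range[1]:
            raise ParameterError("excavation_range must be (lo, hi) with lo <= hi")


def learning_params(**overrides) -> WalkGenParams:
    """Default learning-walk conditions (slow loop, 1-3 scan bouts)."""
    return WalkGenParams(kind="learning", **overrides)


def excavation_params(**overrides) -> WalkGenParams:
    """Default excavation-trip conditions (fast, straight, no scans)."""
    base = dict(
        kind="excavation", n_scan_bouts=0, speed_mean=5.0,
        head_osc_amp=15.0, head_osc_freq=2.0,
    )
    base.update(overrides)
    return WalkGenParams(**base)


@dataclass(frozen=True)
class BoutTruth:
    start_t: float
    end_t: float
    n_fixations: int


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for oracle-style tests."""

    kind: str
    commanded_speed: float
    max_excursion: float  # true max thorax distance from nest, cm
    bouts: tuple[BoutTruth, ...] = ()
    drop_distance: float | None = None  # excavation: where the sand went, cm

    @property
    def n_scan_bouts(self) -> int:
        return len(self.bouts)

    def as_dict(self) -> dict:
        return asdict(self)


def _ar1(rng, n, rho=0.9):
    e = rng.standard_normal(n) * np.sqrt(1 - rho**2)
    a = np.empty(n)
    a[0] = rng.standard_normal()
    for i in range(1, n):
        a[i] = rho * a[i - 1] + e[i]
    return a


def _resample_arc(dense: np.ndarray, p: WalkGenParams, rng) -> np.ndarray:
    """Place video frames along a dense path at the commanded mean speed.

    Per-frame speeds follow an AR(1) profile with coefficient of variation
    ``speed_cv``, renormalized over the walk so the realized mean speed
    equals ``speed_mean`` up to frame-count rounding.
    """
    seg = np.hypot(*np.diff(dense, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    dt = 1.0 / p.frame_rate
    m = max(int(round(total / (p.speed_mean * dt))), 2)
    if p.speed_cv > 0:
        f = np.clip(1.0 + p.speed_cv * _ar1(rng, m), 0.1, None)
        f /= f.mean()
    else:
        f = np.ones(m)
    s = np.concatenate([[0.0], np.cumsum(f * total / m)])
    s[-1] = total
    x = np.interp(s, arc, dense[:, 0])
    y = np.interp(s, arc, dense[:, 1])
    return np.column_stack([x, y])


def _fourier_wobble(rng, s, total, sd, n_modes=5):
    """Smooth zero-at-endpoints wobble along arc length: a few random
    low-order sine modes, so step directions stay smooth frame to frame."""
    if sd <= 0:
        return np.zeros_like(s)
    amps = rng.standard_normal(n_modes) / np.arange(1, n_modes + 1)
    phases = np.pi * np.arange(1, n_modes + 1)[:, None] * s[None, :] / total
    w = (amps[:, None] * np.sin(phases)).sum(axis=0)
    peak = np.abs(w).max()
    return w / peak * sd if peak > 0 else w


def _bout_orientation_script(rng, start_orient, frame_rate):
    """Orientation series (deg, unwrapped) for one scanning bout.

    3-5 fixations held 0.4-0.8 s each, separated by fast saccades
    (~400 deg/s) through 70-130 deg jumps of random sign.
    """
    n_fix = int(rng.integers(3, 6))
    orient = [np.full(int(rng.uniform(0.4, 0.8) * frame_rate), start_orient)]
    cur = start_orient
    for _ in range(n_fix - 1):
        jump = rng.uniform(70.0, 130.0) * rng.choice([-1.0, 1.0])
        n_turn = max(int(abs(jump) / 400.0 * frame_rate), 1)
        orient.append(cur + np.linspace(0, jump, n_turn + 1)[1:])
        cur += jump
        orient.append(np.full(int(rng.uniform(0.4, 0.8) * frame_rate), cur))
    return np.concatenate(orient), n_fix


def _assemble(frame_rate, thorax, travel_dir, bout_spans, bout_scripts, bout_nfix,
              p: WalkGenParams, rng, label):
    """Insert bout frames into a walking skeleton and attach head positions."""
    n_walk = len(thorax)
    th_parts, orient_parts, truth = [], [], []
    prev = 0
    t_cursor = 0.0
    for idx, script in zip(bout_spans, bout_scripts):
        th_parts.append(thorax[prev:idx])
        orient_parts.append(("walk", prev, idx))
        t_cursor += (idx - prev) / frame_rate
        nb = len(script)
        th_parts.append(np.repeat(thorax[idx - 1 : idx], nb, axis=0))
        orient_parts.append(("bout", script, idx))
        truth.append((t_cursor, t_cursor + (nb - 1) / frame_rate))
        t_cursor += nb / frame_rate
        prev = idx
    th_parts.append(thorax[prev:])
    orient_parts.append(("walk", prev, n_walk))

    th = np.concatenate(th_parts, axis=0)
    n = len(th)
    t = np.arange(n) / frame_rate
    osc = p.head_osc_amp * np.sin(2 * np.pi * p.head_osc_freq * t + rng.uniform(0, 2 * np.pi))

    orient = np.empty(n)
    pos = 0
    n_fix_per_bout = []
    for part in orient_parts:
        if part[0] == "walk":
            _, a, b = part
            m = b - a
            orient[pos : pos + m] = travel_dir[a:b] + osc[pos : pos + m]
            pos += m
        else:
            _, script, _ = part
            m = len(script)
            orient[pos : pos + m] = script
            pos += m

    if p.noise_sd_orient > 0:
        orient = orient + rng.standard_normal(n) * p.noise_sd_orient
    head = th + BODY_LENGTH_CM * _unit(orient)
    if p.noise_sd_pos > 0:
        th = th + rng.standard_normal((n, 2)) * p.noise_sd_pos
        head = head + rng.standard_normal((n, 2)) * p.noise_sd_pos

    traj = Trajectory(
        frame_index=np.arange(n), head=head, thorax=th,
        frame_rate=frame_rate, label=label,
    )
    bouts = tuple(
        BoutTruth(start_t=s, end_t=e, n_fixations=nf)
        for (s, e), nf in zip(truth, bout_nfix)
    )
    return traj, bouts


def gen_learning_walk(p: WalkGenParams | None = None) -> tuple[Trajectory, GroundTruth]:
    """One naive learning walk: a loop from and back to the nest with scans.

    The loop is a teardrop r(phi) = R sin(phi/2) around the nest (leaves and
    re-enters at the origin), traversed at the commanded speed with AR(1)
    speed variability and a smooth perpendicular wobble that vanishes at the
    endpoints, so the walk starts and ends within 1 cm of the nest.
    ``n_scan_bouts`` stationary scanning bouts are spliced in at random arc
    positions.
    """
    p = p or learning_params()
    if p.kind != "learning":
        raise ParameterError("gen_learning_walk needs kind='learning'")
    rng = np.random.default_rng(p.seed)
    R = p.loop_radius
    theta0 = rng.uniform(0.0, 360.0)
    direction = rng.choice([-1.0, 1.0])

    # dense teardrop curve (laterally squeezed so the hull stays slim) with
    # smooth perpendicular wobble (zero at endpoints)
    phi = np.linspace(0.0, 2.0 * np.pi, 4096)
    r = R * np.sin(phi / 2.0)
    az = theta0 + direction * np.degrees(phi)
    pts = r[:, None] * _unit(az)
    e_r = _unit(theta0)
    e_p = np.array([-e_r[1], e_r[0]])
    dense = (pts @ e_r)[:, None] * e_r + p.loop_aspect * (pts @ e_p)[:, None] * e_p
    seg = np.hypot(*np.diff(dense, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    wob = _fourier_wobble(rng, arc, total, p.path_wobble)
    d = np.gradient(dense, axis=0)
    norm = np.hypot(d[:, 0], d[:, 1])
    norm[norm == 0] = 1.0
    perp = np.column_stack([-d[:, 1], d[:, 0]]) / norm[:, None]
    dense = dense + perp * wob[:, None]

    thorax = _resample_arc(dense, p, rng)
    seg_f = np.hypot(*np.diff(thorax, axis=0).T)
    total = float(seg_f.sum())

    dstep = np.diff(thorax, axis=0)
    travel = azimuth_deg(dstep[:, 0], dstep[:, 1])
    travel = np.degrees(np.unwrap(np.radians(travel)))
    travel = np.concatenate([travel, travel[-1:]])

    n_walk = len(thorax)
    k = int(p.n_scan_bouts)
    if k > 0:
        # bout locations spaced >= 3 cm along the arc so bouts never merge
        min_frac = min(3.0 / total, 0.6 / k)
        for _ in range(200):
            fracs = np.sort(rng.uniform(0.15, 0.85, size=k))
            if k == 1 or np.diff(fracs).min() >= min_frac:
                break
        else:
            fracs = np.linspace(0.2, 0.8, k)
        idxs = np.minimum((fracs * n_walk).astype(int), n_walk - 2)
        spans = [int(i) for i in np.unique(idxs)]
        scripts, nfix = [], []
        for i in spans:
            script, nf = _bout_orientation_script(rng, travel[i], p.frame_rate)
            scripts.append(script)
            nfix.append(nf)
    else:
        spans, scripts, nfix = [], [], []

    traj, bouts = _assemble(p.frame_rate, thorax, travel, spans, scripts, nfix,
                            p, rng, "learning")
    truth = GroundTruth(
        kind="learning",
        commanded_speed=p.speed_mean,
        max_excursion=float(np.hypot(*thorax.T).max()),
        bouts=bouts,
    )
    return traj, truth


def gen_excavation_trip(p: WalkGenParams | None = None) -> tuple[Trajectory, GroundTruth]:
    """One excavation trip: straight out, drop the sand, straight back.

    The drop distance is uniform on ``excavation_range`` (default 5-10 cm).
    Heading jitter is AR(1) with stationary spread 1/sqrt(turn_kappa)
    radians about the target bearing; at the default concentration the
    outbound leg has straightness above 0.98.  No stops, no scanning.
    """
    p = p or excavation_params()
    if p.kind != "excavation":
        raise ParameterError("gen_excavation_trip needs kind='excavation'")
    rng = np.random.default_rng(p.seed)
    bearing = rng.uniform(0.0, 360.0)
    drop = float(rng.uniform(*p.excavation_range))
    drop = min(drop, p.max_excursion)
    # dense path shape: fine steps with AR(1) heading jitter about the target
    # bearing (out) / the nest-ward bearing (back); stationary heading spread
    # is 1/sqrt(turn_kappa) radians
    ds = 0.02  # cm per fine step
    frame_step = p.speed_mean / p.frame_rate
    rho_f = 0.8 ** (ds / frame_step)
    sd_head = np.degrees(1.0 / np.sqrt(p.turn_kappa))

    def leg(start, target_az_of, stop_when):
        pos = [start.copy()]
        dev = 0.0
        for _ in range(200000):
            dev = rho_f * dev + rng.standard_normal() * sd_head * np.sqrt(1 - rho_f**2)
            nxt = pos[-1] + ds * _unit(target_az_of(pos[-1]) + dev)
            pos.append(nxt)
            if stop_when(nxt):
                break
        return np.asarray(pos)

    out = leg(np.zeros(2), lambda q: bearing, lambda q: np.hypot(*q) >= drop)
    back = leg(out[-1], lambda q: azimuth_deg(-q[0], -q[1]), lambda q: np.hypot(*q) <= 0.3)
    # legs are framed independently so no video frame straddles the turn
    thorax = np.concatenate(
        [_resample_arc(out, p, rng), _resample_arc(back, p, rng)[1:]], axis=0
    )

    dstep = np.diff(thorax, axis=0)
    travel = azimuth_deg(dstep[:, 0], dstep[:, 1])
    travel = np.degrees(np.unwrap(np.radians(travel)))
    travel = np.concatenate([travel, travel[-1:]])

    traj, _ = _assemble(p.frame_rate, thorax, travel, [], [], [], p, rng, "excavation")
    truth = GroundTruth(
        kind="excavation",
        commanded_speed=p.speed_mean,
        max_excursion=float(np.hypot(*thorax.T).max()),
        drop_distance=drop,
    )
    return traj, truth


def gen_headings(n: int, mu: float, kappa: float, seed=None, condition: str = "") -> HeadingSet:
    """Seeded von Mises headings (deg); kappa = 0 is the uniform null."""
    if n < 1 or kappa < 0:
        raise ParameterError("need n >= 1 and kappa >= 0")
    rng = np.random.default_rng(seed)
    if kappa == 0:
        ang = rng.uniform(0.0, 360.0, size=n)
    else:
        ang = wrap_deg(np.degrees(rng.vonmises(np.radians(mu), kappa, size=n)))
    return HeadingSet(angles=ang, condition=condition)


# ---------------------------------------------------------------------------
# parametric landmark scenes and the panorama renderer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSpec:
    """Synthetic landmark scene around the nest.

    objects : (azimuth_deg from nest, distance_m from nest, width_m,
        height_m, albedo in [0,1]) per discrete landmark (bush/tree block).
    skyline : optional continuous vegetation line on a circle of radius
        ``skyline_dist`` centred on the nest; its height above ground is
        base + sum of a few Fourier modes of the world azimuth, so it
        shifts with correct parallax when rendered from displaced
        positions.  ``skyline_modes`` is a tuple of (k, amplitude_m,
        phase_rad).
    """

    objects: tuple = ()
    sky_level: float = 0.9
    ground_level: float = 0.5
    skyline_dist: float = 0.0  # m; 0 disables the skyline
    skyline_base: float = 2.0  # m
    skyline_modes: tuple = ()
    skyline_albedo: float = 0.2

    def __post_init__(self):
        for (_, d, w, h, a) in self.objects:
            if d <= 0 or w <= 0 or h <= 0:
                raise ParameterError("object distance/width/height must be > 0")
            if not 0.0 <= a <= 1.0:
                raise ParameterError("albedo must be in [0,1]")
        if self.skyline_dist < 0:
            raise ParameterError("skyline_dist must be >= 0")


def default_scene(seed=None, n_objects: int = 12) -> SceneSpec:
    """A cluttered semi-arid horizon: tussocks, bushes and trees.

    Most landmarks sit 5-30 m out (grass clumps, Acacia, Eucalyptus);
    a couple of near tussocks add foreground.  A predominantly distant
    skyline is what makes nest views generalize over a few metres of
    displacement.
    """
    rng = np.random.default_rng(seed)
    # the recording area and test corridors (out to ~9 m N and E) stay clear,
    # as the field site was cleared of vegetation around the nest
    clear = [np.array(q, dtype=float) for q in
             [(0.0, 0.0), (0.0, 2.0), (0.0, 4.0), (2.0, 0.0), (4.0, 0.0),
              (0.0, 6.0), (0.0, 8.0), (6.0, 0.0), (8.0, 0.0)]]
    objs = []
    for i in range(n_objects):
        for _ in range(50):
            if i < 2:  # near tussocks
                d = float(rng.uniform(2.5, 5.0))
                h = float(rng.uniform(0.3, 1.0))
            else:
                d = float(rng.uniform(8.0, 30.0))
                h = float(rng.uniform(1.5, 8.0))
            w = float(rng.uniform(0.5, min(4.0, 0.6 * d)))
            az = float(rng.uniform(0, 360))
            centre = d * _unit(az)
            if all(np.hypot(*(centre - q)) > w / 2.0 + 0.3 for q in clear):
                break
        objs.append((az, d, w, h, float(rng.uniform(0.05, 0.35))))
    modes = tuple(
        (k, float(rng.uniform(0.6, 3.0) / np.sqrt(k)), float(rng.uniform(0, 2 * np.pi)))
        for k in (1, 2, 3, 5, 8, 13)
    )
    return SceneSpec(objects=tuple(objs), skyline_dist=20.0, skyline_base=3.5,
                     skyline_modes=modes)


def render_panorama(
    scene: SceneSpec,
    position: tuple[float, float] = (0.0, 0.0),
    n_cols: int = 360,
    n_rows: int = 90,
) -> Panorama:
    """Render an equirectangular grayscale view of ``scene`` from ``position``.

    Rows map elevation from +90 deg (top) to -90 deg; the horizon sits at
    the middle.  Each object is drawn as a block of angular width
    2 atan(w / 2d) and angular height atan(h / d) at its bearing, nearer
    objects over farther ones.  Column 0 faces the nest-ward bearing (true
    North when rendering at the nest itself).
    """
    if n_cols < 1 or n_rows < 1:
        raise ParameterError("panorama grid must be non-degenerate")
    pos = np.asarray(position, dtype=float)
    for (azi, d, w, h, a) in scene.objects:
        obj = d * _unit(azi)
        if np.hypot(*(obj - pos)) <= w / 2.0:
            raise ParameterError("viewing position lies inside an object footprint")
    if np.hypot(*pos) > 0:
        h0 = float(azimuth_deg(-pos[0], -pos[1]))  # bearing toward the nest
    else:
        h0 = 0.0
    col_az = wrap_deg(h0 + np.arange(n_cols) * 360.0 / n_cols)
    elev = np.linspace(90.0, -90.0, n_rows, endpoint=False) - 90.0 / n_rows  # row centres
    img = np.where(elev[:, None] > 0, scene.sky_level, scene.ground_level) * np.ones(
        (n_rows, n_cols)
    )
    if scene.skyline_dist > 0:
        # ray from `pos` along each column azimuth to the skyline circle
        # (radius skyline_dist about the nest): correct parallax by construction
        u = _unit(col_az)  # (n_cols, 2)
        pu = u @ pos
        disc2 = pu**2 + scene.skyline_dist**2 - float(pos @ pos)
        t = -pu + np.sqrt(np.maximum(disc2, 0.0))  # distance to the vegetation line
        hit = pos[None, :] + t[:, None] * u
        theta = np.radians(azimuth_deg(hit[:, 0], hit[:, 1]))
        height = np.full(n_cols, scene.skyline_base)
        for k, amp, phase in scene.skyline_modes:
            height = height + amp * np.sin(k * theta + phase)
        ang_h = np.degrees(np.arctan(np.maximum(height, 0.0) / t))
        veg = (elev[:, None] > 0) & (elev[:, None] <= ang_h[None, :])
        img[veg] = scene.skyline_albedo
    order = sorted(scene.objects, key=lambda o: -np.hypot(*(o[1] * _unit(o[0]) - pos)))
    for (azi, d, w, h, albedo) in order:
        obj = d * _unit(azi)
        v = obj - pos
        dist = float(np.hypot(*v))
        b = float(azimuth_deg(v[0], v[1]))
        half_w = np.degrees(np.arctan(w / (2.0 * dist)))
        ang_h = np.degrees(np.arctan(h / dist))
        dcol = np.abs(np.angle(np.exp(1j * np.radians(col_az - b))))
        cols = dcol <= np.radians(half_w)
        rows = (elev > 0) & (elev <= ang_h)
        img[np.ix_(rows, cols)] = albedo
    return Panorama(intensity=np.clip(img, 0.0, 1.0), heading_of_col0=h0)


# ---------------------------------------------------------------------------
# full synthetic experiment
# ---------------------------------------------------------------------------

DISPLACEMENT_POSITIONS = {  # metres, map frame (+x East, +y North)
    "2mN": (0.0, 2.0),
    "2mE": (2.0, 0.0),
    "4mN": (0.0, 4.0),
    "4mE": (4.0, 0.0),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of the synthetic study (the paper-like default)."""

    n_ants: int = 20
    n_excavation_trips: int = 3
    heading_n_per_condition: int = 20
    heading_kappa_2m: float = 3.0
    heading_kappa_4m: float = 0.0
    heading_mu: float = 0.0  # nestward
    scale_cm_per_px: float = 0.026  # ~1 m recording area over 3860 px
    nest_pixel: tuple[float, float] = (1930.0, 1080.0)
    frame_rate: float = 25.0
    seed: int = 0


def _child(seed, *idx):
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([int(seed)] + [int(i) for i in idx])
    return int(ss.generate_state(1)[0] % (2**31))


def gen_experiment_walks(cfg: ExperimentConfig):
    """Yield (ant_id, condition, Trajectory, GroundTruth) for the full design."""
    for a in range(cfg.n_ants):
        ant = f"ant{a:02d}"
        rng = np.random.default_rng(_child(cfg.seed, 1, a))
        lw = learning_params(
            n_scan_bouts=int(rng.integers(1, 4)),
            loop_radius=float(rng.uniform(7.0, 10.0)),
            speed_mean=float(rng.uniform(2.2, 3.0)),
            frame_rate=cfg.frame_rate,
            seed=_child(cfg.seed, 2, a),
        )
        traj, truth = gen_learning_walk(lw)
        yield ant, "LW", traj.with_label("learning", ant), truth
        for e in range(cfg.n_excavation_trips):
            ex = excavation_params(
                speed_mean=float(rng.uniform(4.5, 5.5)),
                frame_rate=cfg.frame_rate,
                seed=_child(cfg.seed, 3, a, e),
            )
            traj, truth = gen_excavation_trip(ex)
            yield ant, f"E{e + 1}", traj.with_label("excavation", ant), truth


def gen_experiment_headings(cfg: ExperimentConfig) -> dict[str, HeadingSet]:
    """Final-heading sets per displacement condition (2 m oriented, 4 m not)."""
    out = {}
    for i, cond in enumerate(DISPLACEMENT_POSITIONS):
        kappa = cfg.heading_kappa_2m if cond.startswith("2") else cfg.heading_kappa_4m
        out[cond] = gen_headings(
            cfg.heading_n_per_condition, cfg.heading_mu, kappa,
            seed=_child(cfg.seed, 4, i), condition=cond,
        )
    return out


def gen_experiment(cfg: ExperimentConfig, out_dir) -> Path:
    """Write the full synthetic study input tree consumed by the pipeline.

    ``walks/`` pixel tracking tables (one per ant x condition),
    ``headings.csv``, ``panoramas/`` PNG renders (nest + 4 test sites),
    ``ground_truth.json`` and ``config.yaml``.  Byte-identical under the
    same seed.
    """
    import pandas as pd
    import yaml

    from .panorama import save_panorama
    from .trajectory import write_tracking_table

    out = Path(out_dir)
    (out / "walks").mkdir(parents=True, exist_ok=True)
    (out / "panoramas").mkdir(parents=True, exist_ok=True)

    truth: dict = {"walks": {}, "headings": {}, "scene": None}
    for ant, cond, traj, gt in gen_experiment_walks(cfg):
        fname = f"{ant}_{cond}.csv"
        write_tracking_table(
            traj, out / "walks" / fname,
            scale=cfg.scale_cm_per_px, nest_pixel=cfg.nest_pixel,
        )
        truth["walks"][fname] = gt.as_dict()

    rows = []
    for cond, hs in gen_experiment_headings(cfg).items():
        kappa = cfg.heading_kappa_2m if cond.startswith("2") else cfg.heading_kappa_4m
        truth["headings"][cond] = {"mu": cfg.heading_mu, "kappa": kappa, "n": hs.n}
        for i, ang in enumerate(hs.angles):
            rows.append({"ant_id": f"ant{i:02d}", "condition": cond, "angle_deg": ang})
    pd.DataFrame(rows).to_csv(out / "headings.csv", index=False, float_format="%.12g")

    scene = default_scene(seed=_child(cfg.seed, 5))
    truth["scene"] = asdict(scene)
    positions = {"nest": (0.0, 0.0), **DISPLACEMENT_POSITIONS}
    pano_meta = {}
    for name, posn in positions.items():
        pano = render_panorama(scene, posn)
        save_panorama(pano, out / "panoramas" / f"{name}.png")
        pano_meta[name] = {"position_m": list(posn), "heading_of_col0": pano.heading_of_col0}
    truth["panoramas"] = pano_meta

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    config = {
        "frame_rate": cfg.frame_rate,
        "scale_cm_per_px": cfg.scale_cm_per_px,
        "nest_pixel": list(cfg.nest_pixel),
        "flip_y": True,
        "seed": cfg.seed,
        "walks_dir": "walks",
        "headings_csv": "headings.csv",
        "panoramas_dir": "panoramas",
        "reference_panorama": "nest.png",
        "panoramas": pano_meta,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return out
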
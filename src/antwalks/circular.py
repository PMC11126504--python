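"""Circular statistics for displacement-test headings.

Final headings are expressed relative to the nest direction (nest = 0°,
azimuths compass-style) and analysed with the classical circular battery:

* Rayleigh test of uniformity (mean resultant length),
* V test against a prespecified target direction,
* 95% confidence interval of the mean direction (Fisher's dispersion-based
  interval, with a seeded bootstrap fallback for diffuse samples) and the
  wrap-aware check whether the target lies inside it,
* Watson–Williams two-sample comparison of mean directions,
* single-sample von Mises likelihood-ratio test of the mean direction.

Angles are degrees at the API surface and radians internally.  kappa is
estimated by numerically inverting A(kappa) = I1(kappa)/I0(kappa) at the
mean resultant length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .angles import angle_in_arc, azimuth_deg, wrap_deg
from .errors import DataError, InsufficientDataError
from .trajectory import Trajectory

N_WEDGES = 24  # 15° sectors for circular histograms

_RBAR_DIFFUSE = 0.45  # below this the von Mises CI / Watson-Williams assumptions weaken


@dataclass(frozen=True)
class HeadingSet:
    """Final headings (deg, nest direction = 0°) for one displacement condition."""

    angles: np.ndarray
    condition: str = ""

    def __post_init__(self):
        a = wrap_deg(np.asarray(self.angles, dtype=float))
        if a.ndim != 1 or a.size < 1:
            raise InsufficientDataError("HeadingSet needs at least one angle")
        if not np.isfinite(a).all():
            raise DataError("non-finite heading angle")
        object.__setattr__(self, "angles", a)

    @property
    def n(self) -> int:
        return self.angles.size

    @property
    def radians(self) -> np.ndarray:
        return np.radians(self.angles)


@dataclass(frozen=True)
class CircTestResult:
    """Result container shared by the whole battery; unused fields stay None."""

    test: str
    n: int
    mu: float | None = None  # mean direction, deg
    rbar: float | None = None  # mean resultant length
    ci_lo: float | None = None  # deg
    ci_hi: float | None = None  # deg
    z: float | None = None  # test statistic (Rayleigh Z, V-test u, W-W F)
    p: float | None = None
    kappa: float | None = None  # von Mises concentration
    chi2: float | None = None  # likelihood-ratio statistic
    df: tuple | None = None
    flags: tuple = field(default_factory=tuple)


def circ_mean_rbar(rad: np.ndarray) -> tuple[float, float]:
    """Mean direction (radians) and mean resultant length of a circular sample."""
    C, S = np.cos(rad).mean(), np.sin(rad).mean()
    return float(np.arctan2(S, C)), float(np.hypot(C, S))


def kappa_mle(rbar: float, n: int | None = None) -> float:
    """ML estimate of the von Mises concentration from the resultant length.

    Numerically inverts A(kappa) = I1/I0 = rbar (Brent); returns 0 for
    rbar <= 0 and a large finite value as rbar -> 1.
    """
    if rbar <= 1e-10:
        return 0.0
    if rbar >= 1.0 - 1e-12:
        return 1e12
    f = lambda k: special.i1e(k) / special.i0e(k) - rbar
    hi = 2.0
    while f(hi) < 0 and hi < 1e9:
        hi *= 2.0
    return float(optimize.brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-14))


def final_heading(
    traj: Trajectory,
    release_point: tuple[float, float] = (0.0, 0.0),
    arena_radius: float = 50.0,
) -> tuple[float, bool]:
    """Heading (deg, nest = 0°) on the last frame inside the recording area.

    The heading is the thorax->head azimuth relative to the release->nest
    bearing, positive in the compass sense, wrapped to [0, 360).  If the
    ant never leaves the ``arena_radius`` circle around the release point,
    the final frame is used and the returned flag is True.
    """
    rel = np.hypot(traj.thorax[:, 0] - release_point[0], traj.thorax[:, 1] - release_point[1])
    outside = np.nonzero(rel > arena_radius)[0]
    if outside.size and outside[0] > 0:
        idx, flagged = int(outside[0]) - 1, False
    else:
        idx, flagged = traj.n_frames - 1, True
    axis = traj.head[idx] - traj.thorax[idx]
    heading_az = azimuth_deg(axis[0], axis[1])
    to_nest = np.asarray(traj.nest) - np.asarray(release_point, dtype=float)
    if np.hypot(*to_nest) == 0:
        raise DataError("release point coincides with the nest: nest bearing undefined")
    nest_az = azimuth_deg(to_nest[0], to_nest[1])
    return float(wrap_deg(heading_az - nest_az)), flagged


def wedge_histogram(h: HeadingSet) -> np.ndarray:
    """Counts per 15° wedge, half-open bins [k*15, (k+1)*15); sums to n."""
    counts, _ = np.histogram(h.angles, bins=np.linspace(0.0, 360.0, N_WEDGES + 1))
    return counts


def rayleigh_test(h: HeadingSet) -> CircTestResult:
    """Rayleigh test of circular uniformity.

    Z = n * rbar^2, p by the standard series approximation
    p = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)].
    """
    if h.n < 2:
        raise InsufficientDataError("Rayleigh test needs n >= 2")
    mu, rbar = circ_mean_rbar(h.radians)
    n = h.n
    Z = n * rbar**2
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z**2) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n**2)
    )
    return CircTestResult(
        test="rayleigh", n=n, mu=wrap_deg(np.degrees(mu)), rbar=rbar, z=float(Z),
        p=float(np.clip(p, 0.0, 1.0)),
    )


def v_test(h: HeadingSet, target: float) -> CircTestResult:
    """V test: uniformity test with power focused on a prespecified direction.

    V = rbar * cos(mu - target); u = V * sqrt(2n); one-sided p from the
    normal approximation to u.
    """
    if h.n < 2:
        raise InsufficientDataError("V test needs n >= 2")
    mu, rbar = circ_mean_rbar(h.radians)
    V = rbar * np.cos(mu - np.radians(target))
    u = V * np.sqrt(2.0 * h.n)
    return CircTestResult(
        test="v", n=h.n, mu=wrap_deg(np.degrees(mu)), rbar=rbar, z=float(u),
        p=float(stats.norm.sf(u)),
    )


def mean_ci(
    h: HeadingSet,
    confidence: float = 0.95,
    method: str = "fisher",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float, float, tuple]:
    """Confidence interval for the mean direction.

    Fisher's dispersion-based interval by default: the circular standard
    error is sqrt(dispersion / n) with dispersion
    (1 - rho2) / (2 rbar^2), rho2 the mean of cos 2(theta - mu);
    half-width = arcsin(t_{alpha/2, n-1} * se).  The t quantile (rather
    than the normal z) is a small-sample correction: the dispersion is
    estimated from the same sample, and with the plain z the interval
    under-covers at the n of a typical displacement condition.
    ``method="bootstrap"`` uses a seeded percentile bootstrap of the mean
    direction instead (preferred for diffuse samples, rbar < 0.45).

    Returns (mu_deg, ci_lo_deg, ci_hi_deg, flags); a sample too diffuse for
    either interval yields a flagged full-circle interval.
    """
    rad = h.radians
    mu, rbar = circ_mean_rbar(rad)
    mu_deg = wrap_deg(np.degrees(mu))
    flags: list[str] = []
    if rbar < 1e-9:
        return mu_deg, wrap_deg(mu_deg - 180.0), wrap_deg(mu_deg + 180.0), ("ci_full_circle",)
    if np.allclose(wrap_deg(h.angles - h.angles[0]), 0.0):
        return mu_deg, mu_deg, mu_deg, ("ci_zero_width",)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, h.n, size=(n_boot, h.n))
        boot = rad[idx]
        mus = np.arctan2(np.sin(boot).mean(axis=1), np.cos(boot).mean(axis=1))
        # percentile interval on deviations from the sample mean (wrap-safe)
        dev = np.degrees(np.angle(np.exp(1j * (mus - mu))))
        alpha = 1.0 - confidence
        lo, hi = np.quantile(dev, [alpha / 2.0, 1.0 - alpha / 2.0])
        return mu_deg, wrap_deg(mu_deg + lo), wrap_deg(mu_deg + hi), ("ci_bootstrap",)
    if method != "fisher":
        raise ValueError(f"unknown CI method {method!r}")
    if rbar < _RBAR_DIFFUSE:
        flags.append("ci_diffuse_sample")
    rho2 = float(np.cos(2.0 * (rad - mu)).mean())
    dispersion = (1.0 - rho2) / (2.0 * rbar**2)
    se = np.sqrt(dispersion / h.n)
    zq = stats.t.ppf(0.5 + confidence / 2.0, h.n - 1)
    if zq * se >= 1.0:
        return mu_deg, wrap_deg(mu_deg - 180.0), wrap_deg(mu_deg + 180.0), ("ci_full_circle",)
    half = np.degrees(np.arcsin(zq * se))
    return mu_deg, wrap_deg(mu_deg - half), wrap_deg(mu_deg + half), tuple(flags)


def mean_ci_test(
    h: HeadingSet,
    target: float = 0.0,
    confidence: float = 0.95,
    method: str = "fisher",
    seed: int | None = None,
) -> tuple[CircTestResult, bool]:
    """CI-inclusion check: does ``target`` lie inside the 95% CI of the mean?

    This is the procedure reported as the "Watson test" for nestward
    orientation: compute the CI of the mean heading and ask whether the
    nest direction (0°) falls inside it, wrap-aware.
    """
    if h.n < 5:
        raise InsufficientDataError("mean-direction CI needs n >= 5")
    mu_deg, lo, hi, flags = mean_ci(h, confidence=confidence, method=method, seed=seed)
    _, rbar = circ_mean_rbar(h.radians)
    inside = angle_in_arc(target, lo, hi)
    if "ci_full_circle" in flags:
        inside = True
    res = CircTestResult(
        test="mean_ci", n=h.n, mu=mu_deg, rbar=rbar, ci_lo=float(lo), ci_hi=float(hi),
        flags=flags,
    )
    return res, bool(inside)


def watson_williams_test(h1: HeadingSet, h2: HeadingSet) -> CircTestResult:
    """Watson–Williams two-sample test for equal mean directions.

    F = g * (N-2)(R1 + R2 - R) / (N - R1 - R2) with the kappa-based
    correction g = 1 + 3/(8 kappa_hat); p from F(1, N-2).  Assumes both
    samples are unimodal and reasonably concentrated; a pooled rbar below
    0.45 is flagged.
    """
    if h1.n < 5 or h2.n < 5:
        raise InsufficientDataError("Watson–Williams needs n >= 5 per sample")
    r1, r2 = h1.radians, h2.radians
    n1, n2 = h1.n, h2.n
    N = n1 + n2
    _, rbar1 = circ_mean_rbar(r1)
    _, rbar2 = circ_mean_rbar(r2)
    R1, R2 = n1 * rbar1, n2 * rbar2
    _, rbar_all = circ_mean_rbar(np.concatenate([r1, r2]))
    R = N * rbar_all
    rbar_w = (R1 + R2) / N
    flags: list[str] = []
    if rbar_w < _RBAR_DIFFUSE:
        flags.append("ww_diffuse_assumption")
    kappa = kappa_mle(rbar_w)
    g = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = N - R1 - R2
    F = 0.0 if denom <= 0 else float(g * (N - 2) * max(R1 + R2 - R, 0.0) / denom)
    p = float(stats.f.sf(F, 1, N - 2))
    mu1 = wrap_deg(np.degrees(circ_mean_rbar(r1)[0]))
    return CircTestResult(
        test="watson_williams", n=N, mu=mu1, rbar=rbar_w, z=F, p=p, kappa=kappa,
        df=(1, N - 2), flags=tuple(flags),
    )


def _vm_loglik(rad: np.ndarray, mu: float, kappa: float) -> float:
    return float(kappa * np.cos(rad - mu).sum() - rad.size * (np.log(2.0 * np.pi) + np.log(special.i0e(kappa)) + kappa))


def vonmises_lrt(h: HeadingSet, target: float) -> CircTestResult:
    """Single-sample von Mises likelihood-ratio test of the mean direction.

    Fits (mu, kappa) by maximum likelihood, then refits with mu fixed at
    ``target``; chi2 = 2 (l_free - l_constrained), p from chi-squared with
    1 df.  Returns the unconstrained kappa estimate.  Nearly-uniform
    samples (kappa ~ 0) make the test degenerate and are flagged.
    """
    if h.n < 5:
        raise InsufficientDataError("von Mises LRT needs n >= 5")
    rad = h.radians
    mu_hat, rbar = circ_mean_rbar(rad)
    kappa_free = kappa_mle(rbar, h.n)
    t = np.radians(target)
    c_target = float(np.cos(rad - t).mean())
    kappa_con = kappa_mle(c_target) if c_target > 0 else 0.0
    chi2 = 2.0 * (_vm_loglik(rad, mu_hat, kappa_free) - _vm_loglik(rad, t, kappa_con))
    chi2 = max(chi2, 0.0)
    flags = ("lrt_degenerate_uniform",) if kappa_free < 1e-6 else ()
    return CircTestResult(
        test="vonmises_lrt", n=h.n, mu=wrap_deg(np.degrees(mu_hat)), rbar=rbar,
        chi2=float(chi2), p=float(stats.chi2.sf(chi2, 1)), kappa=float(kappa_free),
        df=(1,), flags=flags,
    )


def condition_summary(h: HeadingSet, target: float = 0.0, seed: int | None = None) -> dict:
    """Table-1-style row for one displacement condition.

    Mean vector with 95% CI, Rayleigh Z and p, V-test u and p against the
    target direction, CI-inclusion of the target, and the von Mises LRT
    chi2, kappa and p.
    """
    ray = rayleigh_test(h)
    v = v_test(h, target)
    ci_res, inside = mean_ci_test(h, target=target, seed=seed)
    lrt = vonmises_lrt(h, target)
    return {
        "condition": h.condition,
        "n": h.n,
        "mu": ray.mu,
        "rbar": ray.rbar,
        "ci_lo": ci_res.ci_lo,
        "ci_hi": ci_res.ci_hi,
        "target_in_ci": inside,
        "rayleigh_z": ray.z,
        "rayleigh_p": ray.p,
        "v_u": v.z,
        "v_p": v.p,
        "lrt_chi2": lrt.chi2,
        "lrt_kappa": lrt.kappa,
        "lrt_p": lrt.p,
    }
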
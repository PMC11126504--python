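"""Condition-comparison statistics for walk metrics.

The experimental design is complete repeated measures: every ant performs
one learning walk (LW) and three excavation trips (E1, E2, E3), and every
ant is tested at all four displacement sites.  Planned Helmert contrasts
across the four walk conditions are therefore evaluated *exactly* within
ants: each ant contributes one contrast value, and a one-sample t test of
those values against zero replaces mixed-model machinery while preserving
the repeated-measures structure.  Bounded (0, 1) metrics (straightness,
sinuosity) are logit-transformed before contrast testing.

Also provided: Welch's one-way ANOVA (for heteroscedastic groups), Welch's
two-sample t test, Tukey-adjusted within-ant pairwise comparisons, and a
seeded bootstrap of a difference in means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError

WALK_CONDITIONS = ["LW", "E1", "E2", "E3"]
DISPLACEMENT_SITES = ["2mN", "2mE", "4mN", "4mE"]

ALPHA_WALKS = 0.01  # multi-metric walk comparisons
ALPHA_CIRCULAR = 0.05  # circular battery

BOUNDED_METRICS = ("straightness", "sinuosity")
_LOGIT_CLIP = (1e-6, 1.0 - 1e-6)


@dataclass(frozen=True)
class ContrastResult:
    contrast_id: str
    estimate: float  # mean within-ant contrast value (or mean difference)
    statistic: float  # t or F
    df: float | tuple
    p: float
    n: int
    flags: tuple = ()


def helmert_contrasts(levels: list[str] | None = None) -> dict[str, np.ndarray]:
    """Forward Helmert coefficients for exactly 4 ordered levels.

    c1 compares level 1 with the mean of levels 2–4 (LW vs all excavation
    trips), c2 level 2 with the mean of 3–4, c3 level 3 with level 4.
    Rows are mutually orthogonal and sum to zero.
    """
    levels = WALK_CONDITIONS if levels is None else list(levels)
    if len(levels) != 4:
        raise ParameterError(f"Helmert scheme here is for 4 levels, got {len(levels)}")
    return {
        f"{levels[0]} vs {'+'.join(levels[1:])}": np.array([1.0, -1 / 3, -1 / 3, -1 / 3]),
        f"{levels[1]} vs {'+'.join(levels[2:])}": np.array([0.0, 1.0, -0.5, -0.5]),
        f"{levels[2]} vs {levels[3]}": np.array([0.0, 0.0, 1.0, -1.0]),
    }


def logit_bounded(x: np.ndarray) -> np.ndarray:
    """Logit transform for (0,1)-bounded metrics, clamped away from {0, 1}."""
    x = np.clip(np.asarray(x, dtype=float), *_LOGIT_CLIP)
    return np.log(x / (1.0 - x))


def _complete_wide(table: pd.DataFrame, metric: str, conditions: list[str]) -> pd.DataFrame:
    """ant_id x condition matrix of one metric, dropping incomplete ants."""
    for col in ("ant_id", "condition", metric):
        if col not in table.columns:
            raise ParameterError(f"metrics table lacks column {col!r}")
    wide = table.pivot_table(index="ant_id", columns="condition", values=metric)
    missing_cond = [c for c in conditions if c not in wide.columns]
    if missing_cond:
        raise InsufficientDataError(f"conditions absent from table: {missing_cond}")
    wide = wide[conditions]
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} ant(s) without all conditions: "
            f"{list(incomplete)}", stacklevel=3,
        )
        wide = wide.dropna()
    if len(wide) < 3:
        raise InsufficientDataError(
            f"need >= 3 ants with complete data, have {len(wide)}"
        )
    return wide


def repeated_contrast_test(
    table: pd.DataFrame,
    metric: str,
    contrast: np.ndarray,
    contrast_id: str = "",
    conditions: list[str] | None = None,
    logit: bool | None = None,
) -> ContrastResult:
    """Exact within-ant contrast test.

    Each complete ant contributes sum(coef * metric) across conditions; a
    one-sample t test (two-sided) asks whether the mean contrast is zero.
    F = t^2 is reported alongside.  ``logit=None`` auto-applies the logit
    transform for bounded metrics.
    """
    conditions = conditions or WALK_CONDITIONS
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (len(conditions),):
        raise ParameterError("contrast length must match the number of conditions")
    wide = _complete_wide(table, metric, conditions)
    vals = wide.to_numpy(float)
    flags: tuple = ()
    if logit is None:
        logit = metric in BOUNDED_METRICS
    if logit:
        vals = logit_bounded(vals)
        flags = ("logit_transformed",)
    per_ant = vals @ contrast
    n = per_ant.size
    if np.allclose(per_ant.std(ddof=1), 0.0):
        # all ants identical under this contrast: estimate is exact
        est = float(per_ant.mean())
        p = 1.0 if np.isclose(est, 0.0) else 0.0
        return ContrastResult(contrast_id, est, 0.0 if p == 1.0 else np.inf,
                              n - 1, p, n, flags + ("zero_variance",))
    t_res = stats.ttest_1samp(per_ant, 0.0)
    return ContrastResult(
        contrast_id=contrast_id,
        estimate=float(per_ant.mean()),
        statistic=float(t_res.statistic),
        df=n - 1,
        p=float(t_res.pvalue),
        n=n,
        flags=flags,
    )


def helmert_table(
    table: pd.DataFrame, metric: str, conditions: list[str] | None = None
) -> list[ContrastResult]:
    """All three planned Helmert contrasts for one metric."""
    conditions = conditions or WALK_CONDITIONS
    return [
        repeated_contrast_test(table, metric, coef, contrast_id=cid, conditions=conditions)
        for cid, coef in helmert_contrasts(conditions).items()
    ]


def welch_anova(groups: list[np.ndarray]) -> ContrastResult:
    """Welch's one-way ANOVA for k groups with unequal variances.

    F* = sum(w_j (m_j - m_w)^2) / (k-1) / [1 + 2(k-2)/(k^2-1) sum_h] with
    w_j = n_j / s_j^2 and Welch–Satterthwaite denominator df.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(g.size < 2 for g in groups):
        raise InsufficientDataError("Welch ANOVA needs k >= 2 groups with n >= 2")
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    flags: tuple = ()
    if (v == 0).any():
        if np.allclose(m, m[0]):
            return ContrastResult("welch_anova", 0.0, 0.0, (k - 1, np.inf), 1.0,
                                  int(n.sum()), ("zero_variance",))
        flags = ("zero_variance",)
        v = np.where(v == 0, 1e-300, v)
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    h = ((1.0 - w / w.sum()) ** 2 / (n - 1)).sum()
    den = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * h
    F = num / den
    df2 = (k**2 - 1.0) / (3.0 * h)
    p = float(stats.f.sf(F, k - 1, df2))
    return ContrastResult("welch_anova", float(np.ptp(m)), float(F), (k - 1, float(df2)),
                          p, int(n.sum()), flags)


def welch_t_test(a: np.ndarray, b: np.ndarray) -> ContrastResult:
    """Welch's two-sample t test (unequal variances, Welch–Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("Welch t test needs n >= 2 per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return ContrastResult("welch_t", 0.0, 0.0, a.size + b.size - 2, 1.0,
                                  a.size + b.size, ("zero_variance",))
        return ContrastResult("welch_t", float(a.mean() - b.mean()), np.inf,
                              a.size + b.size - 2, 0.0, a.size + b.size, ("zero_variance",))
    res = stats.ttest_ind(a, b, equal_var=False)
    return ContrastResult(
        contrast_id="welch_t",
        estimate=float(a.mean() - b.mean()),
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        n=a.size + b.size,
    )


def tukey_pairwise(
    table: pd.DataFrame, metric: str, conditions: list[str] | None = None
) -> list[ContrastResult]:
    """Within-ant pairwise comparisons with Tukey (studentized-range) adjustment.

    Uses the repeated-measures error term: MS_error from the ant x condition
    interaction, df = (k-1)(n-1); q = |mean_i - mean_j| / sqrt(MS_error / n)
    referred to the studentized range with k groups.
    """
    conditions = conditions or WALK_CONDITIONS
    wide = _complete_wide(table, metric, conditions)
    vals = wide.to_numpy(float)
    if metric in BOUNDED_METRICS:
        vals = logit_bounded(vals)
    n, k = vals.shape
    grand = vals.mean()
    ant_means = vals.mean(axis=1, keepdims=True)
    cond_means = vals.mean(axis=0, keepdims=True)
    resid = vals - ant_means - cond_means + grand
    df_err = (k - 1) * (n - 1)
    ms_err = float((resid**2).sum() / df_err)
    se = np.sqrt(ms_err / n)
    out: list[ContrastResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(vals[:, i].mean() - vals[:, j].mean())
            if se == 0:
                q = 0.0 if np.isclose(diff, 0.0) else np.inf
                p = 1.0 if q == 0.0 else 0.0
                flags = ("zero_variance",)
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_err))
                flags = ()
            out.append(
                ContrastResult(
                    contrast_id=f"{conditions[i]} vs {conditions[j]}",
                    estimate=diff, statistic=float(q), df=(k, df_err),
                    p=min(p, 1.0), n=n, flags=flags,
                )
            )
    return out


def bootstrap_mean_diff(
    a: np.ndarray, b: np.ndarray, n_boot: int = 2000, seed: int | None = None,
    confidence: float = 0.95,
) -> dict:
    """Seeded nonparametric bootstrap of mean(a) - mean(b).

    Returns the observed difference, the bootstrap mean, and the percentile
    interval at the requested confidence.
    """
    if n_boot < 1000:
        raise ParameterError("use n_boot >= 1000 for stable percentile intervals")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    boots = (
        a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
        - b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    )
    alpha = 1.0 - confidence
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return {
        "mean_diff": float(a.mean() - b.mean()),
        "boot_mean": float(boots.mean()),
        "ci_lo": float(lo),
        "ci_hi": float(hi),
        "n_boot": n_boot,
        "confidence": confidence,
    }


def results_table(results: list[ContrastResult], metric: str, alpha: float) -> pd.DataFrame:
    """Flat report rows (metric, contrast, estimate, statistic, df, p, alpha, decision)."""
    return pd.DataFrame(
        [
            {
                "metric": metric,
                "contrast": r.contrast_id,
                "estimate": r.estimate,
                "statistic": r.statistic,
                "df": str(r.df),
                "p": r.p,
                "alpha": alpha,
                "significant": r.p < alpha,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )
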
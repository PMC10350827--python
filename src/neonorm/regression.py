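"""Regression toolkit for deviation z-scores.

Provides simple linear (OLS) regression with fit diagnostics, quantile
regression solved exactly as a linear program (tau = 0.25 / 0.5 / 0.75 by
convention: quartile and median regression), an AIC for median regression
under the asymmetric-Laplace working likelihood, the extra sum-of-squares
F-test comparing slopes and intercepts (elevations) of two groups, and
whole-brain-volume (WBV) adjusted group median z-scores.

The extra sum-of-squares test is hierarchical: first, separate lines per
group are compared against a shared-slope model (slope test); only
conditional on a shared slope is the shared-slope model compared against a
single pooled line (intercept / elevation test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import linprog

__all__ = [
    "RegressionResult",
    "SlopeComparisonResult",
    "ols_fit",
    "quantile_fit",
    "check_loss",
    "median_aic",
    "extra_ss_ftest",
    "wbv_adjusted_median",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    f_statistic: float
    p_value: float
    n: int
    quantile_fits: list = field(default_factory=list)  # (tau, slope, intercept)
    aic_median: float | None = None


@dataclass
class SlopeComparisonResult:
    measure_name: str
    f_slope: float
    p_slope: float
    f_intercept: float
    p_intercept: float
    chosen_model: str  # separate | shared-slope | shared


def _clean_xy(x, y, min_n):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def ols_fit(x, y) -> RegressionResult:
    """Simple linear regression with R^2, adjusted R^2 and the overall F-test."""
    x, y = _clean_xy(x, y, 3)
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    n = x.size
    res = sps.linregress(x, y)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    # overall F for one predictor is t^2 with (1, n-2) df
    with np.errstate(divide="ignore"):
        f = np.inf if res.stderr == 0 else (res.slope / res.stderr) ** 2
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(r2), adj_r2=float(adj), f_statistic=float(f),
                            p_value=float(res.pvalue), n=n)


def check_loss(residuals, tau: float) -> float:
    """Total tau-weighted absolute-residual (pinball) loss."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(np.where(r >= 0, tau * r, (tau - 1.0) * r)))


def quantile_fit(x, y, tau: float) -> tuple[float, float]:
    """Quantile regression line minimizing the check loss, as an exact LP.

    Decision variables: split intercept/slope (a+, a-, b+, b-) and residual
    parts (u, v >= 0) with y = a + b x + u - v; objective tau*u + (1-tau)*v.
    Returns (slope, intercept).
    """
    x, y = _clean_xy(x, y, 5)
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    n = x.size
    # columns: a+, a-, b+, b-, u (n), v (n)
    c = np.concatenate([[0.0, 0.0, 0.0, 0.0], np.full(n, tau), np.full(n, 1.0 - tau)])
    A = np.zeros((n, 4 + 2 * n))
    A[:, 0] = 1.0
    A[:, 1] = -1.0
    A[:, 2] = x
    A[:, 3] = -x
    A[:, 4:4 + n] = np.eye(n)
    A[:, 4 + n:] = -np.eye(n)
    res = linprog(c, A_eq=A, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    a = res.x[0] - res.x[1]
    b = res.x[2] - res.x[3]
    return float(b), float(a)


def median_aic(x, y, slope: float, intercept: float, tau: float = 0.5,
               k: int = 2) -> float:
    """AIC for a quantile fit under the asymmetric-Laplace working likelihood:
    AIC = 2k + 2n ln(mean check loss).  Only differences between models on the
    same data are meaningful.  Zero loss returns -inf as a sentinel.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    loss = check_loss(y - intercept - slope * x, tau) / n
    if loss <= 0:
        return float("-inf")
    return float(2 * k + 2 * n * np.log(loss))


def _sse_line(x, y):
    """Residual SS of the least-squares line (2 parameters)."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _sse_shared_slope(xa, ya, xb, yb):
    """Residual SS of the common-slope, separate-intercepts model (3 params)."""
    n, m = xa.size, xb.size
    X = np.zeros((n + m, 3))
    X[:n, 0] = 1.0
    X[n:, 1] = 1.0
    X[:, 2] = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def extra_ss_ftest(group_a, group_b, measure_name: str = "",
                   alpha: float = 0.05) -> SlopeComparisonResult:
    """Extra sum-of-squares F-test: do two groups share a slope, and if so,
    an intercept?

    ``group_a``/``group_b`` are (x, y) pairs.  The slope test compares the
    full model (separate lines, 4 parameters) to the shared-slope model
    (3 parameters); the intercept test compares the shared-slope model to a
    single pooled line (2 parameters).
    """
    xa, ya = _clean_xy(*group_a, 3)
    xb, yb = _clean_xy(*group_b, 3)
    n = xa.size + xb.size
    ss_full = _sse_line(xa, ya) + _sse_line(xb, yb)
    df_full = n - 4
    if df_full <= 0:
        raise ValueError("too few points for the slope comparison")
    scale = float(np.var(np.concatenate([ya, yb]))) * n
    if ss_full <= max(1e-300, 1e-12 * scale):
        raise ValueError("degenerate fit: zero residual sum of squares")
    ss_shared = _sse_shared_slope(xa, ya, xb, yb)
    f_slope = max(0.0, (ss_shared - ss_full) / 1.0 / (ss_full / df_full))
    p_slope = float(sps.f.sf(f_slope, 1, df_full))
    ss_pooled = _sse_line(np.concatenate([xa, xb]), np.concatenate([ya, yb]))
    df_shared = n - 3
    f_int = max(0.0, (ss_pooled - ss_shared) / 1.0 / (ss_shared / df_shared))
    p_int = float(sps.f.sf(f_int, 1, df_shared))
    if p_slope < alpha:
        chosen = "separate"
    elif p_int < alpha:
        chosen = "shared-slope"
    else:
        chosen = "shared"
    return SlopeComparisonResult(measure_name=measure_name, f_slope=float(f_slope),
                                 p_slope=p_slope, f_intercept=float(f_int),
                                 p_intercept=p_int, chosen_model=chosen)


def wbv_adjusted_median(z_segment, z_wbv, groups, *, seed: int = 0,
                        n_boot: int = 2000) -> dict:
    """Whole-brain-adjusted group median z-scores.

    Per group, a median regression of the segment z-score on the paired WBV
    z-score is fitted; the adjusted median is the fitted value at WBV z = 0
    (i.e. the intercept: the segment deviation expected for a typically sized
    brain).  With exactly two groups, the intercept difference is tested by a
    seeded subject bootstrap.

    Returns ``{"adjusted": {group: value}, "difference": float | None,
    "p_boot": float | None}``.
    """
    z_segment = np.asarray(z_segment, dtype=float)
    z_wbv = np.asarray(z_wbv, dtype=float)
    groups = np.asarray(groups)
    if not (z_segment.size == z_wbv.size == groups.size):
        raise ValueError("z_segment, z_wbv and groups must be paired")
    labels = list(dict.fromkeys(groups.tolist()))  # stable order
    masks = {g: groups == g for g in labels}
    for g, m in masks.items():
        if m.sum() < 5:
            raise ValueError(f"group {g!r} has fewer than 5 subjects")
    adjusted = {}
    for g in labels:
        m = masks[g]
        slope, intercept = quantile_fit(z_wbv[m], z_segment[m], 0.5)
        adjusted[g] = float(intercept)
    diff = p_boot = None
    if len(labels) == 2:
        ga, gb = labels
        diff = adjusted[ga] - adjusted[gb]
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        idx = {g: np.flatnonzero(masks[g]) for g in labels}
        for b in range(n_boot):
            vals = []
            for g in labels:
                take = rng.choice(idx[g], size=idx[g].size, replace=True)
                try:
                    _, intercept = quantile_fit(z_wbv[take], z_segment[take], 0.5)
                except RuntimeError:
                    intercept = np.median(z_segment[take])
                vals.append(intercept)
            boot[b] = vals[0] - vals[1]
        lo = np.mean(boot <= 0)
        hi = np.mean(boot >= 0)
        p_boot = float(min(1.0, 2.0 * min(lo, hi)))
    return {"adjusted": adjusted, "difference": diff, "p_boot": p_boot}
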
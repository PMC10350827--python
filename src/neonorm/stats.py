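"""Nonparametric comparison battery.

Groupwise comparisons of deviation z-scores use rank-based tests throughout
(Mann-Whitney U, Kruskal-Wallis) with Cliff's delta as the effect size and
Benjamini-Hochberg control of the false discovery rate within each analysis
table.  Correlation strength is reported as banded Spearman rho.  Growth-chart
z-scores for weight and head circumference use the LMS (skewness / median /
coefficient-of-variation) method with linear age interpolation.

Effect-size bands for |d|:  negligible < 0.148 <= small < 0.34 <= medium
< 0.475 <= large.  Spearman bands for |rho| use cut-points 0.195 / 0.395 /
0.595 / 0.795 (midpoints of the conventional printed band edges, so every
rho maps to exactly one band).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cliffs_delta",
    "effect_category",
    "mann_whitney",
    "kruskal_wallis",
    "bh_fdr",
    "spearman",
    "spearman_band",
    "significance_stars",
    "LMSReference",
    "lms_zscore",
]

_CLIFF_BANDS = ((0.148, "negligible"), (0.34, "small"), (0.475, "medium"))
_SPEARMAN_BANDS = ((0.195, "very weak"), (0.395, "weak"), (0.595, "moderate"),
                   (0.795, "strong"))


def effect_category(d: float) -> str:
    """Cliff's-delta magnitude band (total on |d| in [0, 1])."""
    a = abs(d)
    for cut, name in _CLIFF_BANDS:
        if a < cut:
            return name
    return "large"


def cliffs_delta(x, y) -> tuple[float, str]:
    """Dominance effect size d = [#(x_i > y_j) - #(x_i < y_j)] / (n*m).

    Returns (d, magnitude band).  d > 0 means x tends to exceed y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires two non-empty samples")
    # rank-based O((n+m) log(n+m)) dominance count; avoids an n*m matrix
    xs = np.sort(x)
    greater = np.searchsorted(xs, y, side="right")   # per y_j: #(x <= y_j)
    greater_eq = np.searchsorted(xs, y, side="left")  # per y_j: #(x < y_j)
    n_less = greater.sum()        # pairs with x <= y, counting ties
    n_lt = greater_eq.sum()       # pairs with x < y
    total = x.size * y.size
    n_gt = total - n_less         # pairs with x > y
    d = (n_gt - n_lt) / total
    return float(d), effect_category(d)


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) and its p-value.

    Exact enumeration when n*m <= 64 and the pooled sample is tie-free;
    otherwise the normal approximation with midranks, tie-corrected variance
    and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("constant pooled sample; Mann-Whitney p set to 1", stacklevel=2)
        return float(x.size * y.size / 2.0), 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size * y.size <= 64 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df)."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and \
            not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis requires >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical; Kruskal-Wallis p set to 1", stacklevel=2)
        return 0.0, 1.0
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_band(rho: float) -> str:
    """Correlation-strength band on |rho|."""
    a = abs(rho)
    for cut, name in _SPEARMAN_BANDS:
        if a < cut:
            return name
    return "very strong"


def spearman(x, y) -> tuple[float, float, str]:
    """Midrank Spearman rho, t-approximation p-value, strength band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p), spearman_band(rho)


def significance_stars(p_fdr: float) -> str:
    """Table styling: *, **, *** for p_fdr < 0.05 / 0.01 / 0.001, else 'ns'."""
    if p_fdr < 0.001:
        return "***"
    if p_fdr < 0.01:
        return "**"
    if p_fdr < 0.05:
        return "*"
    return "ns"


@dataclass
class LMSReference:
    """Growth-chart reference grid: per (sex, age) an L (skewness power),
    M (median) and S (coefficient of variation), linearly interpolated in age.
    """

    table: pd.DataFrame

    def __post_init__(self):
        req = {"sex", "age_weeks", "L", "M", "S"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"LMS reference lacks columns: {sorted(missing)}")
        if (self.table["M"] <= 0).any() or (self.table["S"] <= 0).any():
            raise ValueError("LMS reference requires M > 0 and S > 0")
        for sex, grp in self.table.groupby("sex"):
            ages = grp["age_weeks"].to_numpy()
            if not np.all(np.diff(np.sort(ages)) > 0):
                raise ValueError(f"age grid for sex {sex!r} not strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def lookup(self, sex: str, age: float) -> tuple[float, float, float]:
        grp = self.table[self.table["sex"] == sex].sort_values("age_weeks")
        if grp.empty:
            raise KeyError(f"no LMS rows for sex {sex!r}")
        ages = grp["age_weeks"].to_numpy()
        if not ages[0] <= age <= ages[-1]:
            raise ValueError(
                f"age {age} outside LMS reference grid [{ages[0]}, {ages[-1]}]"
                " (no extrapolation)")
        out = []
        for c in ("L", "M", "S"):
            out.append(float(np.interp(age, ages, grp[c].to_numpy())))
        return tuple(out)


def lms_zscore(x: float, ref: LMSReference, sex: str, age: float) -> float:
    """LMS z-score: ((x/M)^L - 1) / (L*S), or ln(x/M)/S as L -> 0."""
    if x <= 0:
        raise ValueError("measurement must be positive")
    L, M, S = ref.lookup(sex, age)
    if abs(L) < 1e-7:
        return float(np.log(x / M) / S)
    return float(((x / M) ** L - 1.0) / (L * S))
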
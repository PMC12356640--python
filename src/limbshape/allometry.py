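"""Reduced Major Axis allometry and non-phylogenetic rank tests.

RMA (a.k.a. standardized major axis) regression fits a symmetric line to
shape scores against log centroid size: slope = sign(r) * s_y / s_x.  The
p-value is the two-sided parametric test on the Pearson correlation; the
slope confidence interval uses the standard SMA closed form.  Group
comparisons use tie-corrected Kruskal-Wallis and Mann-Whitney tests with
Bonferroni adjustment for multiplicity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats


class AllometryError(ValueError):
    pass


@dataclasses.dataclass
class RMAFit:
    intercept: float
    slope: float
    ci_low: float
    ci_high: float
    r_squared: float
    p: float
    n: int


@dataclasses.dataclass
class RankTestResult:
    statistic: float
    p: float
    p_adjusted: float | None = None


def rma_fit(x, y, alpha: float = 0.05, n_perm: int = 0,
            seed: int | None = None) -> RMAFit:
    """Reduced Major Axis regression of y on x.

    slope = sign(r) * s_y / s_x (positive when r = 0 by convention);
    intercept passes through the means.  p is the two-sided t-test on r
    with n - 2 df, or a permutation p when ``n_perm`` > 0.  The slope CI is
    slope * (sqrt(B + 1) +/- sqrt(B)) with
    B = F(1 - alpha; 1, n - 2) * (1 - r^2) / (n - 2).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise AllometryError("RMA needs n >= 3 paired observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise AllometryError("constant x or y: RMA undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = np.sign(r) if r != 0 else 1.0
    slope = float(sign * sy / sx)
    intercept = float(y.mean() - slope * x.mean())
    r2 = r * r
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            rp = float(np.corrcoef(x, rng.permutation(y))[0, 1])
            if abs(rp) >= abs(r) - 1e-15:
                count += 1
        p = count / n_perm
    elif r2 >= 1.0:
        p = 0.0
    else:
        t = abs(r) * np.sqrt((n - 2) / (1.0 - r2))
        p = float(2.0 * stats.t.sf(t, n - 2))
    B = stats.f.isf(alpha, 1, n - 2) * (1.0 - r2) / (n - 2)
    bounds = sorted((slope * (np.sqrt(B + 1.0) - np.sqrt(B)),
                     slope * (np.sqrt(B + 1.0) + np.sqrt(B))))
    return RMAFit(intercept=intercept, slope=slope,
                  ci_low=float(bounds[0]), ci_high=float(bounds[1]),
                  r_squared=r2, p=p, n=n)


def kruskal_wallis(values, groups) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square approximation."""
    values = np.asarray(values, float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise AllometryError("Kruskal-Wallis needs >= 2 groups")
    samples = [values[labels == g] for g in uniq]
    for g, s in zip(uniq, samples):
        if len(s) == 0:
            raise AllometryError(f"group {g!r} has no observations")
    if np.ptp(values) == 0:          # all pooled observations identical
        return RankTestResult(statistic=0.0, p=1.0)
    h, p = stats.kruskal(*samples)
    return RankTestResult(statistic=float(h), p=float(p))


def mann_whitney(values_a, values_b) -> RankTestResult:
    """Mann-Whitney U; exact enumeration when combined n <= 10 and tie-free."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise AllometryError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult(statistic=float(res.statistic), p=float(res.pvalue))


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise AllometryError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * len(p))
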
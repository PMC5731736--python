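"""Robust trend estimation: Theil-Sen slopes, Mann-Kendall significance,
and linear extrapolation of fitted trends.

The Theil-Sen estimator is the median of all pairwise slopes, robust to
outliers (breakdown point about 29%).  Significance of monotone trend uses
the Mann-Kendall S statistic with the normal approximation, tie-corrected
variance and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TrendEstimate:
    slope: float
    intercept: float
    ci_lo: float
    ci_hi: float
    s: float
    p: float
    n: int

    def predict(self, t) -> np.ndarray:
        return self.slope * np.asarray(t, dtype=float) + self.intercept


def theil_sen(t, y, alpha: float = 0.05, method: str = "all_pairs") -> TrendEstimate:
    """Theil-Sen trend of ``y`` against ``t`` with a rank-based slope CI.

    slope = median of all C(n,2) pairwise slopes (pairs with tied ``t``
    excluded); intercept = median(y - slope*t); the (1-alpha) CI on the slope
    comes from the Kendall-score-variance rank method.  ``method='successive'``
    instead takes the median slope of consecutive points (no CI).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 non-missing points")
    if np.ptp(t) == 0:
        raise ValueError("all time values identical")
    if method == "all_pairs":
        slope, _, lo, hi = stats.theilslopes(y, t, alpha=1 - alpha)
    elif method == "successive":
        order = np.argsort(t)
        dt = np.diff(t[order])
        dy = np.diff(y[order])
        good = dt != 0
        slope = float(np.median(dy[good] / dt[good]))
        lo = hi = np.nan
    else:
        raise ValueError(f"unknown method {method!r}")
    intercept = float(np.median(y - slope * t))
    if n >= 4:
        s, p = mann_kendall(y[np.argsort(t)])
    else:
        s, p = np.nan, np.nan
    return TrendEstimate(float(slope), intercept, float(lo), float(hi), s, p, n)


def mann_kendall(y) -> tuple[float, float]:
    """Mann-Kendall S statistic and two-sided p-value.

    S = sum over i<j of sign(y_j - y_i); variance is tie-corrected and the
    normal approximation uses a continuity correction.  A constant series
    returns (0, 1).
    """
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)]
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 non-missing values")
    s = float(np.sign(y[None, :] - y[:, None])[np.triu_indices(n, k=1)].sum())
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:
        return 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return s, min(p, 1.0)


def extrapolate_trend(t, y, target_window: tuple[float, float],
                      alpha: float = 0.05) -> tuple[float, tuple[float, float], TrendEstimate]:
    """Extrapolate a Theil-Sen trend to the midpoint of a future window.

    Point estimate: the fitted trend line evaluated at the window midpoint.
    CI endpoints: lines with the CI-bound slopes pivoted through
    (median t, median y), evaluated at the same midpoint.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    if ok.sum() < 10:
        raise ValueError("need at least 10 non-missing years for extrapolation")
    est = theil_sen(t[ok], y[ok], alpha=alpha)
    mid = 0.5 * (target_window[0] + target_window[1])
    point = float(est.predict(mid))
    mt, my = float(np.median(t[ok])), float(np.median(y[ok]))
    lo = my + est.ci_lo * (mid - mt)
    hi = my + est.ci_hi * (mid - mt)
    return point, (float(min(lo, hi)), float(max(lo, hi))), est
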
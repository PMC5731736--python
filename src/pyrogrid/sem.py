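"""Per-cell path models separating direct and snowpack-mediated temperature
effects on log burned area.

The mediation structure is a recursive two-equation system

    LDPS    = a * T + e1          (temperature shortens the snow season)
    log-AAB = c * T + b * LDPS + e2

so the direct temperature effect is c, the indirect (snow-mediated) effect
is the product a*b, and the reduced-form total effect of T equals c + a*b
exactly.  Because the system is recursive and exactly identified, the two
ordinary-least-squares fits are the maximum-likelihood estimates; no
iterative SEM machinery is needed.  Path coefficients are standardized by
multiplying each regression coefficient by the standard deviation of its
explanatory variable, which makes paths comparable across cells while
leaving them in response units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import AnnualField
from .snow import ldps_month

#: Month labels for long-term mean LDPS classes.
MONTH_LABELS = {11: "Nov", 12: "Dec", 1: "Jan", 2: "Feb", 3: "Mar",
                4: "Apr", 5: "May", 6: "Jun", 7: "Jul", 8: "Aug",
                9: "Sep", 10: "Oct"}


@dataclass
class PathModel:
    """Fitted mediation paths for one cell and season.

    ``a``, ``b``, ``c`` are standardized (coef x SD of explanatory
    variable); the raw OLS coefficients are kept as ``a_raw`` etc.
    ``indirect`` is always the exact product a*b.
    """

    cell_id: int
    season: str
    a: float
    b: float
    c: float
    a_raw: float
    b_raw: float
    c_raw: float
    n: int
    flag: str = "ok"

    @property
    def indirect(self) -> float:
        return self.a * self.b

    @property
    def indirect_raw(self) -> float:
        return self.a_raw * self.b_raw


def _slope(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    M = np.column_stack([np.ones(len(y))] + [x for x in X.T])
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    return beta[1:]


def fit_sem_cell(T, M, y, cell_id: int = 0, season: str = "",
                 min_years: int = 10) -> PathModel:
    """Fit the two-equation path model for one cell.

    ``T`` seasonal temperature, ``M`` LDPS (mediator), ``y`` log-AAB, all
    annual series over the same years.  Cells with fewer than ``min_years``
    complete years, degenerate variance, or |corr(T, M)| > 0.999 are flagged
    and return NaN paths.
    """
    T = np.asarray(T, dtype=float)
    M = np.asarray(M, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(T) & np.isfinite(M) & np.isfinite(y)
    T, M, y = T[ok], M[ok], y[ok]
    n = len(y)

    def bad(flag: str) -> PathModel:
        return PathModel(cell_id, season, np.nan, np.nan, np.nan,
                         np.nan, np.nan, np.nan, n, flag=flag)

    if n < min_years:
        return bad("too-few-years")
    sT, sM = T.std(ddof=1), M.std(ddof=1)
    if sT == 0 or sM == 0 or y.std(ddof=1) == 0:
        return bad("degenerate-variance")
    if abs(np.corrcoef(T, M)[0, 1]) > 0.999:
        return bad("collinear")
    a_raw = float(_slope(M, T[:, None])[0])
    cb = _slope(y, np.column_stack([T, M]))
    c_raw, b_raw = float(cb[0]), float(cb[1])
    return PathModel(cell_id, season,
                     a=a_raw * sT, b=b_raw * sM, c=c_raw * sT,
                     a_raw=a_raw, b_raw=b_raw, c_raw=c_raw, n=n)


def indirect_effect(model: PathModel) -> float:
    """Snow-mediated temperature effect: the product of paths a and b."""
    return model.indirect


def total_effect_raw(T, M, y) -> float:
    """Reduced-form effect of T on y (slope of y ~ T on complete cases).

    For the recursive linear model this equals c_raw + a_raw*b_raw to
    machine precision; exposed for internal-consistency checks.
    """
    T = np.asarray(T, dtype=float)
    M = np.asarray(M, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(T) & np.isfinite(M) & np.isfinite(y)
    return float(_slope(y[ok], T[ok][:, None])[0])


def fit_sem_all(T_field: AnnualField, ldps: AnnualField, log_aab: AnnualField,
                season: str, cells=None, min_years: int = 10) -> dict[int, PathModel]:
    """Fit the seasonal path model for every requested cell."""
    if cells is None:
        cells = np.flatnonzero(np.nansum(np.abs(log_aab.values), axis=1) > 0)
    out = {}
    for cid in cells:
        cid = int(cid)
        out[cid] = fit_sem_cell(T_field.series(cid), ldps.series(cid),
                                log_aab.series(cid), cid, season, min_years)
    return out


def aggregate_by_ldps_class(models: dict[int, PathModel],
                            mean_ldps: dict[int, float] | pd.Series) -> pd.DataFrame:
    """Average direct and indirect paths over monthly snow-duration classes.

    Each cell is assigned to the calendar month containing its long-term
    mean LDPS; per class the mean and standard error (SD/sqrt(n)) of the
    direct (c) and indirect (a*b) standardized paths are reported.  Cells
    with missing mean LDPS or unfit path models are excluded; empty classes
    are simply absent.
    """
    mean_ldps = pd.Series(mean_ldps)
    rows = []
    n_excluded = 0
    for cid, m in models.items():
        ml = mean_ldps.get(cid, np.nan)
        if m.flag != "ok" or not np.isfinite(ml):
            n_excluded += 1
            continue
        month = ldps_month(ml)
        rows.append({"cell_id": cid, "month": month, "direct": m.c,
                     "indirect": m.indirect})
    if not rows:
        raise ValueError("no classifiable cells")
    df = pd.DataFrame(rows)
    out = []
    for month, sub in df.groupby("month"):
        n = len(sub)
        rec = {"month": month, "label": MONTH_LABELS[month], "n_cells": n}
        for col in ("direct", "indirect"):
            rec[f"{col}_mean"] = sub[col].mean()
            rec[f"{col}_se"] = sub[col].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        out.append(rec)
    summary = pd.DataFrame(out)
    # order Nov..Jun style: months sorted on the fire-year day scale
    order = summary["month"].map(lambda m: m - 12 if m >= 11 else m)
    summary = summary.iloc[np.argsort(order)].reset_index(drop=True)
    summary.attrs["n_excluded"] = n_excluded
    return summary
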
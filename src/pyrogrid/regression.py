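"""Per-cell multiple regression of log-AAB on seasonal climate and LDPS.

Each grid cell gets its own ordinary least squares model.  Coefficient
z-scores (coefficient / standard error) feed the driver PCA; stepwise
backward elimination on AIC produces the parsimonious per-cell models used
for projection.  AIC here is the linear-model form n*ln(RSS/n) + 2*k with k
the number of fitted coefficients (additive constants drop out of
comparisons).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import AnnualField, lag_field

#: Predictor presets.  COMPLETE drives the driver PCA; PROJECTION is the
#: candidate set for backward-AIC selection and future projection.
COMPLETE_PRESET = [
    "T_winter", "T_spring", "T_summer",
    "P_winter", "P_spring", "P_summer",
    "T_spring_prev", "T_summer_prev",
    "P_spring_prev", "P_summer_prev",
    "LDPS",
]
PROJECTION_PRESET = [
    "T_winter", "T_spring", "T_summer",
    "P_winter", "P_spring",
    "LDPS", "P_winter_prev",
]


@dataclass
class PredictorSet:
    """Named annual predictor fields sharing one grid and year range."""

    fields: dict[str, AnnualField]

    def __post_init__(self) -> None:
        names = list(self.fields)
        if len(set(names)) != len(names):
            raise ValueError("duplicate predictor names")
        year0 = next(iter(self.fields.values())).years
        for f in self.fields.values():
            if not np.array_equal(f.years, year0):
                raise ValueError("predictor fields must share one year range")

    @property
    def names(self) -> list[str]:
        return list(self.fields)

    @property
    def years(self) -> np.ndarray:
        return next(iter(self.fields.values())).years

    def design_matrix(self, cell_id: int) -> pd.DataFrame:
        """Year-indexed predictor matrix for one cell."""
        return pd.DataFrame(
            {name: f.series(cell_id) for name, f in self.fields.items()},
            index=self.years,
        )


def build_predictors(temperature: dict[str, AnnualField],
                     precipitation: dict[str, AnnualField],
                     ldps: AnnualField,
                     preset: str = "projection") -> PredictorSet:
    """Assemble a preset predictor set from seasonal aggregates and LDPS.

    ``temperature`` / ``precipitation`` map season name (winter/spring/
    summer) to fields; ``_prev`` terms are the same aggregates lagged one
    year.
    """
    pool: dict[str, AnnualField] = {}
    for season, f in temperature.items():
        pool[f"T_{season}"] = f
        pool[f"T_{season}_prev"] = lag_field(f)
    for season, f in precipitation.items():
        pool[f"P_{season}"] = f
        pool[f"P_{season}_prev"] = lag_field(f)
    pool["LDPS"] = ldps
    names = {"projection": PROJECTION_PRESET, "complete": COMPLETE_PRESET}[preset]
    return PredictorSet({n: pool[n] for n in names})


@dataclass
class CellModel:
    """OLS fit for one grid cell.

    ``coef``/``se``/``z`` are keyed by term name; the intercept is the
    ``Intercept`` key of ``coef``/``se`` and is never part of ``terms``.
    """

    cell_id: int
    terms: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    r2: float
    p: float
    aic: float
    n: int
    fitted: bool = True
    dropped: list[str] = field(default_factory=list)
    aic_path: list[float] = field(default_factory=list)

    def predict(self, x: dict[str, float]) -> float:
        """Evaluate the fitted model at one set of predictor values."""
        val = self.coef["Intercept"]
        for t in self.terms:
            val += self.coef[t] * x[t]
        return float(val)


def _ols(y: np.ndarray, X: np.ndarray) -> dict:
    """Plain OLS with intercept-first design matrix X (n x p)."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    dof = n - p
    sigma2 = rss / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    if p > 1 and rss > 0 and tss > rss:
        f = ((tss - rss) / (p - 1)) / (rss / dof)
        pval = float(stats.f.sf(f, p - 1, dof))
    elif p > 1 and rss == 0:
        pval = 0.0
    else:
        pval = 1.0
    aic = n * np.log(rss / n) + 2 * p if rss > 0 else -np.inf
    return {"beta": beta, "se": se, "rss": rss, "r2": r2, "p": pval,
            "aic": float(aic), "n": n}


def _prepare(y: np.ndarray, X: pd.DataFrame, min_extra: int = 3):
    """Complete cases, zero-variance and exact-collinearity handling."""
    mask = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[mask], X.loc[mask]
    dropped: list[str] = []
    for name in list(X.columns):
        if np.ptp(X[name].to_numpy()) == 0:
            dropped.append(name)
            X = X.drop(columns=name)
    if dropped:
        warnings.warn(f"dropped zero-variance predictors: {dropped}")
    # exact collinearity: drop later-listed columns until full rank
    while len(X.columns) > 0:
        M = np.column_stack([np.ones(len(X)), X.to_numpy()])
        if len(X) >= M.shape[1] and np.linalg.matrix_rank(M) == M.shape[1]:
            break
        name = X.columns[-1]
        dropped.append(name)
        warnings.warn(f"dropped collinear predictor: {name}")
        X = X.drop(columns=name)
    enough = len(y) >= len(X.columns) + min_extra
    return y, X, dropped, enough


def fit_cell_model(y, X: pd.DataFrame, cell_id: int = 0,
                   min_extra_years: int = 3) -> CellModel:
    """OLS of one cell's log-AAB series on its predictor matrix.

    Requires at least k + ``min_extra_years`` complete years for k
    predictors; otherwise the returned model has ``fitted=False`` and is
    excluded downstream.
    """
    y = np.asarray(y, dtype=float)
    y, X, dropped, enough = _prepare(y, X, min_extra_years)
    if not enough:
        return CellModel(cell_id, [], {}, {}, {}, np.nan, np.nan, np.nan,
                         len(y), fitted=False, dropped=dropped)
    # zero predictors is a legitimate intercept-only model
    M = np.column_stack([np.ones(len(y)), X.to_numpy()])
    res = _ols(y, M)
    names = ["Intercept"] + list(X.columns)
    coef = dict(zip(names, res["beta"]))
    se = dict(zip(names, res["se"]))
    z = {nm: (coef[nm] / se[nm] if se[nm] > 0 else np.inf * np.sign(coef[nm]))
         for nm in names}
    return CellModel(cell_id, list(X.columns), coef, se, z, res["r2"],
                     res["p"], res["aic"], res["n"], dropped=dropped)


def backward_aic_select(y, X: pd.DataFrame, cell_id: int = 0,
                        min_extra_years: int = 3) -> CellModel:
    """Stepwise backward elimination on AIC from the full model.

    At each step the single term whose removal most lowers AIC is deleted;
    elimination stops when no removal lowers AIC.  The intercept is never
    removed.  The AIC sequence visited is recorded in ``aic_path``.
    """
    y = np.asarray(y, dtype=float)
    y, X, dropped, enough = _prepare(y, X, min_extra_years)
    if not enough or len(X.columns) == 0:
        return CellModel(cell_id, [], {}, {}, {}, np.nan, np.nan, np.nan,
                         len(y), fitted=False, dropped=dropped)

    def aic_of(cols: list[str]) -> float:
        M = np.column_stack([np.ones(len(y))] + [X[c].to_numpy() for c in cols])
        return _ols(y, M)["aic"]

    current = list(X.columns)
    path = [aic_of(current)]
    while current:
        candidates = [(aic_of([c for c in current if c != drop]), drop)
                      for drop in current]
        best_aic, best_drop = min(candidates, key=lambda c: c[0])
        if best_aic < path[-1]:
            current.remove(best_drop)
            path.append(best_aic)
        else:
            break
    model = fit_cell_model(y, X[current], cell_id, min_extra_years)
    model.dropped = dropped
    model.aic_path = path
    return model


def exhaustive_aic_select(y, X: pd.DataFrame) -> list[str]:
    """Best submodel by AIC over all predictor subsets (oracle for small k)."""
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[mask], X.loc[mask]
    best, best_aic = [], np.inf
    for r in range(len(X.columns) + 1):
        for combo in itertools.combinations(X.columns, r):
            M = np.column_stack([np.ones(len(y))] + [X[c].to_numpy() for c in combo])
            a = _ols(y, M)["aic"]
            if a < best_aic:
                best, best_aic = list(combo), a
    return best


def fit_all_cells(log_aab: AnnualField, predictors: PredictorSet,
                  cells=None, select: bool = False,
                  min_extra_years: int = 3) -> dict[int, CellModel]:
    """Fit every requested cell; returns only successfully fitted models.

    ``cells`` defaults to cells with at least one non-missing, nonzero
    log-AAB year (the evaluated subset).
    """
    if cells is None:
        vals = log_aab.values
        cells = np.flatnonzero(np.nansum(np.abs(vals), axis=1) > 0)
    fitfun = backward_aic_select if select else fit_cell_model
    out: dict[int, CellModel] = {}
    for cid in cells:
        model = fitfun(log_aab.series(int(cid)),
                       predictors.design_matrix(int(cid)),
                       int(cid), min_extra_years)
        if model.fitted:
            out[int(cid)] = model
    return out


def zscore_matrix(models: dict[int, CellModel],
                  names: list[str] | None = None) -> pd.DataFrame:
    """Cells x predictors matrix of coefficient z-scores.

    Rows are fitted cells (cell id index); terms absent from a cell's model
    are NaN.
    """
    fitted = {cid: m for cid, m in models.items() if m.fitted}
    if not fitted:
        raise ValueError("no fitted cell models")
    if names is None:
        names = list(dict.fromkeys(
            t for m in fitted.values() for t in m.terms))
    rows = {cid: [m.z.get(t, np.nan) for t in names] for cid, m in fitted.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


def models_to_frame(models: dict[int, CellModel]) -> pd.DataFrame:
    """Long-format per-term table (cell_id, term, coef, se, z, r2, p, aic, n)."""
    rows = []
    for cid, m in models.items():
        for term in ["Intercept"] + m.terms:
            rows.append({"cell_id": cid, "term": term, "coef": m.coef[term],
                         "se": m.se[term], "z": m.z[term], "r2": m.r2,
                         "p": m.p, "aic": m.aic, "n": m.n})
    return pd.DataFrame(rows)
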
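"""Delta-method projection of annual area burned under a climate ensemble.

Ensemble anomalies (absolute changes relative to a baseline climatology) are
two-stage averaged (runs within model, then across models), added to the
observed baseline climatology, pushed through a per-cell LDPS regression to
obtain projected snow-season timing, and finally fed to the selected
per-cell AAB models.  Percent change compares the back-transformed projected
AAB with the baseline-period median AAB, and regional contrasts use a
Kruskal-Wallis test with Bonferroni-corrected pairwise comparisons
summarized as a compact letter display.
"""

from __future__ import annotations

import itertools
import string
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .grid import AnnualField, inverse_log_transform
from .regression import CellModel, _ols

#: Predictors of the LDPS projection regression.
LDPS_PREDICTORS = ["T_winter", "T_spring", "T_summer", "P_winter", "P_spring"]

#: Plausible LDPS window (day index) used to clamp projections.
LDPS_CLAMP = (-120.0, 280.0)


def ensemble_mean(anomalies: pd.DataFrame,
                  value: str = "delta") -> pd.DataFrame:
    """Two-stage ensemble mean: average runs within each model, then models.

    ``anomalies`` needs columns model, run, variable, ``value`` and
    optionally cell_id.  Returns one row per (cell_id,) variable.
    """
    if len(anomalies) == 0:
        raise ValueError("empty ensemble")
    keys = ["variable"] + (["cell_id"] if "cell_id" in anomalies else [])
    per_model = (anomalies.groupby(keys + ["model"], as_index=False)[value].mean())
    return per_model.groupby(keys, as_index=False)[value].mean()


def climatology(field: AnnualField, years: tuple[int, int]) -> np.ndarray:
    """Per-cell mean of an annual field over a baseline year range."""
    mask = (field.years >= years[0]) & (field.years <= years[1])
    if not mask.any():
        raise ValueError("baseline years not covered by field")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(field.values[:, mask], axis=1)


def apply_anomalies(baseline: dict[str, np.ndarray],
                    deltas: pd.DataFrame,
                    n_cells: int | None = None) -> dict[str, np.ndarray]:
    """Add ensemble-mean absolute changes to the baseline climatology.

    ``deltas`` is the output of :func:`ensemble_mean`.  Projected
    precipitation (variables starting with ``P``) is floored at zero with a
    warning.
    """
    out: dict[str, np.ndarray] = {}
    for var, base in baseline.items():
        sub = deltas[deltas["variable"] == var]
        if len(sub) == 0:
            continue
        base = np.asarray(base, dtype=float)
        if "cell_id" in sub.columns and sub["cell_id"].nunique() > 1:
            d = np.full(len(base), np.nan)
            d[sub["cell_id"].to_numpy(dtype=int)] = sub["delta"].to_numpy()
        else:
            d = float(sub["delta"].iloc[0])
        proj = base + d
        if var.startswith("P"):
            n_floor = int(np.sum(proj < 0))
            if n_floor:
                warnings.warn(f"{var}: floored {n_floor} projected values at 0 mm")
            proj = np.maximum(proj, 0.0)
        out[var] = proj
    return out


def project_ldps(ldps: AnnualField, predictors: dict[str, AnnualField],
                 projected: dict[str, np.ndarray],
                 min_extra_years: int = 3,
                 clamp: tuple[float, float] = LDPS_CLAMP) -> pd.DataFrame:
    """Project LDPS by per-cell regression on seasonal climate.

    Per cell, LDPS over the baseline years is regressed on winter/spring/
    summer temperature and winter/spring precipitation; the fit is then
    evaluated at the projected climate.  Returns a DataFrame indexed by cell
    id with columns ``ldps_proj``, ``ldps_fitted_baseline`` and ``clamped``;
    cells with too few complete years are missing.
    """
    names = [n for n in LDPS_PREDICTORS if n in predictors]
    rows = {}
    for cid in range(ldps.grid.n_cells):
        y = ldps.series(cid)
        X = np.column_stack([predictors[n].series(cid) for n in names])
        ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
        if ok.sum() < len(names) + min_extra_years:
            continue
        M = np.column_stack([np.ones(int(ok.sum())), X[ok]])
        res = _ols(y[ok], M)
        beta = res["beta"]
        x_proj = np.array([1.0] + [float(np.asarray(projected[n]).ravel()[cid]
                                         if np.ndim(projected[n]) else projected[n])
                                   for n in names])
        x_base = np.array([1.0] + [float(np.nanmean(X[ok][:, j]))
                                   for j in range(len(names))])
        proj = float(beta @ x_proj)
        clamped = not (clamp[0] <= proj <= clamp[1])
        rows[cid] = {
            "ldps_proj": float(np.clip(proj, *clamp)),
            "ldps_fitted_baseline": float(beta @ x_base),
            "clamped": clamped,
        }
    if not rows:
        raise ValueError("no cells with sufficient data for LDPS projection")
    return pd.DataFrame.from_dict(rows, orient="index")


def project_log_aab(models: dict[int, CellModel],
                    projected: dict[str, np.ndarray | float],
                    ldps_proj: pd.DataFrame,
                    log_offset: float = 1.0,
                    p_threshold: float = 0.05) -> pd.DataFrame:
    """Evaluate selected per-cell models at projected conditions.

    Only models with overall p < ``p_threshold`` are projected.  Prior-year
    terms (``*_prev``) use the projected mean of the same variable (steady
    state).  Returns a DataFrame indexed by cell id with ``log_aab_proj``,
    ``aab_proj`` (ha) and an exclusion ``reason`` for skipped cells.
    """
    rows = {}
    for cid, m in models.items():
        if not m.fitted:
            rows[cid] = {"log_aab_proj": np.nan, "aab_proj": np.nan,
                         "reason": "unfit"}
            continue
        if not (np.isfinite(m.p) and m.p < p_threshold):
            rows[cid] = {"log_aab_proj": np.nan, "aab_proj": np.nan,
                         "reason": "not-significant"}
            continue
        x = {}
        missing = None
        for term in m.terms:
            base_name = term[:-5] if term.endswith("_prev") else term
            if base_name == "LDPS":
                if cid in ldps_proj.index:
                    x[term] = float(ldps_proj.loc[cid, "ldps_proj"])
                else:
                    missing = "no-ldps-projection"
                    break
            elif base_name in projected:
                v = projected[base_name]
                x[term] = float(np.asarray(v).ravel()[cid] if np.ndim(v) else v)
            else:
                missing = f"missing-predictor:{base_name}"
                break
        if missing:
            rows[cid] = {"log_aab_proj": np.nan, "aab_proj": np.nan,
                         "reason": missing}
            continue
        log_proj = m.predict(x)
        rows[cid] = {"log_aab_proj": log_proj,
                     "aab_proj": float(inverse_log_transform(log_proj, log_offset)),
                     "reason": ""}
    return pd.DataFrame.from_dict(rows, orient="index")


def percent_change(projected: pd.DataFrame, baseline_aab: AnnualField,
                   baseline_years: tuple[int, int]) -> pd.DataFrame:
    """Cell-level percent change of projected AAB vs the baseline median.

    percent = 100 * (projected / baseline median - 1).  Cells with zero (or
    missing) baseline median are flagged and carry NaN percent change.
    """
    mask = (baseline_aab.years >= baseline_years[0]) & (baseline_aab.years <= baseline_years[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(baseline_aab.values[:, mask], axis=1)
    rows = []
    for cid, row in projected.iterrows():
        if row.get("reason"):
            continue
        base = med[int(cid)]
        ok = np.isfinite(base) and base > 0 and np.isfinite(row["aab_proj"])
        rows.append({
            "cell_id": int(cid),
            "aab_proj": row["aab_proj"],
            "baseline_median": base,
            "pct_change": 100.0 * (row["aab_proj"] / base - 1.0) if ok else np.nan,
            "flag": "" if ok else "zero-or-missing-baseline-median",
        })
    return pd.DataFrame(rows)


def compact_letters(items: list, different: set[tuple]) -> dict:
    """Compact letter display by greedy insert-absorb.

    Groups sharing a letter are not significantly different; ``different``
    holds unordered pairs found significantly different.
    """
    letters: list[set] = [set(items)]
    for i, j in sorted(different, key=lambda p: (str(p[0]), str(p[1]))):
        for grp in [g for g in letters if i in g and j in g]:
            letters.remove(grp)
            letters.append(grp - {i})
            letters.append(grp - {j})
        # absorb: drop groups contained in another
        letters = [g for g in letters
                   if g and not any(g < h for h in letters)]
        # dedupe
        uniq = []
        for g in letters:
            if g not in uniq:
                uniq.append(g)
        letters = uniq
    letters.sort(key=lambda g: sorted(str(x) for x in g))
    out = {it: "" for it in items}
    for g, ch in zip(letters, string.ascii_lowercase):
        for it in sorted(g, key=str):
            out[it] += ch
    return out


def regional_summary(cell_changes: pd.DataFrame, regions: pd.Series,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Regional medians of percent change with Kruskal-Wallis group tests.

    ``regions`` maps cell id to region label.  Flagged cells (undefined
    percent change) are excluded.  Pairwise Mann-Whitney rank tests at
    Bonferroni-adjusted alpha feed a compact letter display; regions with
    fewer than 2 usable cells are summarized but excluded from the tests.
    """
    df = cell_changes[np.isfinite(cell_changes["pct_change"])].copy()
    df["region"] = df["cell_id"].map(regions)
    df = df[df["region"].notna()]
    groups = {reg: sub["pct_change"].to_numpy() for reg, sub in df.groupby("region")}
    if len(groups) < 2:
        raise ValueError("need at least 2 regions")
    testable = {r: v for r, v in groups.items() if len(v) >= 2}
    if len(testable) >= 2:
        h, p_kw = stats.kruskal(*testable.values())
    else:
        h, p_kw = np.nan, np.nan
    pairs = list(itertools.combinations(sorted(testable), 2))
    alpha_adj = alpha / len(pairs) if pairs else alpha
    different = set()
    for r1, r2 in pairs:
        try:
            p = stats.mannwhitneyu(testable[r1], testable[r2],
                                   alternative="two-sided").pvalue
        except ValueError:
            p = 1.0
        if p < alpha_adj:
            different.add((r1, r2))
    letters = compact_letters(sorted(testable), different)
    rows = []
    for reg in sorted(groups):
        v = groups[reg]
        rows.append({
            "region": reg,
            "n_cells": len(v),
            "median_pct": float(np.median(v)),
            "q1_pct": float(np.percentile(v, 25)),
            "q3_pct": float(np.percentile(v, 75)),
            "letters": letters.get(reg, ""),
            "in_tests": reg in testable,
            "kw_h": float(h),
            "kw_p": float(p_kw),
        })
    return pd.DataFrame(rows)
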
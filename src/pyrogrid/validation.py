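"""Validation of projected regional AAB change against observed trends.

The check mirrors a split-sample design: per region, the observed AAB
series (which extends past the model calibration period) is extrapolated
with a Theil-Sen trend to the midpoint of the projection window and
converted to a percent change against the same regional baseline median the
projection uses.  Agreement is scored on sign and on whether the projection
falls inside the extrapolation's 95% confidence interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trend import extrapolate_trend


def validate_regions(observed: pd.DataFrame, projections: pd.DataFrame,
                     baseline_years: tuple[int, int] = (1972, 2004),
                     target_window: tuple[int, int] = (2010, 2039),
                     min_years: int = 10) -> pd.DataFrame:
    """Compare projected regional percent change with trend extrapolation.

    ``observed`` has columns region, year, value (regional AAB, ha);
    ``projections`` has columns region, median_pct.  Regions present on only
    one side are listed with status ``uncompared``.  Percent changes on the
    observation side use the regional baseline-period median, making the two
    sides unit-free and directly comparable.
    """
    obs_regions = set(observed["region"].unique())
    proj = projections.set_index("region")["median_pct"]
    rows = []
    for region in sorted(obs_regions | set(proj.index), key=str):
        rec = {"region": region, "status": "ok", "proj_pct": np.nan,
               "extrap_pct": np.nan, "extrap_ci_lo_pct": np.nan,
               "extrap_ci_hi_pct": np.nan, "sign_agreement": np.nan,
               "within_ci": np.nan}
        if region not in proj.index or region not in obs_regions:
            rec["status"] = "uncompared"
            rows.append(rec)
            continue
        sub = observed[observed["region"] == region]
        t = sub["year"].to_numpy(dtype=float)
        y = sub["value"].to_numpy(dtype=float)
        ok = np.isfinite(t) & np.isfinite(y)
        if ok.sum() < min_years:
            rec["status"] = "too-few-years"
            rows.append(rec)
            continue
        base_mask = ok & (t >= baseline_years[0]) & (t <= baseline_years[1])
        base_med = float(np.median(y[base_mask])) if base_mask.any() else np.nan
        if not (np.isfinite(base_med) and base_med > 0):
            rec["status"] = "zero-baseline-median"
            rows.append(rec)
            continue
        point, (lo, hi), _ = extrapolate_trend(t[ok], y[ok], target_window)
        to_pct = lambda v: 100.0 * (v / base_med - 1.0)
        p_pct = float(proj.loc[region])
        e_pct, lo_pct, hi_pct = to_pct(point), to_pct(lo), to_pct(hi)
        rec.update(
            proj_pct=p_pct, extrap_pct=e_pct,
            extrap_ci_lo_pct=lo_pct, extrap_ci_hi_pct=hi_pct,
            sign_agreement=bool(np.sign(p_pct) == np.sign(e_pct)),
            within_ci=bool(lo_pct <= p_pct <= hi_pct),
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def sign_agreement_experiment(n_reps: int = 200, seed: int = 0,
                              years: tuple[int, int] = (1972, 2015),
                              beta: float = 0.5,
                              driver_trend: float = 0.04,
                              driver_sd: float = 1.0,
                              noise_sd: float = 0.6,
                              base_log: float = 4.0,
                              delta: float = 1.5,
                              baseline_years: tuple[int, int] = (1972, 2004),
                              target_window: tuple[int, int] = (2010, 2039)) -> float:
    """Fraction of replicates where extrapolated and projected signs agree.

    Each replicate builds one regional AAB series driven by a single
    trending climate driver (trend ``driver_trend`` per year, interannual SD
    ``driver_sd``) through a log-linear response with coefficient ``beta``
    and lognormal noise, so the observed trend and the model projection
    share the same driver.  The projection side is the closed-form percent
    change for an imposed driver change ``delta``; the observation side is
    the Theil-Sen extrapolation of the simulated series.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(years[0], years[1] + 1, dtype=float)
    proj_pct = 100.0 * (np.exp(beta * delta) - 1.0)
    agree = 0
    for _ in range(n_reps):
        x = driver_trend * (t - t[0]) + rng.normal(0, driver_sd, len(t))
        log_aab = base_log + beta * x + rng.normal(0, noise_sd, len(t))
        y = np.exp(log_aab)
        obs = pd.DataFrame({"region": "R", "year": t.astype(int), "value": y})
        projections = pd.DataFrame({"region": ["R"], "median_pct": [proj_pct]})
        report = validate_regions(obs, projections, baseline_years, target_window)
        if bool(report.loc[0, "sign_agreement"]):
            agree += 1
    return agree / n_reps
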
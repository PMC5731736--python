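"""Last Day of Permanent Snowpack (LDPS) from weekly snow-cover charts.

LDPS is the last date inside the final run of at least two consecutive weeks
of snow cover, expressed as a signed day index relative to Jan 1 of the fire
year: Jan 1 is day 1, Dec 31 of the prior year day 0, earlier dates negative
(so Feb 1 is day 32 and Nov 3 of the prior year is day -58).  Indices in
leap fire years are reduced by one after Feb 29 so that every year shares a
365-day scale.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .grid import AnnualField, GridSpec

#: Default search window for the permanent snowpack, relative to the fire year.
DEFAULT_WINDOW = ((-1, 7, 1), (0, 9, 30))  # (year offset, month, day)

STATUS_OK = "ok"
STATUS_NO_RUN = "no-qualifying-run"
STATUS_CENSORED = "censored"

#: Numeric status codes stored alongside LDPS grids.
STATUS_CODES = {STATUS_OK: 0, STATUS_NO_RUN: 1, STATUS_CENSORED: 2}


@dataclass(frozen=True)
class LDPSValue:
    """Signed day index of snowpack termination plus a status flag."""

    day: int | None
    status: str

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def _window_dates(fire_year: int,
                  window=DEFAULT_WINDOW) -> tuple[date, date]:
    (oy0, m0, d0), (oy1, m1, d1) = window
    return date(fire_year + oy0, m0, d0), date(fire_year + oy1, m1, d1)


def day_index(d: date, fire_year: int, window=DEFAULT_WINDOW) -> int:
    """Signed day index of a calendar date relative to Jan 1 of the fire year.

    Jan 1 of the fire year is 1, Dec 31 of the prior year 0; in leap fire
    years dates after Feb 29 are shifted down by one so the index is
    comparable across years.
    """
    lo, hi = _window_dates(fire_year, window)
    if not (lo <= d <= hi):
        raise ValueError(f"date {d} outside LDPS window [{lo}, {hi}]")
    idx = (d - date(fire_year, 1, 1)).days + 1
    if calendar.isleap(fire_year) and d >= date(fire_year, 3, 1):
        idx -= 1
    return idx


def index_to_date(day: int, fire_year: int = 1999) -> date:
    """Inverse of :func:`day_index` on a non-leap reference year."""
    return date(fire_year, 1, 1) + timedelta(days=int(day) - 1)


def date_from_index(day: int, fire_year: int) -> date:
    """Calendar date whose :func:`day_index` equals ``day`` in ``fire_year``.

    Honours the leap correction: in leap fire years the calendar date of a
    given index shifts one day later from March onward.
    """
    d = date(fire_year, 1, 1) + timedelta(days=int(day) - 1)
    if calendar.isleap(fire_year) and d >= date(fire_year, 3, 1):
        d += timedelta(days=1)
    return d


def ldps_month(day: float) -> int:
    """Calendar month (1-12) containing a (mean) LDPS day index."""
    return index_to_date(int(round(day))).month


def compute_ldps(week_ends, flags, fire_year: int,
                 window=DEFAULT_WINDOW, min_run_weeks: int = 2) -> LDPSValue:
    """LDPS from one cell's weekly snow series for one fire year.

    ``flags`` are 1 (snow), 0 (bare) or NaN (missing chart).  A single
    missing week flanked by snow on both sides is treated as snow; two or
    more consecutive missing weeks break a run.  Runs of fewer than
    ``min_run_weeks`` consecutive snow weeks do not qualify.  Censored means
    the latest qualifying run reaches the end of the window, so the true
    termination may lie beyond it.
    """
    week_ends = list(week_ends)
    if len(week_ends) == 0:
        raise ValueError("empty weekly snow series")
    flags = np.asarray(flags, dtype=float)
    if len(flags) != len(week_ends):
        raise ValueError("week_ends and flags length mismatch")
    order = np.argsort(np.asarray(week_ends))
    week_ends = [week_ends[i] for i in order]
    flags = flags[order]
    lo, hi = _window_dates(fire_year, window)
    keep = [i for i, w in enumerate(week_ends) if lo <= w <= hi]
    week_ends = [week_ends[i] for i in keep]
    flags = flags[keep]
    if len(week_ends) == 0:
        return LDPSValue(None, STATUS_NO_RUN)
    for a, b in zip(week_ends, week_ends[1:]):
        if (b - a).days != 7:
            raise ValueError("weekly series must be strictly increasing at 7-day spacing")

    snow = flags.copy()
    # chart-gap filling: a lone missing week between two snow weeks is snow
    for i in range(1, len(snow) - 1):
        if np.isnan(snow[i]) and snow[i - 1] == 1 and snow[i + 1] == 1:
            snow[i] = 1.0
    snow = np.nan_to_num(snow, nan=0.0)

    best_end = None
    run_len = 0
    for i, s in enumerate(snow):
        if s == 1:
            run_len += 1
            if run_len >= min_run_weeks:
                best_end = i
        else:
            run_len = 0
    if best_end is None:
        return LDPSValue(None, STATUS_NO_RUN)
    day = day_index(week_ends[best_end], fire_year, window)
    status = STATUS_CENSORED if best_end == len(snow) - 1 else STATUS_OK
    return LDPSValue(day, status)


def ldps_annual_field(snow_table: pd.DataFrame, grid: GridSpec,
                      years: tuple[int, int],
                      window=DEFAULT_WINDOW) -> tuple[AnnualField, AnnualField]:
    """Per-cell LDPS for a range of fire years from a weekly snow table.

    ``snow_table`` has columns cell_id, week_end (datetime-like), flag
    (1/0/NaN) and optionally fire_year.  A continuous chart is windowed per
    fire year; when a ``fire_year`` column is present (e.g. per-year chart
    extracts) rows are grouped by it instead.  Returns the LDPS field (NaN
    where no qualifying run) and a parallel field of numeric status codes
    (see ``STATUS_CODES``).
    """
    y0, y1 = years
    yrs = np.arange(y0, y1 + 1)
    values = np.full((grid.n_cells, len(yrs)), np.nan)
    status = np.full((grid.n_cells, len(yrs)), np.nan)
    tbl = snow_table.copy()
    tbl["week_end"] = pd.to_datetime(tbl["week_end"]).dt.date
    if "fire_year" in tbl.columns:
        for (cid, fy), sub in tbl.groupby(["cell_id", "fire_year"]):
            fy = int(fy)
            if not (y0 <= fy <= y1):
                continue
            res = compute_ldps(sub["week_end"].tolist(),
                               sub["flag"].to_numpy(dtype=float), fy, window)
            status[int(cid), fy - y0] = STATUS_CODES[res.status]
            if res.day is not None:
                values[int(cid), fy - y0] = res.day
        field = AnnualField(grid, yrs, values, name="LDPS", units="day index")
        stat = AnnualField(grid, yrs, status, name="LDPS_status", units="code")
        return field, stat
    for cid, sub in tbl.groupby("cell_id"):
        ends = sub["week_end"].tolist()
        fl = sub["flag"].to_numpy(dtype=float)
        for j, fy in enumerate(yrs):
            lo, hi = _window_dates(fy, window)
            mask = [lo <= w <= hi for w in ends]
            if not any(mask):
                continue
            w = [e for e, m in zip(ends, mask) if m]
            f = fl[np.asarray(mask)]
            res = compute_ldps(w, f, fy, window)
            status[int(cid), j] = STATUS_CODES[res.status]
            if res.day is not None:
                values[int(cid), j] = res.day
    field = AnnualField(grid, yrs, values, name="LDPS", units="day index")
    stat = AnnualField(grid, yrs, status, name="LDPS_status", units="code")
    return field, stat
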
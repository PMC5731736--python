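"""Synthetic gridded world generator with known ground truth.

Every pipeline stage is exercised against data whose generating process is
known exactly: monthly climate with imposed seasonal trends, weekly snow
charts whose termination date responds linearly to winter and spring
temperature, point fire records realizing a log-linear AAB model with
region-specific coefficients, and a multi-model anomaly ensemble.  The
generator is a pure function of (config, seed) and exposes its ground truth
(true coefficients, true termination dates, exact ensemble means, and the
closed-form regional percent change implied by the imposed anomalies) for
recovery tests.

Default conditions emulate the study setting: a 10x10 one-degree grid, 33
fire years (1972-2004), winter warming of 0.6 degC/decade and 0.2
degC/decade in other seasons, snow termination shifting about -8 days per
degC of spring warming, and ensemble anomalies of +2.5 degC (winter) and
+1.5 degC (spring/summer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import timedelta

import numpy as np
import pandas as pd
import yaml

from .grid import (AnnualField, GridSpec, MonthlySeries, make_grid,
                   seasonal_aggregate)
from .snow import date_from_index

#: Mean monthly temperature cycle (degC anomaly around the annual mean).
T_CYCLE = np.array([-11.0, -9.0, -5.0, 1.0, 7.0, 11.0, 14.0, 13.0, 9.0,
                    3.0, -4.0, -9.0])

DEFAULT_REGION_BETAS = {
    0: {"T_summer": 0.5, "T_spring": 0.2, "LDPS": -0.02},
    1: {"T_summer": 0.4, "LDPS": -0.03},
    2: {"T_summer": 0.3, "T_spring": 0.3},
    3: {"T_summer": -0.2, "T_spring": -0.2, "LDPS": -0.02},
}

DEFAULT_DELTA_MU = {"T_winter": 2.5, "T_spring": 1.5, "T_summer": 1.5,
                    "P_winter": 0.0, "P_spring": 0.0}


@dataclass
class WorldConfig:
    """Full description of a synthetic world; (config, seed) -> world."""

    # grid / period
    n_lon: int = 10
    n_lat: int = 10
    lon_min: float = -120.0
    lat_min: float = 40.0
    resolution: float = 1.0
    year_start: int = 1972
    n_years: int = 33
    # climate
    t_base_south: float = 11.0
    t_lat_gradient: float = -0.7     # degC per cell row northward
    t_trend_winter: float = 0.06     # degC/yr, JFM months
    t_trend_other: float = 0.02      # degC/yr, remaining months
    t_noise_sd: float = 1.8          # monthly, degC
    p_base: float = 40.0             # mm/month
    p_noise_sd: float = 12.0
    # snow season
    d0_south: float = 30.0           # mean termination day index, southern row
    d0_lat_gradient: float = 10.0    # days per row northward
    alpha_winter: float = -4.0       # days per degC of winter T
    alpha_spring: float = -8.0       # days per degC of spring T
    snow_noise_sd: float = 6.0
    season_weeks: int = 20           # snow weeks ending at the termination date
    post_season_weeks: int = 4
    isolated_week_prob: float = 0.1  # lone snow week after the season
    # burned area
    beta0: float = 5.0               # log(ha + offset) at mean conditions
    region_betas: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGION_BETAS.items()})
    aab_noise_sd: float = 0.4
    log_offset: float = 1.0
    mean_fire_size: float = 500.0    # ha, sets the Poisson fire count rate
    fire_size_sigma: float = 1.0     # lognormal spread of individual fires
    # anomaly ensemble
    delta_mu: dict = field(default_factory=lambda: dict(DEFAULT_DELTA_MU))
    n_models: int = 5
    runs_per_model: tuple = (1, 2, 3, 2, 1)
    model_offset_sd: float = 0.3
    run_noise_sd: float = 0.2

    def grid(self) -> GridSpec:
        return make_grid((self.lon_min, self.lon_min + self.n_lon * self.resolution,
                          self.lat_min, self.lat_min + self.n_lat * self.resolution),
                         self.resolution)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_start + self.n_years)

    def region_of_cells(self) -> np.ndarray:
        """Quadrant region labels 0..3 (SW, SE, NW, NE)."""
        grid = self.grid()
        rows, cols = np.divmod(np.arange(grid.n_cells), grid.n_lon)
        return (rows >= grid.n_lat // 2).astype(int) * 2 + (cols >= grid.n_lon // 2).astype(int)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "runs_per_model" in raw:
            raw["runs_per_model"] = tuple(raw["runs_per_model"])
        if "region_betas" in raw:
            raw["region_betas"] = {int(k): dict(v) for k, v in raw["region_betas"].items()}
        return cls(**raw)


# --- expected (noise-free) predictor values at mid-period, used for centering

def _expected_seasonal_t(cfg: WorldConfig, season_months, row: np.ndarray,
                         year_offset: float) -> np.ndarray:
    base = cfg.t_base_south + cfg.t_lat_gradient * row
    cyc = T_CYCLE[list(season_months)].mean()
    trend = cfg.t_trend_winter if tuple(season_months) == (0, 1, 2) else cfg.t_trend_other
    return base + cyc + trend * year_offset


def expected_predictor_centers(cfg: WorldConfig) -> dict[str, np.ndarray]:
    """Noise-free mid-period predictor values per cell (centering constants)."""
    grid = cfg.grid()
    row = np.arange(grid.n_cells) // grid.n_lon
    mid = (cfg.n_years - 1) / 2.0
    centers = {
        "T_winter": _expected_seasonal_t(cfg, (0, 1, 2), row, mid),
        "T_spring": _expected_seasonal_t(cfg, (3, 4, 5), row, mid),
        "T_summer": _expected_seasonal_t(cfg, (6, 7, 8), row, mid),
        "P_winter": np.full(grid.n_cells, 3 * cfg.p_base),
        "P_spring": np.full(grid.n_cells, 3 * cfg.p_base),
        "P_winter_prev": np.full(grid.n_cells, 3 * cfg.p_base),
    }
    centers["LDPS"] = cfg.d0_south + cfg.d0_lat_gradient * row
    return centers


def gen_climate(cfg: WorldConfig, rng: np.random.Generator
                ) -> tuple[MonthlySeries, MonthlySeries]:
    """Monthly temperature and precipitation with imposed trends and noise."""
    grid = cfg.grid()
    row = (np.arange(grid.n_cells) // grid.n_lon).astype(float)
    base = cfg.t_base_south + cfg.t_lat_gradient * row
    trend = np.where(np.arange(12) < 3, cfg.t_trend_winter, cfg.t_trend_other)
    yoff = np.arange(cfg.n_years, dtype=float)
    mean = (base[:, None, None] + T_CYCLE[None, None, :]
            + trend[None, None, :] * yoff[None, :, None])
    temp = mean + rng.normal(0, cfg.t_noise_sd, mean.shape)
    prec = np.maximum(
        cfg.p_base + rng.normal(0, cfg.p_noise_sd, mean.shape), 0.0)
    return (MonthlySeries(grid, cfg.years, temp, "temperature"),
            MonthlySeries(grid, cfg.years, prec, "precipitation"))


def gen_weekly_snow(cfg: WorldConfig, temperature: MonthlySeries,
                    rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, AnnualField]:
    """Weekly snow charts whose termination tracks winter/spring warmth.

    Per cell-year the snow season terminates at day index
    ``d0(cell) + alpha_w*(T_JFM - center) + alpha_s*(T_AMJ - center) +
    noise``; the emitted weekly grid is anchored so that one week ends
    exactly on the termination date, followed by bare weeks and, with small
    probability, a single isolated snow week (which must not move LDPS).
    Returns the chart table and the true LDPS field.
    """
    grid = temperature.grid
    seas = seasonal_aggregate(temperature)
    centers = expected_predictor_centers(cfg)
    row = (np.arange(grid.n_cells) // grid.n_lon).astype(float)
    d0 = cfg.d0_south + cfg.d0_lat_gradient * row
    true_vals = np.full((grid.n_cells, cfg.n_years), np.nan)
    recs: list[tuple[int, int, object, float]] = []
    for cid in range(grid.n_cells):
        tw = seas["winter"].series(cid) - centers["T_winter"][cid]
        ts = seas["spring"].series(cid) - centers["T_spring"][cid]
        noise = rng.normal(0, cfg.snow_noise_sd, cfg.n_years)
        iso = rng.random(cfg.n_years) < cfg.isolated_week_prob
        for j, fy in enumerate(cfg.years):
            d = int(round(d0[cid] + cfg.alpha_winter * tw[j]
                          + cfg.alpha_spring * ts[j] + noise[j]))
            true_vals[cid, j] = d
            term = date_from_index(d, int(fy))
            for k in range(-(cfg.season_weeks - 1), cfg.post_season_weeks + 1):
                flag = 1.0 if k <= 0 else (1.0 if (k == 2 and iso[j]) else 0.0)
                recs.append((cid, int(fy), term + timedelta(days=7 * k), flag))
    table = pd.DataFrame(recs, columns=["cell_id", "fire_year", "week_end", "flag"])
    truth = AnnualField(grid, cfg.years, true_vals, name="LDPS_true",
                        units="day index")
    return table, truth


def _true_log_aab(cfg: WorldConfig, temperature: MonthlySeries,
                  precipitation: MonthlySeries, ldps_true: AnnualField,
                  rng: np.random.Generator) -> AnnualField:
    grid = temperature.grid
    seas_t = seasonal_aggregate(temperature)
    seas_p = seasonal_aggregate(precipitation)
    centers = expected_predictor_centers(cfg)
    fields = {"T_winter": seas_t["winter"], "T_spring": seas_t["spring"],
              "T_summer": seas_t["summer"], "P_winter": seas_p["winter"],
              "P_spring": seas_p["spring"], "LDPS": ldps_true}
    regions = cfg.region_of_cells()
    log_target = np.full((grid.n_cells, cfg.n_years), cfg.beta0)
    for cid in range(grid.n_cells):
        betas = cfg.region_betas[int(regions[cid])]
        for name, b in betas.items():
            log_target[cid] += b * (fields[name].series(cid) - centers[name][cid])
    log_target += rng.normal(0, cfg.aab_noise_sd, log_target.shape)
    return AnnualField(grid, cfg.years, log_target, name="log_target")


def gen_fire_records(cfg: WorldConfig, log_target: AnnualField,
                     rng: np.random.Generator
                     ) -> tuple[pd.DataFrame, AnnualField]:
    """Point fire records realizing the per-cell-year target AAB exactly.

    Target AAB = exp(log target) - offset, floored at 0.  A positive target
    is realized as max(1, Poisson) fires with lognormal sizes rescaled to
    sum to the target; coordinates are uniform within the cell.  Returns the
    record table and the target AAB field (the generator's bookkeeping).
    """
    grid = log_target.grid
    target = np.maximum(np.exp(log_target.values) - cfg.log_offset, 0.0)
    rows = []
    for cid in range(grid.n_cells):
        west, east, south, north = grid.cell_bounds(cid)
        for j, fy in enumerate(log_target.years):
            tgt = target[cid, j]
            if tgt <= 0:
                continue
            n = max(1, int(rng.poisson(tgt / cfg.mean_fire_size)))
            sizes = rng.lognormal(np.log(cfg.mean_fire_size),
                                  cfg.fire_size_sigma, n)
            sizes *= tgt / sizes.sum()
            lon = rng.uniform(west, east, n)
            lat = rng.uniform(south, north, n)
            for k in range(n):
                rows.append((lon[k], lat[k], int(fy), sizes[k]))
    records = pd.DataFrame(rows, columns=["lon", "lat", "year", "area_ha"])
    aab_target = AnnualField(grid, log_target.years, target,
                             name="AAB_target", units="ha")
    return records, aab_target


def gen_anomalies(cfg: WorldConfig, rng: np.random.Generator
                  ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Multi-model anomaly ensemble and its exact two-stage mean.

    Per variable: run delta = mu + model offset + run noise, spatially
    uniform.  The returned truth maps variable -> the exact two-stage mean
    (mu + mean of model offsets + mean over models of mean run noise).
    """
    rows = []
    truth: dict[str, float] = {}
    for var, mu in cfg.delta_mu.items():
        offsets = rng.normal(0, cfg.model_offset_sd, cfg.n_models)
        model_means = []
        for m in range(cfg.n_models):
            n_runs = cfg.runs_per_model[m % len(cfg.runs_per_model)]
            noise = rng.normal(0, cfg.run_noise_sd, n_runs)
            for r in range(n_runs):
                rows.append((f"GCM{m:02d}", r, var, mu + offsets[m] + noise[r]))
            model_means.append(mu + offsets[m] + noise.mean())
        truth[var] = float(np.mean(model_means))
    return pd.DataFrame(rows, columns=["model", "run", "variable", "delta"]), truth


@dataclass
class World:
    """A generated synthetic world plus its ground truth."""

    config: WorldConfig
    grid: GridSpec
    temperature: MonthlySeries
    precipitation: MonthlySeries
    snow_table: pd.DataFrame
    fire_records: pd.DataFrame
    anomalies: pd.DataFrame
    regions: np.ndarray
    truth: dict


def delta_ldps_true(cfg: WorldConfig, delta: dict[str, float]) -> float:
    """Closed-form LDPS change implied by imposed temperature anomalies."""
    return (cfg.alpha_winter * delta.get("T_winter", 0.0)
            + cfg.alpha_spring * delta.get("T_spring", 0.0))


def closed_form_pct_change(cfg: WorldConfig,
                           delta: dict[str, float]) -> dict[int, float]:
    """Per-region percent change in AAB implied by the generator's betas.

    dlog(region) = sum_k beta_k * delta_k with the LDPS delta derived from
    the snow model; percent change = 100 * (exp(dlog) - 1).  Exact for the
    log-linear generator evaluated at mean conditions.
    """
    d_ldps = delta_ldps_true(cfg, delta)
    out = {}
    for region, betas in cfg.region_betas.items():
        dlog = sum(b * (d_ldps if name == "LDPS" else delta.get(name, 0.0))
                   for name, b in betas.items())
        out[int(region)] = 100.0 * (np.exp(dlog) - 1.0)
    return out


def make_world(config: WorldConfig | None = None, seed: int = 0) -> World:
    """Generate a full synthetic world; deterministic in (config, seed)."""
    cfg = config or WorldConfig()
    rng = np.random.default_rng(seed)
    temperature, precipitation = gen_climate(cfg, rng)
    snow_table, ldps_true = gen_weekly_snow(cfg, temperature, rng)
    log_target = _true_log_aab(cfg, temperature, precipitation, ldps_true, rng)
    fire_records, aab_target = gen_fire_records(cfg, log_target, rng)
    anomalies, delta_true = gen_anomalies(cfg, rng)
    truth = {
        "region_betas": cfg.region_betas,
        "beta0": cfg.beta0,
        "ldps_true": ldps_true,
        "log_target": log_target,
        "aab_target": aab_target,
        "delta_mu": dict(cfg.delta_mu),
        "delta_true": delta_true,
        "delta_ldps_true": delta_ldps_true(cfg, delta_true),
        "pct_change_region": closed_form_pct_change(cfg, delta_true),
        "centers": expected_predictor_centers(cfg),
    }
    return World(cfg, cfg.grid(), temperature, precipitation, snow_table,
                 fire_records, anomalies, cfg.region_of_cells(), truth)
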
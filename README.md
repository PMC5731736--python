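# pyrogrid

Cell-based statistical modelling of climate and snow-cover controls on
annual wildfire area burned (AAB), with delta-method projection of future
burned area.

## The problem

Seasonal climate influences wildfire both directly (fuel desiccation from
warm fire seasons) and indirectly, by shortening the snow season and
changing the water supply available to fuels before the fire season starts.
`pyrogrid` implements the full analysis chain for separating and projecting
these effects on a 1°×1° lattice:

- **Gridding** — point fire records summed to per-cell annual area burned
  (AAB, ha); a 5% redistribution filter smears boundary fires (1% to each
  orthogonal neighbour, 0.25% to each diagonal); log transform
  `ln(AAB + 1)`.
- **Snow phenology** — the last day of permanent snowpack (LDPS): the last
  date inside the final run of ≥ 2 consecutive snow-covered weeks, as a
  signed day index with Jan 1 of the fire year = 1 (Feb 1 → 32, Nov 3 of
  the prior year → −58) and leap correction to a common 365-day scale.
- **Trends** — Theil-Sen slopes (median of all pairwise slopes) with
  rank-based confidence intervals and the Mann-Kendall test.
- **Per-cell regression** — OLS of log-AAB on seasonal temperature and
  precipitation (JFM winter / AMJ spring / JAS summer means and sums) and
  LDPS; coefficient z-scores (coef/SE); stepwise backward elimination on
  `AIC = n·ln(RSS/n) + 2k`.
- **Driver mapping** — PCA (SVD of the correlation matrix) of the cells ×
  predictors z-score matrix, with components labelled by predictors whose
  z columns correlate with the component scores at |r| ≥ 0.5.
- **Mediation** — per-cell recursive path models
  `LDPS = a·T + e₁`, `log-AAB = c·T + b·LDPS + e₂`, so the direct
  temperature effect is `c`, the snow-mediated indirect effect is `a·b`,
  and the reduced-form total effect is exactly `c + a·b`.  Paths are
  standardized by multiplying each coefficient by the SD of its explanatory
  variable.
- **Projection** — two-stage GCM ensemble means (runs within model, then
  across models) added to the baseline climatology; LDPS projected through
  a per-cell climate regression; selected per-cell models (overall
  p < 0.05) evaluated at projected conditions; percent change against the
  baseline-period median AAB; regional medians with Kruskal-Wallis +
  Bonferroni pairwise tests and a compact letter display.
- **Validation** — regional Theil-Sen extrapolation of observed AAB to the
  projection-window midpoint, compared with the projected median change on
  sign and CI overlap.
- **Synthetic worlds** — a generator producing all of the above inputs with
  known coefficients and exposed ground truth, so every stage is testable
  end to end without external data.

## Worked example

```python
import pyrogrid as pg

world = pg.make_world(seed=1)            # 10x10 grid, 33 fire years, 4 regions
result = pg.run_world_pipeline(world)    # fires -> AAB -> models -> projection
print(result.regional[["region", "n_cells", "median_pct", "letters"]])
```

prints

```
 region  n_cells  median_pct letters
      0       25       364.0       a
      1       25       231.1       b
      2       25       164.0       c
      3       21       -10.7       d
```

Each row is one region's projected change in annual area burned for the
imposed ensemble anomalies (+2.5 °C winter, +1.5 °C spring and summer):
region 0's median cell is projected to burn about 4.6× its baseline median
(+364%), while region 3 — planted with negative temperature responses —
declines slightly.  Distinct letters mean the regional medians differ
significantly (Kruskal-Wallis with Bonferroni-corrected pairwise tests).
The generator's closed-form values for this world are +379%, +266%, +168%
and −14%: the pipeline recovers the planted responses within sampling
error.  Of the 100 per-cell models, 96 pass the p < 0.05 significance gate
used for projection.

A command-line entry point covers the data-facing stages:

```sh
pyrogrid simulate --seed 42 -o world/        # write synthetic datasets + truth
pyrogrid ldps --snow world/snow.csv --grid -120,-110,40,50 --years 1972:2004 -o ldps.csv
pyrogrid trend --in series.csv --per-decade -o trends.csv
pyrogrid pipeline --seed 42 -o change/       # end-to-end on a synthetic world
```

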
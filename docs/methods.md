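# Methods

This note documents the statistical procedures, the conventions chosen
where several readings were defensible, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Grid and fire aggregation

The analysis lattice is a regular lon/lat grid (default 1°, domain
170–52°W × 25–72°N, 118 × 47 = 5546 cells).  Cells are half-open intervals
[west, east) × [south, north), so a fire mapped exactly on an interior cell
boundary belongs deterministically to the cell to its northeast.  Cell-year
AAB is the sum of point fire areas; cell-years without fires are zero, not
missing.  An optional minimum fire size (`min_area_ha`, e.g. 200 ha when
emulating federal large-fire records) filters records before aggregation.

The neighbour redistribution filter softens the artefact of large fires
mapped to a single point near a cell edge: each cell keeps 95% of its AAB
and donates 1% to each orthogonal and 0.25% to each diagonal neighbour.
It is implemented as a 3×3 convolution with zero padding, so mass crossing
the domain edge is dropped and the filter never increases the total.
Interior impulses conserve mass exactly.

Log transform: `ln(AAB + offset)` with offset 1 ha by default, keeping
zero-AAB years at exactly 0.  The offset matters only for small AAB;
regression coefficients at large AAB shift by < 1e-3 across offsets
0.1–10 ha (tested).  Regridding uses block averaging when the source grid
is exactly nested at half the resolution (the 0.5° → 1° case) and bilinear
interpolation at destination cell centres otherwise; bilinear interpolation
reproduces affine fields exactly.

## LDPS: last day of permanent snowpack

LDPS is the last date inside the final run of at least two consecutive
snow-covered weeks, as a signed day index: Jan 1 of the fire year is day 1,
Dec 31 of the prior year day 0, earlier dates negative (Feb 1 → 32,
Nov 3 prior → −58, Sep 6 → 249).  Conventions the weekly-chart format
forces us to fix:

- **Within-week dating** — "last date" of a run is the end date of its
  last snow-covered week (weekly charts do not resolve finer).
- **Leap years** — indices of dates after Feb 29 of a leap fire year are
  reduced by one, putting all years on a common 365-day scale (Feb 29 and
  Mar 1 then share an index; the mapping is otherwise a bijection over the
  search window).
- **Missing charts** — one missing week flanked by snow on both sides is
  filled as snow; two or more consecutive missing weeks break a run.
- **Run length** — runs of exactly two weeks qualify (inclusive ≥ 2).
- **Search window** — July 1 of the prior year through Sep 30 of the fire
  year (configurable).  A qualifying run reaching the window end is flagged
  censored.

## Trend estimation

Theil-Sen slopes are the median over all C(n,2) pairwise slopes (pairs with
tied abscissae excluded), with the rank-based confidence interval from the
Kendall score variance (delegated to `scipy.stats.theilslopes`); the
intercept is `median(y − slope·t)`.  A "successive pairs" variant (median
slope of consecutive points) is available behind a flag for comparison but
is not the default: the standard estimator, and the accuracy results
motivating it, use all pairs.  The Mann-Kendall test uses the
tie-corrected variance and a continuity correction; with fewer than four
points the test statistics are NaN.  Trend extrapolation evaluates the
fitted line at the midpoint of the target window (2024.5 for 2010–2039);
CI endpoints pivot the CI-bound slopes through (median t, median y).  No
prewhitening for serial correlation is applied (a known limitation; annual
series at these lengths are treated as exchangeable under the null).

## Per-cell regression and selection

Each cell gets an OLS fit of log-AAB on a preset of predictors.  The
COMPLETE preset (driver PCA) holds fire-year T and P for all three seasons,
prior-year spring/summer T and P, and LDPS; the PROJECTION preset holds
fire-year T (three seasons), fire-year winter/spring P, LDPS and
prior-winter P.  Cells need at least k + 3 complete years for k predictors;
zero-variance predictors are dropped with a warning, exact collinearity is
resolved by dropping later-listed predictors.  "z-scores" are coefficient
t-statistics (coef/SE) — comparable across cells whose predictors have
different scales, which is what the driver PCA requires; standardized
coefficients would be an alternative reading and can be computed from the
stored models.

Backward elimination uses `AIC = n·ln(RSS/n) + 2k` with k the number of
fitted coefficients (additive constants cancel in comparisons; this is the
linear-model convention of standard stepwise tools).  At each step the
deletion that most lowers AIC is taken; the intercept is never removed; an
intercept-only model is a legitimate endpoint.  The greedy path is not
guaranteed to find the AIC-optimal subset, but matches exhaustive search on
≥ 90% of small random instances (tested), and its AIC sequence is strictly
decreasing by construction.  Models passing to projection must have overall
F-test p < 0.05.

## Driver PCA

The cells × predictors z-score matrix is column-standardized (complete-case
cells only; dropped cells counted) and decomposed by SVD — the
eigendecomposition of the correlation matrix.  Variance percentages are
eigenvalues over their total; they sum to 100 because the z matrix's total
standardized variance is the number of predictors.  Each component is
oriented so its largest-|loading| predictor loads positively — a
deterministic replacement for ad hoc sign flips.  Component labels list
predictors whose z columns correlate with the component's cell scores at
|r| ≥ 0.5 (threshold configurable), signed; score correlations rather than
raw loadings are used so the labels describe the mapped spatial pattern.

## Mediation (path) models

The mediation structure is recursive and exactly identified, so the two
OLS equations are the maximum-likelihood estimates and no iterative SEM
machinery is needed; the reduced-form identity total = c + a·b holds to
machine precision and is asserted in tests as an internal-consistency
check.  Winter and spring temperature models are fit independently (one
temperature node per model); a joint two-season model is out of scope.
Standardization multiplies each coefficient by the SD of its explanatory
variable, leaving paths in response (log-AAB) units; full standardization
(also dividing by SD of the response) is available via the raw
coefficients.  Cells are summarized by classes of long-term mean LDPS
(calendar month containing the mean index), with class mean ± SE of the
direct (c) and indirect (a·b) paths.

## Projection

Ensemble anomalies are averaged in two stages — runs within each model,
then across models — so models with many runs are not over-weighted.
Projected climate is baseline climatology plus the ensemble-mean change
(precipitation floored at 0).  LDPS is projected by a per-cell regression
on winter/spring/summer temperature and winter/spring precipitation over
the baseline years, evaluated at projected climate and clamped to a
plausible window (−120 to 280).  Selected AAB models are evaluated at
projected mean seasonal conditions — no year-by-year future weather is
simulated, matching the use of 30-year ensemble changes — and prior-year
terms use the projected mean of the same variable (steady-state
assumption).  Percent change is 100 × (projected / baseline-median − 1),
undefined (flagged) where the baseline median is zero.  The climate
baseline and the fire baseline are separate configuration keys, since
observational climate normals (e.g. 1961–1990) and fire records
(e.g. 1972–2004) rarely share a window.  Regional contrasts use
Kruskal-Wallis across regions and pairwise two-sided Mann-Whitney tests at
Bonferroni-adjusted α, rendered as a compact letter display built by greedy
insert-absorb.  Regional medians are computed over cells with significant
selected models only.

## Validation

Per region, observed AAB (extending past the calibration period) is
extrapolated by Theil-Sen to the projection-window midpoint and converted
to percent change against the same regional baseline median the projection
uses, making the comparison unit-free.  Agreement is scored on sign and on
whether the projection falls inside the extrapolation's 95% CI.  The
midpoint evaluation equals the median of year-wise extrapolations for a
linear trend.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes, not
the visual realism of the source datasets:

- **Climate** — monthly temperature = latitudinal baseline + fixed seasonal
  cycle + linear trend + iid Gaussian noise (winter trend 0.06 °C/yr,
  0.02 °C/yr otherwise, monthly SD 1.8 °C); precipitation = 40 mm/month +
  noise, floored at 0.
- **Snow** — per cell-year the season terminates at
  `d₀(cell) + α_w·(T_JFM − center) + α_s·(T_AMJ − center) + noise`
  (α_w = −4, α_s = −8 days/°C, noise SD 6 d), emitted as weekly flags whose
  grid is anchored so one week ends exactly on the termination date — a
  fixed calendar grid would quantize LDPS by up to six days and break exact
  closed-loop recovery.  Isolated post-season snow weeks are injected with
  probability 0.1 to exercise the ≥ 2-week rule.
- **Burned area** — `ln(AAB + 1) = β₀ + Σ β_k·(x_k − center_k) + ε`
  (ε SD 0.4) with region-specific β on summer/spring temperature and LDPS
  spanning strong increases to mild decreases.  Predictors are centered at
  their noise-free mid-period expectations so β₀ sets the baseline level
  directly.  A positive target is realized as `max(1, Poisson)` point fires
  with lognormal sizes rescaled to sum to the target exactly — a plain
  Poisson draw of zero fires would silently zero the cell-year and break
  the generator's bookkeeping.
- **Anomalies** — per variable, run delta = μ + model offset + run noise
  (μ: +2.5 °C winter, +1.5 °C spring/summer, 0 mm precipitation; offsets
  SD 0.3, run noise SD 0.2, five models with unequal run counts so the
  two-stage mean differs from the flat mean).  The exact two-stage mean is
  exposed as truth.

The closed-form regional percent change implied by the generator is
`100·(exp(Σ β_k Δ_k) − 1)` with the LDPS delta `α_w ΔT_winter + α_s
ΔT_spring`; the end-to-end test compares pipeline regional medians to this
in log-ratio space with tolerance 0.25, set from the design noise budget
(25 cells per region, per-cell coefficient noise ≈ 0.1–0.2 in log units,
ensemble model-offset sampling ≈ 0.08).

What the generator does **not** emulate: spatial autocorrelation of noise
(available optionally for climate but off by default), fire-size power
laws and their year-to-year clustering, snow-chart classification error,
observation gaps, and the real datasets' spatial patterns.  Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the assumed model, not robustness to the messiness of the real
records.

## Problem sizes

The default world is 10 × 10 cells × 33 years with four regions — large
enough that every stage's preconditions hold and regional tests have
power, small enough that the full pipeline runs in a few seconds.
Simulation-based tests use 200–10,000 replicates depending on the
sharpness of the quantity under test.

## Known limitations

- No spatial autocorrelation handling in per-cell models (each cell is fit
  independently; neighbouring cells share smeared AAB after the filter).
- No prewhitening in trend tests; Mann-Kendall p-values assume
  exchangeability.
- Greedy backward AIC can miss the optimal subset on adversarial designs.
- The LDPS projection regression extrapolates linearly outside the
  baseline climate range; projections are clamped but not otherwise
  constrained.
- Percent change is undefined for cells that never burned in the baseline
  period; such cells are excluded from regional medians.
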
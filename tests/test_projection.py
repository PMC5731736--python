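import numpy as np
import pandas as pd
import pytest

import pyrogrid as pg
from pyrogrid.projection import compact_letters


def anomaly_frame(entries):
    return pd.DataFrame(entries, columns=["model", "run", "variable", "delta"])


class TestEnsembleMean:
    def test_two_stage_mean_differs_from_flat(self):
        df = anomaly_frame([("A", 0, "T_winter", 1.0), ("A", 1, "T_winter", 3.0),
                            ("B", 0, "T_winter", 5.0)])
        out = pg.ensemble_mean(df)
        assert out["delta"].iloc[0] == pytest.approx(3.5)  # not the flat 3.0

    def test_single_model_single_run_identity(self):
        df = anomaly_frame([("A", 0, "T_winter", 2.2)])
        assert pg.ensemble_mean(df)["delta"].iloc[0] == pytest.approx(2.2)

    def test_model_order_irrelevant(self):
        rows = [("A", 0, "v", 1.0), ("B", 0, "v", 2.0), ("B", 1, "v", 4.0)]
        a = pg.ensemble_mean(anomaly_frame(rows))
        b = pg.ensemble_mean(anomaly_frame(rows[::-1]))
        assert a["delta"].iloc[0] == pytest.approx(b["delta"].iloc[0])

    def test_equal_run_counts_equals_flat_mean(self):
        rng = np.random.default_rng(60)
        rows = [(m, r, "v", rng.normal()) for m in "ABC" for r in range(3)]
        df = anomaly_frame(rows)
        assert pg.ensemble_mean(df)["delta"].iloc[0] == \
            pytest.approx(df["delta"].mean())

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            pg.ensemble_mean(anomaly_frame([]))

    def test_generator_truth_matches_two_stage_mean(self, default_world):
        out = pg.ensemble_mean(default_world.anomalies)
        for _, row in out.iterrows():
            assert row["delta"] == pytest.approx(
                default_world.truth["delta_true"][row["variable"]], abs=1e-12)


class TestApplyAnomalies:
    def test_addition_and_identity(self):
        base = {"T_winter": np.array([10.0, 0.0])}
        deltas = pd.DataFrame({"variable": ["T_winter"], "delta": [1.5]})
        out = pg.apply_anomalies(base, deltas)
        np.testing.assert_allclose(out["T_winter"], [11.5, 1.5])
        zero = pd.DataFrame({"variable": ["T_winter"], "delta": [0.0]})
        np.testing.assert_allclose(pg.apply_anomalies(base, zero)["T_winter"],
                                   base["T_winter"])

    def test_precipitation_floored_at_zero_with_warning(self):
        base = {"P_winter": np.array([5.0])}
        deltas = pd.DataFrame({"variable": ["P_winter"], "delta": [-8.0]})
        with pytest.warns(UserWarning, match="floored"):
            out = pg.apply_anomalies(base, deltas)
        assert out["P_winter"][0] == 0.0


class TestProjectLdps:
    def _setup(self, delta_spring=1.5, noise_sd=3.0, n_cells=200, seed=61):
        rng = np.random.default_rng(seed)
        grid = pg.make_grid((0, n_cells, 0, 1))
        years = np.arange(1972, 2005)
        t_spring = pg.AnnualField(grid, years, rng.normal(10, 1, (n_cells, 33)))
        ldps_vals = 120.0 - 8.0 * t_spring.values + rng.normal(0, noise_sd, (n_cells, 33))
        ldps = pg.AnnualField(grid, years, ldps_vals)
        predictors = {"T_spring": t_spring}
        base = float(np.mean(t_spring.values))
        projected = {"T_spring": np.full(n_cells, base + delta_spring)}
        return ldps, predictors, projected, t_spring

    def test_known_slope_projects_expected_shift(self):
        ldps, predictors, projected, t_spring = self._setup()
        out = pg.project_ldps(ldps, predictors, projected)
        # +1.5 degC at -8 days/degC -> about 12 days earlier than baseline fit
        shift = out["ldps_proj"] - out["ldps_fitted_baseline"]
        # cell-mean T differs from the domain mean, so allow per-cell slack
        assert np.mean(shift) == pytest.approx(-12.0, abs=2.0)

    def test_zero_delta_returns_baseline_fit(self):
        ldps, predictors, projected, t_spring = self._setup()
        proj0 = {"T_spring": np.nanmean(t_spring.values, axis=1)}
        out = pg.project_ldps(ldps, predictors, proj0)
        np.testing.assert_allclose(out["ldps_proj"], out["ldps_fitted_baseline"],
                                   atol=1e-8)

    def test_insufficient_cells_missing(self):
        ldps, predictors, projected, t_spring = self._setup()
        ldps.values[5, 2:] = np.nan  # too few complete years
        out = pg.project_ldps(ldps, predictors, projected)
        assert 5 not in out.index


class TestProjectAndPercentChange:
    def _model(self, p=0.01, terms=("T_summer",), coefs=(0.8,), intercept=2.0):
        coef = {"Intercept": intercept, **dict(zip(terms, coefs))}
        se = {k: 0.1 for k in coef}
        z = {k: v / 0.1 for k, v in coef.items()}
        return pg.CellModel(0, list(terms), coef, se, z, 0.7, p, -10.0, 33)

    def test_closed_form_projection(self):
        m = self._model()
        ldps_proj = pd.DataFrame({"ldps_proj": []},
                                 index=pd.Index([], dtype=int))
        out = pg.project_log_aab({0: m}, {"T_summer": np.array([2.0])}, ldps_proj)
        # log-AAB = 2 + 0.8*2 = 3.6
        assert out.loc[0, "aab_proj"] == pytest.approx(np.exp(3.6) - 1.0)

    def test_insignificant_model_excluded(self):
        m = self._model(p=0.5)
        out = pg.project_log_aab({0: m}, {"T_summer": np.array([2.0])},
                                 pd.DataFrame())
        assert out.loc[0, "reason"] == "not-significant"

    def test_missing_predictor_reported(self):
        m = self._model(terms=("P_spring",), coefs=(0.1,))
        out = pg.project_log_aab({0: m}, {"T_summer": np.array([2.0])},
                                 pd.DataFrame())
        assert out.loc[0, "reason"].startswith("missing-predictor")

    @pytest.mark.parametrize("ratio, expected", [(1.0, 0.0), (10.0, 900.0),
                                                 (0.5, -50.0)])
    def test_percent_change_arithmetic(self, small_grid, ratio, expected):
        years = np.arange(2000, 2011)
        base_vals = np.full((small_grid.n_cells, len(years)), 100.0)
        baseline = pg.AnnualField(small_grid, years, base_vals)
        projected = pd.DataFrame({"aab_proj": [100.0 * ratio],
                                  "log_aab_proj": [np.nan], "reason": [""]},
                                 index=[0])
        out = pg.percent_change(projected, baseline, (2000, 2010))
        assert out["pct_change"].iloc[0] == pytest.approx(expected)

    def test_zero_baseline_median_flagged(self, small_grid):
        years = np.arange(2000, 2011)
        baseline = pg.AnnualField(small_grid, years,
                                  np.zeros((small_grid.n_cells, len(years))))
        projected = pd.DataFrame({"aab_proj": [50.0], "log_aab_proj": [np.nan],
                                  "reason": [""]}, index=[0])
        out = pg.percent_change(projected, baseline, (2000, 2010))
        assert out["flag"].iloc[0] != ""
        assert np.isnan(out["pct_change"].iloc[0])

    def test_percent_change_scale_invariant(self, small_grid):
        years = np.arange(2000, 2011)
        rng = np.random.default_rng(62)
        vals = rng.uniform(10, 100, (small_grid.n_cells, len(years)))
        for lam in (1.0, 7.3):
            baseline = pg.AnnualField(small_grid, years, lam * vals)
            projected = pd.DataFrame({"aab_proj": [lam * 55.0],
                                      "log_aab_proj": [np.nan], "reason": [""]},
                                     index=[3])
            out = pg.percent_change(projected, baseline, (2000, 2010))
            if lam == 1.0:
                ref = out["pct_change"].iloc[0]
            else:
                assert out["pct_change"].iloc[0] == pytest.approx(ref)


class TestRegionalSummary:
    def _changes(self, groups):
        rows = []
        cid = 0
        regions = {}
        for reg, vals in groups.items():
            for v in vals:
                rows.append({"cell_id": cid, "aab_proj": 1.0,
                             "baseline_median": 1.0, "pct_change": v, "flag": ""})
                regions[cid] = reg
                cid += 1
        return pd.DataFrame(rows), pd.Series(regions)

    def test_disjoint_regions_get_distinct_letters(self):
        rng = np.random.default_rng(63)
        changes, regions = self._changes({
            "lo": rng.uniform(0, 10, 30), "hi": rng.uniform(100, 200, 30)})
        out = pg.regional_summary(changes, regions)
        letters = dict(zip(out["region"], out["letters"]))
        assert set(letters["lo"]) & set(letters["hi"]) == set()

    def test_identical_regions_share_a_letter(self):
        rng = np.random.default_rng(64)
        vals = rng.uniform(0, 10, 30)
        changes, regions = self._changes({"a": vals, "b": vals, "c": vals})
        out = pg.regional_summary(changes, regions)
        shared = set.intersection(*(set(l) for l in out["letters"]))
        assert shared

    def test_null_pairwise_rejection_rate_bounded(self):
        rng = np.random.default_rng(65)
        rejections = 0
        reps = 500
        for _ in range(reps):
            changes, regions = self._changes({
                "a": rng.normal(50, 10, 200), "b": rng.normal(50, 10, 200)})
            out = pg.regional_summary(changes, regions)
            la, lb = out["letters"].tolist()
            rejections += set(la) & set(lb) == set()
        assert rejections / reps <= 0.05

    def test_single_region_rejected(self):
        changes, regions = self._changes({"only": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            pg.regional_summary(changes, regions)


class TestCompactLetters:
    def test_no_differences_single_letter(self):
        out = compact_letters(["a", "b", "c"], set())
        assert len(set(out.values())) == 1

    def test_chain_structure(self):
        # a != c, but b overlaps both
        out = compact_letters(["a", "b", "c"], {("a", "c")})
        assert set(out["a"]) & set(out["c"]) == set()
        assert set(out["a"]) & set(out["b"]) or set(out["b"]) & set(out["c"])

    def test_all_different(self):
        out = compact_letters([1, 2, 3], {(1, 2), (1, 3), (2, 3)})
        assert len({out[1], out[2], out[3]}) == 3
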
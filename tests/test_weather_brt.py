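"""Boosting engine: trees, stepwise CV selection, influence, dependence."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from aeroecho.diel_mtr import DielPeriodRecord
from aeroecho.weather_brt import (
    BrtConfig,
    Design,
    average_weather_by_period,
    build_design,
    fit_brt,
    partial_dependence,
    predictor_correlations,
    relative_influence,
    step_select,
)


def _noise_design(n=200, p=5, seed=0, signal=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(p)})
    y = rng.normal(size=n) if signal is None else signal(X) + rng.normal(0, 0.1, n)
    return Design(X=X, y=np.asarray(y), categorical=())


class TestFitBrt:
    def test_single_split_recovers_step_function(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        y = np.where(X["x"] > 0.2, 3.0, -1.0)
        cfg = BrtConfig(learning_rate=1.0, tree_complexity=1, bag_fraction=1.0,
                        min_obs_in_node=5, seed=0)
        model = fit_brt(Design(X=X, y=y, categorical=()), cfg, n_trees=1)
        resid = y - model.predict(X, n_trees=1)
        assert np.abs(resid).max() < 1e-9

    def test_training_deviance_never_increases(self):
        d = _noise_design(n=150, seed=3, signal=lambda X: 1.5 * X["x0"])
        model = fit_brt(d, BrtConfig(seed=7), n_trees=150)
        path = np.array(model.training_deviance_path)
        assert np.all(np.diff(path) <= 1e-10)

    def test_constant_response_rejected(self):
        d = _noise_design(n=50)
        d.y = np.ones(50)
        with pytest.raises(ValueError, match="constant"):
            fit_brt(d, n_trees=10)

    def test_duplicated_dataset_leaves_predictions_unchanged(self):
        """With full bagging the fit depends on the empirical distribution
        only, so duplicating every row changes nothing."""
        d = _noise_design(n=120, seed=4, signal=lambda X: X["x0"] + X["x1"] ** 2)
        # min_obs_in_node=1 so the leaf-size floor binds identically at
        # both data scales; otherwise doubling row counts relaxes it
        cfg = BrtConfig(bag_fraction=1.0, min_obs_in_node=1, tree_complexity=4, seed=5)
        m1 = fit_brt(d, cfg, n_trees=60)
        dup = Design(
            X=pd.concat([d.X, d.X], ignore_index=True),
            y=np.concatenate([d.y, d.y]),
            categorical=(),
        )
        m2 = fit_brt(dup, cfg, n_trees=60)
        p1 = m1.predict(d.X)
        p2 = m2.predict(d.X)
        assert np.abs(p1 - p2).max() < 1e-6

    def test_prediction_invariant_to_column_order(self):
        d = _noise_design(n=120, seed=8, signal=lambda X: 2 * X["x2"])
        cfg = BrtConfig(seed=2)
        model = fit_brt(d, cfg, n_trees=40)
        shuffled = d.X[list(reversed(d.X.columns))]
        assert np.allclose(model.predict(d.X), model.predict(shuffled))

    def test_categorical_site_splits(self):
        rng = np.random.default_rng(9)
        n = 200
        site = rng.choice(["a", "b", "c"], size=n)
        X = pd.DataFrame({"x0": rng.normal(size=n), "site_id": site})
        y = np.where(site == "b", 4.0, 0.0) + rng.normal(0, 0.1, n)
        model = fit_brt(Design(X=X, y=y, categorical=("site_id",)),
                        BrtConfig(seed=0), n_trees=100)
        ri = relative_influence(model)
        assert ri["site_id"] > 80.0


class TestRelativeInfluence:
    def test_sums_to_hundred_and_nonnegative(self):
        d = _noise_design(n=150, seed=11, signal=lambda X: X["x0"] - X["x3"])
        model = fit_brt(d, BrtConfig(seed=1), n_trees=80)
        ri = relative_influence(model)
        assert sum(ri.values()) == pytest.approx(100.0, abs=1e-6)
        assert all(v >= 0 for v in ri.values())

    def test_planted_dominant_predictor(self):
        """y = 2·x₁ + noise against 8 noise predictors → x₁ > 80%."""
        d = _noise_design(n=500, p=9, seed=12, signal=lambda X: 2.0 * X["x0"])
        model = fit_brt(d, BrtConfig(seed=3), n_trees=150)
        assert relative_influence(model)["x0"] > 80.0

    def test_influence_ranking_recovered_across_seeds(self):
        """β₁ > β₂ > 0, rest null: ranking x0 > x1 > others in ≥18/20 seeds."""
        hits = 0
        for seed in range(20):
            d = _noise_design(
                n=300, p=6, seed=200 + seed,
                signal=lambda X: 2.0 * X["x0"] + 0.8 * X["x1"],
            )
            model = fit_brt(d, BrtConfig(seed=seed), n_trees=120)
            ri = relative_influence(model)
            rest = max(v for k, v in ri.items() if k not in ("x0", "x1"))
            hits += ri["x0"] > ri["x1"] > rest
        assert hits >= 18

    def test_agrees_with_sklearn_oracle_on_top_predictor(self):
        """Independent gradient-boosting implementation ranks the same
        dominant predictor on identical data."""
        from sklearn.ensemble import GradientBoostingRegressor

        d = _noise_design(n=300, p=6, seed=31, signal=lambda X: 1.5 * X["x2"])
        mine = fit_brt(d, BrtConfig(seed=0), n_trees=150)
        ri = relative_influence(mine)
        gbr = GradientBoostingRegressor(
            n_estimators=150, learning_rate=0.01, max_depth=3, subsample=0.75,
            random_state=0,
        ).fit(d.X, d.y)
        oracle_top = d.X.columns[np.argmax(gbr.feature_importances_)]
        assert max(ri, key=ri.get) == oracle_top == "x2"


class TestStepSelect:
    def test_null_data_low_cv_correlation(self):
        """Pure-noise responses: tiny selected ensembles, |r| < 0.15."""
        corrs, sizes = [], []
        for seed in range(10):
            d = _noise_design(n=300, p=5, seed=400 + seed)
            cfg = BrtConfig(seed=seed, n_folds=10, max_trees=400)
            model = step_select(d, cfg)
            corrs.append(model.cv_correlation)
            sizes.append(model.n_trees_selected)
        assert np.mean(np.abs(corrs)) < 0.15
        assert np.median(sizes) <= 2 * 25  # at or near the first steps

    def test_planted_signal_high_cv_correlation(self):
        d = _noise_design(
            n=400, p=6, seed=55,
            signal=lambda X: 2.0 * X["x0"] + np.sin(2 * X["x1"]),
        )
        model = step_select(d, BrtConfig(seed=1, max_trees=1500))
        assert model.cv_correlation > 0.6
        assert model.n_trees_selected >= 25
        # CV path reaches its minimum at the selected size
        assert min(model.cv_deviance_path) == pytest.approx(
            model.cv_deviance_path[model.n_trees_selected // 25 - 1]
        )

    def test_deterministic_per_seed(self):
        d = _noise_design(n=100, p=4, seed=77, signal=lambda X: X["x0"])
        cfg = BrtConfig(seed=13, n_folds=5, max_trees=300)
        m1 = step_select(d, cfg)
        m2 = step_select(d, cfg)
        assert m1.n_trees_selected == m2.n_trees_selected
        assert m1.cv_correlation == m2.cv_correlation
        assert np.array_equal(m1.oof_predictions, m2.oof_predictions)


class TestPartialDependence:
    def test_flat_for_never_split_predictor(self):
        d = _noise_design(n=200, p=4, seed=90, signal=lambda X: 3.0 * X["x0"])
        model = fit_brt(d, BrtConfig(seed=0), n_trees=100)
        if relative_influence(model)["x3"] == 0.0:
            curve = partial_dependence(model, "x3")
            assert curve["prediction"].std() == pytest.approx(0.0, abs=1e-12)

    def test_monotone_positive_effect_recovered(self):
        d = _noise_design(n=300, p=5, seed=91, signal=lambda X: 1.2 * X["x0"])
        model = fit_brt(d, BrtConfig(seed=4), n_trees=200)
        curve = partial_dependence(model, "x0")
        diffs = np.diff(curve["prediction"])
        assert (diffs >= -1e-9).mean() >= 0.95

    def test_negative_effect_signed_correctly(self):
        from scipy.stats import spearmanr

        d = _noise_design(n=300, p=5, seed=92, signal=lambda X: -1.2 * X["x1"])
        model = fit_brt(d, BrtConfig(seed=5), n_trees=200)
        curve = partial_dependence(model, "x1")
        rho = spearmanr(curve["grid"], curve["prediction"]).statistic
        assert rho < -0.9

    def test_out_of_range_grid_warns(self):
        d = _noise_design(n=100, p=3, seed=93, signal=lambda X: X["x0"])
        model = fit_brt(d, BrtConfig(seed=0), n_trees=30)
        with pytest.warns(UserWarning, match="grid"):
            partial_dependence(model, "x0", grid=np.array([-50.0, 0.0, 50.0]))


def _hourly(site="hula", start="2021-04-01", hours=72, u=1.0):
    times = pd.date_range(start, periods=hours, freq="h", tz="UTC")
    return pd.DataFrame(
        {
            "time": times,
            "site_id": site,
            "temperature_c": np.linspace(10, 20, hours),
            "u_wind_ms": u,
            "v_wind_ms": -1.0,
            "humidity_pct": 50.0,
            "cloud_cover": 0.2,
            "vorticity_s1": 0.0,
            "vertical_motion_pa_s": 0.0,
        }
    )


def _period(date, start_h, end_h, phase="day"):
    return DielPeriodRecord(
        site_id="hula", date=date, phase=phase,
        start=pd.Timestamp(f"{date} {start_h}", tz="UTC"),
        end=pd.Timestamp(f"{date} {end_h}", tz="UTC"),
        sunrise=pd.Timestamp(f"{date} {start_h}", tz="UTC"),
        sunset=pd.Timestamp(f"{date} {end_h}", tz="UTC"),
    )


class TestPeriodWeather:
    def test_constant_field_mean_is_constant(self):
        pw = average_weather_by_period(_hourly(), [_period(dt.date(2021, 4, 1), "04:00", "16:00")])
        assert pw["u_wind_ms"].iloc[0] == pytest.approx(1.0)

    def test_two_hour_mean(self):
        hourly = _hourly(hours=4)
        hourly.loc[hourly.index[:2], "u_wind_ms"] = [0.0, 2.0]
        pw = average_weather_by_period(hourly, [_period(dt.date(2021, 4, 1), "00:00", "02:00")])
        assert pw["u_wind_ms"].iloc[0] == pytest.approx(1.0)

    def test_unmatched_period_flagged_missing(self):
        pw = average_weather_by_period(_hourly(hours=5), [_period(dt.date(2022, 1, 1), "04:00", "16:00")])
        assert pw["missing"].iloc[0]

    def test_matches_brute_force_grouping(self):
        hourly = _hourly(hours=96)
        rng = np.random.default_rng(0)
        hourly["temperature_c"] = rng.normal(15, 3, len(hourly))
        periods = [
            _period(dt.date(2021, 4, 1), "03:00", "15:00"),
            _period(dt.date(2021, 4, 2), "03:00", "15:00"),
        ]
        pw = average_weather_by_period(hourly, periods)
        for i, per in enumerate(periods):
            manual = [
                row.temperature_c
                for row in hourly.itertuples()
                if per.start <= row.time < per.end
            ]
            assert pw["temperature_c"].iloc[i] == pytest.approx(np.mean(manual))


class TestBuildDesign:
    def _mtr(self, mtrs, phase="day", start=dt.date(2021, 4, 1)):
        return pd.DataFrame(
            {
                "site_id": "hula",
                "date": [start + dt.timedelta(days=i) for i in range(len(mtrs))],
                "phase": phase,
                "mtr": mtrs,
            }
        )

    def _pw(self, n, phase="day", start=dt.date(2021, 4, 1)):
        rng = np.random.default_rng(1)
        return pd.DataFrame(
            {
                "site_id": "hula",
                "date": [start + dt.timedelta(days=i) for i in range(n)],
                "phase": phase,
                **{f: rng.normal(size=n) for f in (
                    "temperature_c", "u_wind_ms", "v_wind_ms", "humidity_pct",
                    "cloud_cover", "vorticity_s1", "vertical_motion_pa_s")},
                "missing": False,
            }
        )

    def test_log_response_contract(self):
        d = build_design(self._mtr([0.0, np.e - 1.0, 10.0]), self._pw(3))
        assert d.y[0] == pytest.approx(0.0)
        assert d.y[1] == pytest.approx(1.0)

    def test_disjoint_join_raises(self):
        with pytest.raises(ValueError, match="empty design"):
            build_design(self._mtr([1.0, 2.0]), self._pw(2, start=dt.date(2022, 1, 1)))

    def test_unmatched_rows_counted(self):
        d = build_design(self._mtr([1.0] * 5), self._pw(3))
        assert d.n_unmatched == 2

    def test_predictor_correlation_report_flags_collinear(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=100)})
        X["b"] = X["a"] + rng.normal(0, 0.05, 100)
        X["c"] = rng.normal(size=100)
        rep = predictor_correlations(Design(X=X, y=np.zeros(100), categorical=()))
        flagged = rep[rep["high"]]
        assert set(zip(flagged["a"], flagged["b"])) == {("a", "b")}
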
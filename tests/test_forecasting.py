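import numpy as np
import pytest

from svimon.data_model import (
    ProcessSeries,
    SizeError,
    Standardizer,
    ValidationError,
    make_lag_design,
)
from svimon.forecasting import (
    BoundedForecastStep,
    ForecastTrajectory,
    MSModel,
    fit_ms_model,
    fit_os_model,
    load_model,
    model_from_dict,
    model_to_dict,
    ms_forecast,
    ms_forecaster,
    os_forecaster,
    os_predict,
    rolling_evaluate,
    save_model,
)
from svimon.gpr_core import Hyperparams, KernelSpec, build_gp, predict_mean_var


def _decay_map_model(phi=0.8, n_lags=0):
    """An MS model that has exactly learned y_{t+1} = phi * y_t.

    Training values form the geometric orbit {phi^k}, so plugin
    recursion only ever queries training inputs (exact interpolation).
    """
    v = phi ** np.arange(12)
    design = make_lag_design(v, n_lags)
    xs = Standardizer().fit(design.X)
    ys = Standardizer().fit(design.y[:, None])
    gp = build_gp(
        xs.transform(design.X),
        ys.transform(design.y[:, None]).ravel(),
        KernelSpec("squared_exp"),
        Hyperparams(1.0, 0.35, 1e-12),
    )
    return MSModel(gp=gp, x_scaler=xs, y_scaler=ys, n_lags=n_lags)


class TestBoundedStep:
    def test_envelope_identities(self):
        s = BoundedForecastStep(h=1, mean=150.0, variance=25.0)
        assert s.upper - s.mean == pytest.approx(2 * s.sigma)
        assert s.mean - s.lower == pytest.approx(2 * s.sigma)
        assert s.upper - s.lower == pytest.approx(4 * s.sigma)

    def test_zero_variance_collapses_envelope(self):
        s = BoundedForecastStep(h=1, mean=120.0, variance=0.0)
        assert s.lower == s.mean == s.upper

    def test_trajectory_requires_consecutive_horizons(self):
        s1 = BoundedForecastStep(h=1, mean=1.0, variance=1.0)
        s3 = BoundedForecastStep(h=3, mean=1.0, variance=1.0)
        with pytest.raises(ValidationError):
            ForecastTrajectory(origin_t=0, steps=(s1, s3))


class TestOSPredict:
    @pytest.fixture(scope="class")
    def os_model(self, episode42):
        return fit_os_model(episode42.series, n_train=30, n_restarts=2, seed=0)

    def test_missing_covariate_named_in_error(self, os_model, episode42):
        cov = dict(episode42.series[0].covariates)
        del cov["cod"]
        with pytest.raises(ValidationError, match="cod"):
            os_predict(os_model, cov)

    def test_composition_equals_predict_gp_plus_bounds(self, os_model, episode42):
        sample = episode42.series[35]
        step = os_predict(os_model, sample.covariates)
        x = np.array([sample.covariates[c] for c in os_model.covariate_names])
        xs = os_model.x_scaler.transform(x[None, :])
        mean_s, var_s = predict_mean_var(os_model.gp, xs)
        mean = os_model.y_scaler.inverse_transform(mean_s[:, None]).ravel()[0]
        var = os_model.y_scaler.inverse_transform_variance(var_s)[0]
        assert step.mean == pytest.approx(mean, abs=1e-10)
        assert step.variance == pytest.approx(var, abs=1e-10)
        assert step.upper == pytest.approx(mean + 2 * np.sqrt(var), abs=1e-10)


class TestMSForecast:
    def test_h1_equals_single_prediction_both_modes(self, episode42):
        svi = episode42.series.svi
        model = fit_ms_model(svi[:60], n_lags=7, n_restarts=2, seed=1)
        recent = svi[52:60]
        plug = ms_forecast(model, recent, H=1, propagation="plugin")
        x = recent[::-1][None, :]
        mean_s, var_s = predict_mean_var(model.gp, model.x_scaler.transform(x))
        mean = model.y_scaler.inverse_transform(mean_s[:, None]).ravel()[0]
        var = model.y_scaler.inverse_transform_variance(var_s)[0]
        assert plug.steps[0].mean == pytest.approx(mean, abs=1e-10)
        assert plug.steps[0].variance == pytest.approx(var, abs=1e-10)
        mc = ms_forecast(model, recent, H=1, propagation="monte_carlo",
                         n_samples=4000, seed=2)
        assert mc.steps[0].mean == pytest.approx(mean, abs=3 * np.sqrt(var / 4000) + 1e-6)

    def test_plugin_follows_learned_linear_decay(self):
        model = _decay_map_model(phi=0.8)
        traj = ms_forecast(model, [1.0], H=6, propagation="plugin")
        np.testing.assert_allclose(traj.means, 0.8 ** np.arange(1, 7), atol=1e-6)

    def test_monte_carlo_variance_dominates_plugin_beyond_h1(self, episode42):
        svi = episode42.series.svi
        model = fit_ms_model(svi[:120], n_lags=7, n_restarts=2, seed=3)
        recent = svi[112:120]
        plug = ms_forecast(model, recent, H=4, propagation="plugin")
        mc = ms_forecast(model, recent, H=4, propagation="monte_carlo",
                         n_samples=2000, seed=4)
        for h in range(1, 4):
            assert mc.steps[h].variance >= plug.steps[h].variance * 0.95

    def test_seed_determinism_in_monte_carlo(self, episode42):
        svi = episode42.series.svi
        model = fit_ms_model(svi[:60], n_lags=7, n_restarts=2, seed=1)
        a = ms_forecast(model, svi[52:60], H=3, propagation="monte_carlo", seed=9)
        b = ms_forecast(model, svi[52:60], H=3, propagation="monte_carlo", seed=9)
        assert a.means.tolist() == b.means.tolist()

    def test_near_constant_series_stays_flat_with_variance_floor(self):
        rng = np.random.default_rng(0)
        v = 100.0 + 0.01 * rng.normal(size=40)
        model = fit_ms_model(v, n_lags=3, n_restarts=2, seed=0)
        traj = ms_forecast(model, v[-4:], H=5, propagation="plugin")
        assert np.all(np.abs(traj.means - 100.0) < 1.0)
        floor = traj.steps[0].variance
        # near-constant training: reported variance stays at the one-step
        # floor up to the tiny jitter the standardizer requires
        assert np.all([0.5 * floor <= s.variance <= 2.0 * floor for s in traj.steps])

    def test_domain_errors(self, episode42):
        svi = episode42.series.svi
        model = fit_ms_model(svi[:60], n_lags=7, n_restarts=2, seed=1)
        with pytest.raises(ValidationError):
            ms_forecast(model, svi[52:60], H=0)
        with pytest.raises(ValidationError):
            ms_forecast(model, svi[52:60], H=2, propagation="monte_carlo", n_samples=1)
        with pytest.raises(ValidationError):
            ms_forecast(model, svi[50:60], H=2)

    def test_standardization_round_trip_matches_raw_units(self):
        # with centred data the standardized GP is analytically identical
        # to a raw-unit GP with rescaled hyperparameters
        rng = np.random.default_rng(5)
        v = 40.0 * np.sin(np.linspace(0, 6, 30)) + rng.normal(0, 2, 30)
        v = v - v.mean()
        model = fit_ms_model(v, n_lags=1, n_restarts=2, seed=0,
                             spec=KernelSpec("squared_exp"))
        traj = ms_forecast(model, v[-2:], H=3, propagation="plugin")
        # raw-unit equivalent: ARD SE with l_j -> l * s_xj, sf2 -> sf2 * s_y^2
        th = model.gp.theta
        sx = model.x_scaler.scale_
        sy = float(model.y_scaler.scale_[0])
        my = float(model.y_scaler.mean_[0])
        raw_th = Hyperparams(
            th.signal_variance * sy**2,
            th.length_scales[0] * sx,
            th.noise_variance * sy**2,
        )
        design = make_lag_design(v, 1)
        raw_gp = build_gp(design.X, design.y - my, KernelSpec("squared_exp", ard=True),
                          raw_th)
        window = v[-2:]
        for step in traj.steps:
            mean, var = predict_mean_var(raw_gp, window[::-1][None, :])
            assert step.mean == pytest.approx(mean[0] + my, abs=1e-6)
            assert step.variance == pytest.approx(var[0], rel=1e-6, abs=1e-8)
            window = np.append(window[1:], step.mean)


class TestRollingEvaluate:
    def _series(self):
        rng = np.random.default_rng(1)
        return ProcessSeries.from_arrays(svi=rng.uniform(80, 120, 30))

    def test_perfect_predictor_has_zero_rmse_and_unit_r(self):
        s = self._series()
        res = rolling_evaluate(lambda hist, h: s.svi[len(hist) - 1 + h], s, h=2,
                               test_index=range(10, 30))
        assert res.rmse == 0.0
        assert res.r == 1.0

    def test_constant_predictor_hand_rmse(self):
        s = ProcessSeries.from_arrays(svi=[100.0, 100.0, 90.0, 110.0])
        res = rolling_evaluate(lambda hist, h: 100.0, s, h=1, test_index=[2, 3])
        assert res.rmse == pytest.approx(10.0)

    def test_horizon_beyond_history_is_coverage_error(self):
        s = self._series()
        with pytest.raises(SizeError):
            rolling_evaluate(lambda hist, h: 100.0, s, h=5, test_index=[3])

    def test_h1_os_evaluation_matches_pointwise_os_predict(self, episode42):
        series = episode42.series.slice(0, 60)
        model = fit_os_model(series, n_train=40, n_restarts=2, seed=0)
        fc = os_forecaster(model, series)
        res = rolling_evaluate(fc, series, h=1, test_index=range(45, 55))
        direct = [os_predict(model, series[t].covariates).mean for t in range(45, 55)]
        np.testing.assert_allclose(res.predicted, direct, atol=1e-12)


class TestModelSerialization:
    def test_ms_round_trip_preserves_forecasts(self, tmp_path, episode42):
        svi = episode42.series.svi
        model = fit_ms_model(svi[:60], n_lags=7, n_restarts=2, seed=1)
        path = tmp_path / "ms.json"
        save_model(model, path)
        back = load_model(path)
        a = ms_forecast(model, svi[52:60], H=4)
        b = ms_forecast(back, svi[52:60], H=4)
        np.testing.assert_allclose(a.means, b.means, rtol=1e-12)

    def test_os_round_trip(self, episode42):
        model = fit_os_model(episode42.series, n_train=30, n_restarts=2, seed=0)
        back = model_from_dict(model_to_dict(model))
        cov = episode42.series[40].covariates
        assert os_predict(back, cov).mean == pytest.approx(
            os_predict(model, cov).mean, rel=1e-12
        )
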
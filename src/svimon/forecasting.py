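"""One-step and recursive multi-step SVI forecasting with 2-sigma bounds.

The one-step (OS) model regresses SVI on the eight current process
covariates.  The multi-step (MS) model is an autoregression on the last
``n_lags + 1`` SVI values; forecasts beyond one day are produced by the
recursive strategy — feed the value just forecast back into the lag
window and apply the same one-step model until the horizon H is reached.

Uncertainty over the horizon is propagated either by the plugin rule
(report the GP's one-step variance at the plugged-in input) or by Monte
Carlo (roll many trajectories sampling each step from its one-step
Gaussian and take empirical per-horizon moments).  Every step carries
the envelope y- = mean - 2 sigma, y+ = mean + 2 sigma used by the
monitoring automaton.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .data_model import (
    COVARIATE_NAMES,
    ProcessSeries,
    SizeError,
    Standardizer,
    ValidationError,
    make_lag_design,
)
from .gpr_core import (
    GPModel,
    KernelSpec,
    fit_gp,
    gp_from_dict,
    gp_to_dict,
    predict_mean_var,
)

from .baselines import pearson_r, rmse


# ---------------------------------------------------------------------------
# Forecast containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundedForecastStep:
    """Forecast for one horizon step with its 2-sigma envelope (mL/g)."""

    h: int
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValidationError("horizon step h must be >= 1")
        if self.variance < 0:
            raise ValidationError("variance must be non-negative")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.variance)

    @property
    def lower(self) -> float:
        """y- = mean - 2 sigma."""
        return self.mean - 2.0 * self.sigma

    @property
    def upper(self) -> float:
        """y+ = mean + 2 sigma."""
        return self.mean + 2.0 * self.sigma


@dataclass(frozen=True)
class ForecastTrajectory:
    """H consecutive bounded forecast steps from one origin time."""

    origin_t: int
    steps: tuple[BoundedForecastStep, ...]
    propagation: str = "plugin"

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise ValidationError("trajectory needs at least one step")
        for i, s in enumerate(self.steps, start=1):
            if s.h != i:
                raise ValidationError("horizons must run consecutively from 1")

    @property
    def horizon(self) -> int:
        return len(self.steps)

    @property
    def means(self) -> np.ndarray:
        return np.array([s.mean for s in self.steps])

    @property
    def uppers(self) -> np.ndarray:
        return np.array([s.upper for s in self.steps])

    @property
    def lowers(self) -> np.ndarray:
        return np.array([s.lower for s in self.steps])

    @property
    def max_upper(self) -> float:
        return float(self.uppers.max())

    @property
    def max_mean(self) -> float:
        return float(self.means.max())


# ---------------------------------------------------------------------------
# Fitted model wrappers (GP + standardization, original-unit predictions)
# ---------------------------------------------------------------------------

@dataclass
class OSModel:
    """One-step model: GP from standardized covariates to standardized SVI."""

    gp: GPModel
    x_scaler: Standardizer
    y_scaler: Standardizer
    covariate_names: tuple[str, ...] = COVARIATE_NAMES
    include_noise: bool = False

    kind: str = field(default="OS", init=False)


@dataclass
class MSModel:
    """Multi-step model: GP on the SVI lag embedding."""

    gp: GPModel
    x_scaler: Standardizer
    y_scaler: Standardizer
    n_lags: int = 7
    include_noise: bool = False

    kind: str = field(default="MS", init=False)


def fit_os_model(
    series: ProcessSeries,
    n_train: int = 50,
    spec: KernelSpec | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    include_noise: bool = False,
    forward_fill: bool = False,
) -> OSModel:
    """Fit the one-step GP on the first ``n_train`` samples of a record."""
    if len(series) < n_train:
        raise SizeError(f"series length {len(series)} < n_train={n_train}")
    names = series.covariate_names
    missing = set(COVARIATE_NAMES) - set(names)
    if missing:
        raise ValidationError(f"series lacks OS covariates: {sorted(missing)}")
    spec = spec or KernelSpec(family="additive")
    train = series.slice(0, n_train)
    X = train.covariate_matrix(COVARIATE_NAMES, forward_fill=forward_fill)
    y = train.svi
    xs = Standardizer().fit(X)
    ys = Standardizer().fit(y[:, None])
    gp = fit_gp(xs.transform(X), ys.transform(y[:, None]).ravel(), spec,
                n_restarts=n_restarts, seed=seed)
    return OSModel(gp=gp, x_scaler=xs, y_scaler=ys,
                   covariate_names=COVARIATE_NAMES, include_noise=include_noise)


def fit_ms_model(
    values,
    n_lags: int = 7,
    spec: KernelSpec | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    include_noise: bool = False,
) -> MSModel:
    """Fit the lag-embedding GP on an SVI history (1-D values or series)."""
    spec = spec or KernelSpec(family="additive")
    design = make_lag_design(values, n_lags)
    xs = Standardizer().fit(design.X)
    ys = Standardizer().fit(design.y[:, None])
    gp = fit_gp(xs.transform(design.X), ys.transform(design.y[:, None]).ravel(),
                spec, n_restarts=n_restarts, seed=seed)
    return MSModel(gp=gp, x_scaler=xs, y_scaler=ys, n_lags=n_lags,
                   include_noise=include_noise)


def _predict_original_units(
    model: OSModel | MSModel, X_raw: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predict in mL/g by standardizing inputs and back-transforming outputs."""
    Xs = model.x_scaler.transform(np.atleast_2d(X_raw))
    mean_s, var_s = predict_mean_var(model.gp, Xs, include_noise=model.include_noise)
    mean = model.y_scaler.inverse_transform(mean_s[:, None]).ravel()
    var = model.y_scaler.inverse_transform_variance(var_s)
    return mean, var


# ---------------------------------------------------------------------------
# One-step prediction
# ---------------------------------------------------------------------------

def os_predict(
    model: OSModel, covariates_now: Mapping[str, float] | Sequence[float]
) -> BoundedForecastStep:
    """One-step-ahead SVI prediction from the current process covariates."""
    if isinstance(covariates_now, Mapping):
        missing = [c for c in model.covariate_names if c not in covariates_now
                   or not np.isfinite(covariates_now[c])]
        if missing:
            raise ValidationError(f"missing covariate(s): {missing}")
        x = np.array([covariates_now[c] for c in model.covariate_names], dtype=float)
    else:
        x = np.asarray(covariates_now, dtype=float)
        if x.shape != (len(model.covariate_names),):
            raise ValidationError(
                f"expected {len(model.covariate_names)} covariates, got {x.shape}"
            )
        if not np.all(np.isfinite(x)):
            bad = model.covariate_names[int(np.flatnonzero(~np.isfinite(x))[0])]
            raise ValidationError(f"missing covariate(s): ['{bad}']")
    mean, var = _predict_original_units(model, x[None, :])
    return BoundedForecastStep(h=1, mean=float(mean[0]), variance=float(var[0]))


# ---------------------------------------------------------------------------
# Recursive multi-step forecasting
# ---------------------------------------------------------------------------

def ms_forecast(
    model: MSModel,
    recent_svi: Sequence[float],
    H: int,
    propagation: str = "plugin",
    n_samples: int = 1000,
    seed: int = 0,
    origin_t: int = 0,
) -> ForecastTrajectory:
    """Recursive H-step-ahead forecast from the latest lag window.

    ``recent_svi`` holds the last ``n_lags + 1`` observed SVI values in
    chronological order (most recent last).  In ``plugin`` mode each
    predictive mean is appended to the window and the reported variance
    is the GP's one-step variance at the plugged-in input; in
    ``monte_carlo`` mode ``n_samples`` trajectories are rolled forward,
    sampling every step from its one-step Gaussian, and per-horizon
    moments are empirical.
    """
    if H < 1:
        raise ValidationError(f"horizon H must be >= 1, got {H}")
    if propagation not in ("plugin", "monte_carlo"):
        raise ValidationError(f"unknown propagation mode {propagation!r}")
    recent = np.asarray(recent_svi, dtype=float)
    if recent.shape != (model.n_lags + 1,):
        raise ValidationError(
            f"recent_svi must hold the last {model.n_lags + 1} values"
        )
    if propagation == "plugin":
        window = recent.copy()
        steps = []
        for h in range(1, H + 1):
            x = window[::-1]  # SVI(t), SVI(t-1), ..., SVI(t-n_lags)
            mean, var = _predict_original_units(model, x[None, :])
            steps.append(BoundedForecastStep(h=h, mean=float(mean[0]),
                                             variance=float(var[0])))
            window = np.append(window[1:], mean[0])
        return ForecastTrajectory(origin_t=origin_t, steps=tuple(steps),
                                  propagation="plugin")
    # monte_carlo
    if n_samples < 2:
        raise ValidationError("monte_carlo needs n_samples >= 2")
    rng = np.random.default_rng(seed)
    windows = np.tile(recent, (n_samples, 1))  # (n_samples, n_lags + 1)
    steps = []
    for h in range(1, H + 1):
        X = windows[:, ::-1]
        mean, var = _predict_original_units(model, X)
        draws = rng.normal(mean, np.sqrt(var))
        steps.append(
            BoundedForecastStep(
                h=h, mean=float(draws.mean()), variance=float(draws.var(ddof=1))
            )
        )
        windows = np.column_stack([windows[:, 1:], draws])
    return ForecastTrajectory(origin_t=origin_t, steps=tuple(steps),
                              propagation="monte_carlo")


# ---------------------------------------------------------------------------
# Rolling-origin evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Paired observed/predicted series plus summary accuracy metrics."""

    observed: np.ndarray
    predicted: np.ndarray
    rmse: float
    r: float
    horizon: int
    test_index: np.ndarray


def rolling_evaluate(
    forecaster: Callable[[np.ndarray, int], float],
    series: ProcessSeries,
    h: int,
    test_index: Sequence[int],
) -> EvalResult:
    """Compare h-step-ahead forecasts against the observed series.

    For each test time t, ``forecaster(history, h)`` is called with the
    SVI values observed up to and including t - h and must return the
    forecast for time t.  Returns the paired series with RMSE and the
    Pearson correlation r (guarded to 1 for an exact predictor).
    """
    svi = series.svi
    test_index = np.asarray(test_index, dtype=int)
    if len(test_index) == 0:
        raise ValidationError("empty test index")
    if test_index.min() - h < 1:
        raise SizeError(
            f"horizon {h} exceeds available history at t={int(test_index.min())}"
        )
    preds = np.array(
        [float(forecaster(svi[: t - h + 1], h)) for t in test_index]
    )
    obs = svi[test_index]
    err = rmse(obs, preds)
    if np.allclose(obs, preds):
        r = 1.0
    else:
        try:
            r = pearson_r(obs, preds)
        except ValidationError:
            r = float("nan")
    return EvalResult(observed=obs, predicted=preds, rmse=err, r=r,
                      horizon=h, test_index=test_index)


def os_forecaster(model: OSModel, series: ProcessSeries) -> Callable[[np.ndarray, int], float]:
    """Adapter: the OS covariate model as a ``forecaster(history, h)``.

    The covariates at the target time are looked up in ``series`` (the
    OS model predicts from same-day process variables, so only h = 1 is
    meaningful and the SVI history enters only through its length).
    """

    def forecast(history: np.ndarray, h: int) -> float:
        t = len(history) - 1 + h
        return os_predict(model, series[t].covariates).mean

    return forecast


def ms_forecaster(model: MSModel) -> Callable[[np.ndarray, int], float]:
    """Adapter: an MS GP as a ``forecaster(history, h)`` for evaluation."""

    def forecast(history: np.ndarray, h: int) -> float:
        recent = np.asarray(history, dtype=float)[-(model.n_lags + 1):]
        traj = ms_forecast(model, recent, H=h, propagation="plugin")
        return traj.steps[-1].mean

    return forecast


# ---------------------------------------------------------------------------
# Serialization of fitted wrappers / forecast CSV
# ---------------------------------------------------------------------------

def model_to_dict(model: OSModel | MSModel) -> dict:
    doc = {
        "kind": model.kind,
        "gp": gp_to_dict(model.gp),
        "x_scaler": model.x_scaler.to_dict(),
        "y_scaler": model.y_scaler.to_dict(),
        "include_noise": model.include_noise,
    }
    if model.kind == "MS":
        doc["n_lags"] = model.n_lags
    else:
        doc["covariate_names"] = list(model.covariate_names)
    return doc


def model_from_dict(doc: dict) -> OSModel | MSModel:
    gp = gp_from_dict(doc["gp"])
    xs = Standardizer.from_dict(doc["x_scaler"])
    ys = Standardizer.from_dict(doc["y_scaler"])
    if doc["kind"] == "MS":
        return MSModel(gp=gp, x_scaler=xs, y_scaler=ys, n_lags=int(doc["n_lags"]),
                       include_noise=bool(doc["include_noise"]))
    if doc["kind"] == "OS":
        return OSModel(gp=gp, x_scaler=xs, y_scaler=ys,
                       covariate_names=tuple(doc["covariate_names"]),
                       include_noise=bool(doc["include_noise"]))
    raise ValidationError(f"unknown model kind {doc.get('kind')!r}")


def save_model(model: OSModel | MSModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> OSModel | MSModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def trajectory_rows(traj: ForecastTrajectory) -> list[dict]:
    """Rows for the forecast CSV (t_origin, h, mean, var, lower, upper)."""
    return [
        {
            "t_origin": traj.origin_t,
            "h": s.h,
            "mean": s.mean,
            "var": s.variance,
            "lower": s.lower,
            "upper": s.upper,
            "propagation": traj.propagation,
        }
        for s in traj.steps
    ]
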
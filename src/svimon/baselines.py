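"""Accuracy metrics and linear reference models.

Root-mean-square error and the Pearson coefficient r are the accuracy
criteria used throughout the package.  The reference models are ARMA
(conditional least squares, forecast by the zero-future-innovation
recursion) and PLS1 with VIP scores; ACF/PACF diagnostics support the
choice of the autoregressive lag depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.cross_decomposition import PLSRegression
from statsmodels.tsa.stattools import acf as _sm_acf
from statsmodels.tsa.stattools import pacf as _sm_pacf

from .data_model import DegenerateScaleError, SizeError, ValidationError


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmse(observed, predicted) -> float:
    """Root mean square error sqrt(mean((y_i - yhat_i)^2))."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 1:
        raise SizeError("need at least one pair")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def pearson_r(a, b) -> float:
    """Sample Pearson correlation coefficient in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("pearson_r is undefined for a constant input")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# ARMA by conditional least squares
# ---------------------------------------------------------------------------

@dataclass
class ArmaModel:
    """ARMA(p, q) with intercept, fitted by conditional least squares."""

    p: int
    q: int
    ar_coeffs: np.ndarray
    ma_coeffs: np.ndarray
    intercept: float
    sigma2: float
    aic: float | None = None

    def __post_init__(self) -> None:
        self.ar_coeffs = np.atleast_1d(np.asarray(self.ar_coeffs, dtype=float)) \
            if self.p else np.empty(0)
        self.ma_coeffs = np.atleast_1d(np.asarray(self.ma_coeffs, dtype=float)) \
            if self.q else np.empty(0)
        if len(self.ar_coeffs) != self.p or len(self.ma_coeffs) != self.q:
            raise ValidationError("coefficient lengths must match (p, q)")


def _innovations(y: np.ndarray, c: float, ar: np.ndarray, ma: np.ndarray) -> np.ndarray:
    """Conditional innovations e_t for t = p..n-1 (pre-sample e = 0)."""
    p, q = len(ar), len(ma)
    n = len(y)
    e = np.zeros(n)
    for t in range(p, n):
        pred = c
        for i in range(p):
            pred += ar[i] * y[t - 1 - i]
        for j in range(q):
            if t - 1 - j >= p:
                pred += ma[j] * e[t - 1 - j]
        e[t] = y[t] - pred
    return e


def arma_fit(series, p: int, q: int) -> ArmaModel:
    """Fit ARMA(p, q) by conditional least squares.

    With q = 0 this reduces exactly to ordinary least squares of y_t on
    an intercept and its p lags.  For q > 0 the sum of squared
    conditional innovations is minimized by Levenberg-Marquardt-type
    least squares, started from the pure-AR OLS solution.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    n_par = p + q + 1
    if n - p < n_par + 1:
        raise SizeError(
            f"series of length {n} too short for ARMA({p},{q}); "
            f"need at least {p + n_par + 1}"
        )
    # OLS on lags (exact CLS solution when q = 0; init otherwise)
    design = np.ones((n - p, p + 1))
    for i in range(p):
        design[:, 1 + i] = y[p - 1 - i : n - 1 - i]
    coef, *_ = np.linalg.lstsq(design, y[p:], rcond=None)
    c0, ar0 = float(coef[0]), coef[1:]
    if q == 0:
        e = _innovations(y, c0, ar0, np.empty(0))[p:]
        sigma2 = float(e @ e) / len(e)
        model = ArmaModel(p=p, q=q, ar_coeffs=ar0, ma_coeffs=np.empty(0),
                          intercept=c0, sigma2=sigma2)
    else:
        x0 = np.concatenate([[c0], ar0, np.zeros(q)])

        def resid(vec):
            return _innovations(y, vec[0], vec[1 : 1 + p], vec[1 + p :])[p:]

        sol = least_squares(resid, x0, method="lm")
        e = resid(sol.x)
        sigma2 = float(e @ e) / len(e)
        model = ArmaModel(p=p, q=q, ar_coeffs=sol.x[1 : 1 + p],
                          ma_coeffs=sol.x[1 + p :], intercept=float(sol.x[0]),
                          sigma2=sigma2)
    model.aic = (n - p) * np.log(max(sigma2, 1e-300)) + 2 * n_par
    if p:
        # AR polynomial 1 - phi_1 z - ... - phi_p z^p; stationarity needs
        # all roots outside the unit circle
        roots = np.roots(np.concatenate([[-model.ar_coeffs[i] for i in
                                          range(p - 1, -1, -1)], [1.0]]))
        if np.any(np.abs(roots) <= 1.0 + 1e-10):
            warnings.warn("fitted AR polynomial is not stationary",
                          UserWarning, stacklevel=2)
    return model


def arma_forecast(model: ArmaModel, history, H: int) -> np.ndarray:
    """H-step forecast: iterate the recursion with future innovations 0."""
    y = np.asarray(history, dtype=float)
    if H < 1:
        raise ValidationError("H must be >= 1")
    if len(y) < model.p:
        raise SizeError(f"history shorter than p={model.p}")
    e = _innovations(y, model.intercept, model.ar_coeffs, model.ma_coeffs)
    vals = list(y)
    es = list(e)
    out = []
    for _ in range(H):
        pred = model.intercept
        for i in range(model.p):
            pred += model.ar_coeffs[i] * vals[-1 - i]
        for j in range(model.q):
            pred += model.ma_coeffs[j] * es[-1 - j]
        vals.append(pred)
        es.append(0.0)
        out.append(pred)
    return np.asarray(out)


def arma_select_order(series, p_max: int = 8, q_max: int = 2) -> ArmaModel:
    """Small AIC grid search over 1 <= p <= p_max, 0 <= q <= q_max."""
    best = None
    for p in range(1, p_max + 1):
        for q in range(0, q_max + 1):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = arma_fit(series, p, q)
            except (SizeError, np.linalg.LinAlgError):
                continue
            if best is None or m.aic < best.aic:
                best = m
    if best is None:
        raise SizeError("series too short for any order in the grid")
    return best


# ---------------------------------------------------------------------------
# PLS1 and VIP scores
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """PLS1 regression (NIPALS extraction) with stored projection terms."""

    n_components: int
    weights: np.ndarray      # (p, A) x-weights w_a
    x_scores: np.ndarray     # (n, A) scores t_a (mutually orthogonal)
    x_loadings: np.ndarray   # (p, A)
    y_loadings: np.ndarray   # (A,)
    explained_y_variance: np.ndarray  # per-component share of SS_Y
    _sk: PLSRegression | None = None

    def predict(self, X) -> np.ndarray:
        return np.asarray(self._sk.predict(np.asarray(X, dtype=float))).ravel()


def pls_fit(X, y, n_components: int) -> PlsModel:
    """Fit PLS1 of a single response on the predictor matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValidationError("X must be (n, p) with matching y")
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if n_components > rank:
        raise ValidationError(
            f"n_components={n_components} exceeds predictor rank {rank}"
        )
    sk = PLSRegression(n_components=n_components, scale=True)
    sk.fit(X, y)
    T = sk.x_scores_
    Q = sk.y_loadings_.ravel()
    # scores/loadings live in the internally standardized space, where the
    # total response sum of squares is n
    ssy = (T**2).sum(axis=0) * Q**2
    total = float(len(y))
    return PlsModel(
        n_components=n_components,
        weights=sk.x_weights_,
        x_scores=T,
        x_loadings=sk.x_loadings_,
        y_loadings=Q,
        explained_y_variance=ssy / max(total, 1e-300),
        _sk=sk,
    )


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ),
    where SSY_a is the response variance captured by component a.  The
    mean of the squared scores is 1, so VIP > 1 flags an important
    predictor.
    """
    W = model.weights
    p = W.shape[0]
    ssy = (model.x_scores**2).sum(axis=0) * model.y_loadings**2
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn**2 @ ssy) / ssy.sum())


# ---------------------------------------------------------------------------
# Correlation diagnostics
# ---------------------------------------------------------------------------

def _check_series(series, max_lag: int) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if max_lag >= len(x):
        raise SizeError(f"max_lag={max_lag} must be < series length {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateScaleError("constant series has undefined autocorrelation")
    return x


def acf(series, max_lag: int) -> np.ndarray:
    """Autocorrelation at lags 0..max_lag (biased 1/n normalization)."""
    x = _check_series(series, max_lag)
    return np.asarray(_sm_acf(x, nlags=max_lag, adjusted=False, fft=False))


def pacf(series, max_lag: int) -> np.ndarray:
    """Partial autocorrelation at lags 0..max_lag (Durbin-Levinson)."""
    x = _check_series(series, max_lag)
    return np.asarray(_sm_pacf(x, nlags=max_lag, method="ldb"))
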
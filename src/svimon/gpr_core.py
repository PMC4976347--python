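"""Exact Gaussian process regression with an additive covariance.

The regression model is ``y = f(x) + eps`` with ``f ~ GP(0, k)`` and
``eps ~ N(0, sigma_n^2)``.  With training inputs ``X`` (n x d) and
targets ``y``, the noisy covariance is ``K_y = K + sigma_n^2 I`` and the
posterior at a query ``x*`` is

    mean = k_*^T K_y^{-1} y
    var  = k(x*, x*) - k_*^T K_y^{-1} k_*        (+ sigma_n^2 if the
                                                  observation-noise flag
                                                  is set)

Hyperparameters are estimated by maximizing the log marginal likelihood

    log p(y | X, theta) = -1/2 y^T K_y^{-1} y - 1/2 log|K_y| - n/2 log 2pi

with analytic gradients in log-parameter space and multi-restart
quasi-Newton optimization.

Four covariance families are provided: squared-exponential (isotropic or
per-dimension length-scales), Matern (roughness 1/2, 3/2, 5/2), the
arcsine "neural network" kernel, and the additive kernel — a weighted
sum of all products of one-dimensional squared-exponential base kernels,
grouped by interaction order r and weighted by per-order variances
sigma2_(r):

    k_add(a, b) = sum_r sigma2_(r) * e_r(z_1, ..., z_d)

where ``z_j = exp(-(a_j - b_j)^2 / (2 l_j^2))`` and ``e_r`` is the r-th
elementary symmetric polynomial, evaluated by the Newton-Girard
recursion in O(d * max_order) rather than by enumerating the 2^d - 1
variable subsets.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .data_model import FitError, NumericalError, ValidationError

KERNEL_FAMILIES = ("squared_exp", "matern", "neural_net", "additive")

#: Initial jitter as a fraction of the mean diagonal of K_y, and the
#: escalation ceiling (x10 per retry).
JITTER_START = 1e-8
JITTER_MAX = 1e-2

#: Restart initial log-parameters are drawn uniformly from this box.
INIT_LOG_RANGE = (-2.0, 2.0)
#: Optimizer box constraints on log-parameters (keeps K_y factorizable).
LOG_BOUNDS = (-15.0, 15.0)

SERIALIZATION_TAG = "svimon-gp-1"


# ---------------------------------------------------------------------------
# Specifications and hyperparameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    """Covariance family selection.

    ``matern_roughness`` is the halved-integer code (1, 3, 5 meaning nu =
    1/2, 3/2, 5/2) and only applies to the Matern family.  ``ard`` gives
    the squared-exponential family one length-scale per input dimension.
    ``max_order`` caps the interaction order of the additive kernel
    (``None`` means the full order d).
    """

    family: str = "squared_exp"
    matern_roughness: int = 3
    ard: bool = False
    base_family: str = "squared_exp"
    max_order: int | None = None

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValidationError(f"unknown kernel family {self.family!r}")
        if self.matern_roughness not in (1, 3, 5):
            raise ValidationError("matern_roughness must be 1, 3 or 5")
        if self.base_family != "squared_exp":
            raise ValidationError("only squared_exp base kernels are supported")
        if self.max_order is not None and self.max_order < 1:
            raise ValidationError("max_order must be >= 1")

    def effective_order(self, d: int) -> int:
        r = d if self.max_order is None else self.max_order
        if r > d:
            raise ValidationError(f"max_order={r} exceeds input dimension d={d}")
        return r

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "matern_roughness": self.matern_roughness,
            "ard": self.ard,
            "base_family": self.base_family,
            "max_order": self.max_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


@dataclass
class Hyperparams:
    """Kernel and noise parameters (natural scale; optimized in log).

    ``length_scales`` is a scalar array for isotropic kernels or a
    length-d vector for ARD squared-exp / additive kernels.
    ``order_variances`` (additive only) holds sigma2_(1..max_order); for
    the additive family the overall signal variance is carried entirely
    by these weights and ``signal_variance`` stays fixed at 1.
    """

    signal_variance: float = 1.0
    length_scales: np.ndarray = field(default_factory=lambda: np.array(1.0))
    noise_variance: float = 0.1
    order_variances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.length_scales = np.atleast_1d(np.asarray(self.length_scales, dtype=float))
        if self.order_variances is not None:
            self.order_variances = np.asarray(self.order_variances, dtype=float)
            if np.any(self.order_variances < 0):
                raise ValidationError("order_variances must be non-negative")
        if self.signal_variance <= 0 or self.noise_variance <= 0:
            raise ValidationError("variances must be strictly positive")
        if np.any(self.length_scales <= 0):
            raise ValidationError("length_scales must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "log_signal_variance": math.log(self.signal_variance),
            "log_length_scales": np.log(self.length_scales).tolist(),
            "log_noise_variance": math.log(self.noise_variance),
            "log_order_variances": None
            if self.order_variances is None
            else np.log(self.order_variances).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparams":
        ov = d.get("log_order_variances")
        return cls(
            signal_variance=math.exp(d["log_signal_variance"]),
            length_scales=np.exp(np.asarray(d["log_length_scales"], dtype=float)),
            noise_variance=math.exp(d["log_noise_variance"]),
            order_variances=None if ov is None else np.exp(np.asarray(ov, dtype=float)),
        )


def default_hyperparams(spec: KernelSpec, d: int) -> Hyperparams:
    """Unit-scale starting hyperparameters for a d-dimensional problem."""
    if spec.family == "additive":
        r = spec.effective_order(d)
        return Hyperparams(
            signal_variance=1.0,
            length_scales=np.ones(d),
            noise_variance=0.1,
            order_variances=np.ones(r),
        )
    n_l = d if (spec.family == "squared_exp" and spec.ard) else 1
    return Hyperparams(length_scales=np.ones(n_l))


def _n_params(spec: KernelSpec, d: int) -> int:
    if spec.family == "additive":
        return d + spec.effective_order(d) + 1
    n_l = d if (spec.family == "squared_exp" and spec.ard) else 1
    return 1 + n_l + 1


def pack_log_theta(spec: KernelSpec, theta: Hyperparams, d: int) -> np.ndarray:
    """Flatten hyperparameters into the optimizer's log-space vector."""
    if spec.family == "additive":
        return np.concatenate(
            [
                np.log(theta.length_scales),
                np.log(theta.order_variances),
                [math.log(theta.noise_variance)],
            ]
        )
    return np.concatenate(
        [
            [math.log(theta.signal_variance)],
            np.log(theta.length_scales),
            [math.log(theta.noise_variance)],
        ]
    )


def unpack_log_theta(spec: KernelSpec, vec: np.ndarray, d: int) -> Hyperparams:
    vec = np.asarray(vec, dtype=float)
    if len(vec) != _n_params(spec, d):
        raise ValidationError("log-theta vector has the wrong length")
    if spec.family == "additive":
        r = spec.effective_order(d)
        return Hyperparams(
            signal_variance=1.0,
            length_scales=np.exp(vec[:d]),
            noise_variance=math.exp(vec[-1]),
            order_variances=np.exp(vec[d : d + r]),
        )
    return Hyperparams(
        signal_variance=math.exp(vec[0]),
        length_scales=np.exp(vec[1:-1]),
        noise_variance=math.exp(vec[-1]),
    )


# ---------------------------------------------------------------------------
# Elementary symmetric polynomials (Newton-Girard)
# ---------------------------------------------------------------------------

def elementary_symmetric(Z: np.ndarray, max_order: int) -> list[np.ndarray]:
    """e_0..e_max_order of the d values stacked along ``Z``'s first axis.

    Uses the Newton-Girard identities on power sums, so the cost is
    O(d * max_order) array operations instead of the 2^d subset sum.
    Returns ``[e_0, e_1, ..., e_max_order]`` with e_0 = 1.
    """
    Z = np.asarray(Z, dtype=float)
    d = Z.shape[0]
    if max_order > d:
        raise ValidationError(f"max_order={max_order} exceeds d={d}")
    shape = Z.shape[1:]
    power_sums = [np.sum(Z**k, axis=0) for k in range(1, max_order + 1)]
    es: list[np.ndarray] = [np.ones(shape)]
    for r in range(1, max_order + 1):
        acc = np.zeros(shape)
        for k in range(1, r + 1):
            term = es[r - k] * power_sums[k - 1]
            acc += term if (k % 2 == 1) else -term
        es.append(acc / r)
    return es


def additive_kernel(base_values, order_variances) -> np.ndarray:
    """Weighted sum of all products of 1-D kernel values, by order.

    ``base_values`` stacks the d one-dimensional kernel evaluations
    z_1..z_d along the first axis; ``order_variances`` holds sigma2_(r)
    for r = 1..max_order.  Returns sum_r sigma2_(r) e_r(z).
    """
    Z = np.asarray(base_values, dtype=float)
    w = np.asarray(order_variances, dtype=float)
    es = elementary_symmetric(Z, len(w))
    out = np.zeros(Z.shape[1:]) if Z.ndim > 1 else np.array(0.0)
    for r, wr in enumerate(w, start=1):
        out = out + wr * es[r]
    return out


def _deflated_e(es: list[np.ndarray], z_j: np.ndarray, max_order: int) -> list[np.ndarray]:
    """e_k of the remaining d-1 variables, from the full e_k and z_j.

    Uses e_k = e_k^(-j) + z_j e_{k-1}^(-j) rearranged into a forward
    recursion; returns [e_0^(-j), ..., e_{max_order-1}^(-j)].
    """
    out = [np.ones_like(z_j)]
    for k in range(1, max_order):
        out.append(es[k] - z_j * out[k - 1])
    return out


# ---------------------------------------------------------------------------
# Kernel matrices
# ---------------------------------------------------------------------------

def _as_2d(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    return A


def _check_dims(spec: KernelSpec, theta: Hyperparams, d: int) -> None:
    if spec.family == "additive":
        if len(theta.length_scales) != d:
            raise ValidationError("additive kernel needs one length-scale per dimension")
        if theta.order_variances is None or len(theta.order_variances) != spec.effective_order(d):
            raise ValidationError("order_variances length must equal max_order")
    elif spec.family == "squared_exp" and spec.ard:
        if len(theta.length_scales) != d:
            raise ValidationError("ARD squared_exp needs one length-scale per dimension")
    else:
        if len(theta.length_scales) != 1:
            raise ValidationError(f"{spec.family} kernel uses a single length-scale")


def kernel_matrix(
    spec: KernelSpec, theta: Hyperparams, A: np.ndarray, B: np.ndarray
) -> np.ndarray:
    """Cross-covariance matrix with entry (i, j) = k(a_i, b_j)."""
    A, B = _as_2d(A), _as_2d(B)
    if A.shape[1] != B.shape[1]:
        raise ValidationError(
            f"input dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    _check_dims(spec, theta, A.shape[1])
    if spec.family == "squared_exp":
        ls = theta.length_scales if spec.ard else np.full(A.shape[1], theta.length_scales[0])
        sq = cdist(A / ls, B / ls, "sqeuclidean")
        return theta.signal_variance * np.exp(-0.5 * sq)
    if spec.family == "matern":
        r = cdist(A, B) / theta.length_scales[0]
        s2 = theta.signal_variance
        if spec.matern_roughness == 1:
            return s2 * np.exp(-r)
        if spec.matern_roughness == 3:
            a = math.sqrt(3.0) * r
            return s2 * (1.0 + a) * np.exp(-a)
        a = math.sqrt(5.0) * r
        return s2 * (1.0 + a + a**2 / 3.0) * np.exp(-a)
    if spec.family == "neural_net":
        s = _nn_sine_arg(theta, A, B)
        return theta.signal_variance * (2.0 / math.pi) * np.arcsin(s)
    # additive
    Z = _additive_base_values(theta, A, B)
    return additive_kernel(Z, theta.order_variances)


def _nn_sine_arg(theta: Hyperparams, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Arcsine-kernel argument 2 x~'S x~ / sqrt((1+2 x~'S x~)(1+2 x~'S x~))."""
    l2 = theta.length_scales[0] ** 2
    dot = (1.0 + A @ B.T) / l2
    qa = (1.0 + np.sum(A * A, axis=1)) / l2
    qb = (1.0 + np.sum(B * B, axis=1)) / l2
    denom = np.sqrt(np.outer(1.0 + 2.0 * qa, 1.0 + 2.0 * qb))
    return 2.0 * dot / denom


def _additive_base_values(theta: Hyperparams, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Stack of d one-dimensional SE kernel evaluations, shape (d, n, m)."""
    diffs = A[:, None, :] - B[None, :, :]  # (n, m, d)
    Z = np.exp(-0.5 * (diffs / theta.length_scales) ** 2)
    return np.moveaxis(Z, -1, 0)


def kernel_diag(spec: KernelSpec, theta: Hyperparams, A: np.ndarray) -> np.ndarray:
    """Prior variances k(a_i, a_i) without forming the full matrix."""
    A = _as_2d(A)
    n, d = A.shape
    if spec.family in ("squared_exp", "matern"):
        return np.full(n, theta.signal_variance)
    if spec.family == "neural_net":
        l2 = theta.length_scales[0] ** 2
        q = 2.0 * (1.0 + np.sum(A * A, axis=1)) / l2
        return theta.signal_variance * (2.0 / math.pi) * np.arcsin(q / (1.0 + q))
    r_max = spec.effective_order(d)
    val = sum(
        theta.order_variances[r - 1] * math.comb(d, r) for r in range(1, r_max + 1)
    )
    return np.full(n, val)


def _kernel_and_grads(
    spec: KernelSpec, theta: Hyperparams, X: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray]]:
    """K(X, X) and dK/d(log parameter) for every non-noise parameter.

    Gradient order matches :func:`pack_log_theta` (noise excluded).
    """
    X = _as_2d(X)
    n, d = X.shape
    if spec.family == "squared_exp":
        ls = theta.length_scales if spec.ard else np.full(d, theta.length_scales[0])
        diffs = X[:, None, :] - X[None, :, :]
        scaled_sq = (diffs / ls) ** 2  # (n, n, d)
        K = theta.signal_variance * np.exp(-0.5 * scaled_sq.sum(axis=-1))
        grads = [K.copy()]  # d/dlog sigma_f^2
        if spec.ard:
            for j in range(d):
                grads.append(K * scaled_sq[:, :, j])
        else:
            grads.append(K * scaled_sq.sum(axis=-1))
        return K, grads
    if spec.family == "matern":
        r = cdist(X, X) / theta.length_scales[0]
        s2 = theta.signal_variance
        if spec.matern_roughness == 1:
            K = s2 * np.exp(-r)
            dK_dl = s2 * r * np.exp(-r)
        elif spec.matern_roughness == 3:
            a = math.sqrt(3.0) * r
            K = s2 * (1.0 + a) * np.exp(-a)
            dK_dl = s2 * a**2 * np.exp(-a)
        else:
            a = math.sqrt(5.0) * r
            K = s2 * (1.0 + a + a**2 / 3.0) * np.exp(-a)
            dK_dl = s2 * (a**2 * (1.0 + a) / 3.0) * np.exp(-a)
        return K, [K.copy(), dK_dl]
    if spec.family == "neural_net":
        l2 = theta.length_scales[0] ** 2
        dot = (1.0 + X @ X.T) / l2
        q = (1.0 + np.sum(X * X, axis=1)) / l2
        Ba = 1.0 + 2.0 * q
        denom = np.sqrt(np.outer(Ba, Ba))
        s = 2.0 * dot / denom
        K = theta.signal_variance * (2.0 / math.pi) * np.arcsin(s)
        # d s / d log l: numerator scales by -2, each denominator factor B
        # contributes +(B-1)/B
        factor = -2.0 + ((Ba - 1.0) / Ba)[:, None] + ((Ba - 1.0) / Ba)[None, :]
        ds = s * factor
        dK_dl = theta.signal_variance * (2.0 / math.pi) * ds / np.sqrt(1.0 - s**2)
        return K, [K.copy(), dK_dl]
    # additive
    r_max = spec.effective_order(d)
    Z = _additive_base_values(theta, X, X)  # (d, n, n)
    es = elementary_symmetric(Z, r_max)
    K = np.zeros((n, n))
    for r in range(1, r_max + 1):
        K += theta.order_variances[r - 1] * es[r]
    grads: list[np.ndarray] = []
    diffs = X[:, None, :] - X[None, :, :]
    for j in range(d):
        z_j = Z[j]
        e_minus = _deflated_e(es, z_j, r_max)
        outer = np.zeros((n, n))
        for r in range(1, r_max + 1):
            outer += theta.order_variances[r - 1] * e_minus[r - 1]
        dz_dlogl = z_j * (diffs[:, :, j] / theta.length_scales[j]) ** 2
        grads.append(outer * dz_dlogl)
    for r in range(1, r_max + 1):
        grads.append(theta.order_variances[r - 1] * es[r])
    return K, grads


# ---------------------------------------------------------------------------
# Model container and factorization
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    """Posterior mean and (non-negative) variance at one query point."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            warnings.warn(
                f"negative posterior variance {self.variance:.3e} clipped to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            self.variance = 0.0


@dataclass
class GPModel:
    """A fitted GP: spec, hyperparameters, training data and Cholesky cache."""

    spec: KernelSpec
    theta: Hyperparams
    X: np.ndarray
    y: np.ndarray
    L: np.ndarray = field(repr=False, default=None)  # lower Cholesky of K_y + jitter
    alpha: np.ndarray = field(repr=False, default=None)  # K_y^{-1} y
    jitter: float = 0.0
    log_marginal_likelihood_: float | None = None


def _factorize(Ky: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky with escalating diagonal jitter."""
    n = Ky.shape[0]
    base = JITTER_START * float(np.mean(np.diag(Ky)))
    jitter = base
    while jitter <= JITTER_MAX * float(np.mean(np.diag(Ky))) + 1e-300:
        try:
            L = cholesky(Ky + jitter * np.eye(n), lower=True)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
        except Exception:
            jitter *= 10.0
    smallest = float(np.linalg.eigvalsh(Ky)[0])
    raise NumericalError(
        f"K_y not positive definite even with jitter {jitter:.1e}; "
        f"smallest eigenvalue ~ {smallest:.3e}"
    )


def build_gp(
    X: np.ndarray, y: np.ndarray, spec: KernelSpec, theta: Hyperparams
) -> GPModel:
    """Assemble and factorize a GP at fixed hyperparameters."""
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != X.shape[0]:
        raise ValidationError("X and y lengths differ")
    K = kernel_matrix(spec, theta, X, X)
    Ky = K + theta.noise_variance * np.eye(len(y))
    L, jitter = _factorize(Ky)
    alpha = cho_solve((L, True), y)
    model = GPModel(spec=spec, theta=theta, X=X, y=y, L=L, alpha=alpha, jitter=jitter)
    model.log_marginal_likelihood_ = _lml_value(model)
    return model


def _lml_value(model: GPModel) -> float:
    n = len(model.y)
    return (
        -0.5 * float(model.y @ model.alpha)
        - float(np.sum(np.log(np.diag(model.L))))
        - 0.5 * n * math.log(2.0 * math.pi)
    )


def log_marginal_likelihood(model: GPModel) -> tuple[float, np.ndarray]:
    """log p(y | X, theta) and its gradient w.r.t. the packed log-theta.

    The gradient entry for each parameter is
    1/2 tr((alpha alpha^T - K_y^{-1}) dK_y/dlog theta_j).
    """
    n = len(model.y)
    L, alpha = model.L, model.alpha
    lml = _lml_value(model)
    Kinv = cho_solve((L, True), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv
    _, grads = _kernel_and_grads(model.spec, model.theta, model.X)
    g = np.empty(len(grads) + 1)
    for j, dK in enumerate(grads):
        g[j] = 0.5 * float(np.sum(A * dK))
    # noise: dK_y/dlog sigma_n^2 = sigma_n^2 I
    g[-1] = 0.5 * model.theta.noise_variance * float(np.trace(A))
    return lml, g


def fit_gp(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    n_restarts: int = 5,
    seed: int = 0,
    init_theta: Hyperparams | None = None,
) -> GPModel:
    """Maximize the marginal likelihood over hyperparameters.

    Runs ``n_restarts`` L-BFGS-B minimizations of the negative log
    marginal likelihood in log-parameter space, each from an initial
    point drawn uniformly from ``INIT_LOG_RANGE`` under ``seed`` (the
    first restart starts from ``init_theta`` or unit scales), and keeps
    the best optimum.  Deterministic given ``seed``.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 2:
        raise ValidationError("need at least 2 training points")
    d = X.shape[1]
    p = _n_params(spec, d)
    rng = np.random.default_rng(seed)

    def objective(vec: np.ndarray) -> tuple[float, np.ndarray]:
        try:
            theta = unpack_log_theta(spec, vec, d)
            model = build_gp(X, y, spec, theta)
            lml, g = log_marginal_likelihood(model)
        except (NumericalError, FloatingPointError):
            return 1e25, np.zeros(p)
        if not np.isfinite(lml):
            return 1e25, np.zeros(p)
        return -lml, -g

    inits = []
    if init_theta is not None:
        inits.append(pack_log_theta(spec, init_theta, d))
    else:
        inits.append(pack_log_theta(spec, default_hyperparams(spec, d), d))
    for _ in range(max(0, n_restarts - 1)):
        inits.append(rng.uniform(*INIT_LOG_RANGE, size=p))

    best_vec, best_nlml, diagnostics = None, np.inf, []
    for x0 in inits:
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[LOG_BOUNDS] * p,
            options={"maxiter": 200},
        )
        diagnostics.append((res.fun, res.message))
        if np.isfinite(res.fun) and res.fun < best_nlml and res.fun < 1e24:
            best_nlml, best_vec = res.fun, res.x
    if best_vec is None:
        raise FitError(f"all {len(inits)} restarts failed: {diagnostics}")
    theta = unpack_log_theta(spec, best_vec, d)
    return build_gp(X, y, spec, theta)


def predict_gp(
    model: GPModel, Xstar: np.ndarray, include_noise: bool = False
) -> list[Prediction]:
    """Posterior predictions at the query inputs.

    By default the variance is that of the latent function f; with
    ``include_noise`` the observation noise sigma_n^2 is added, giving
    the predictive variance of a new noisy measurement.
    """
    mean, var = predict_mean_var(model, Xstar, include_noise=include_noise)
    return [Prediction(float(m), float(v)) for m, v in zip(mean, var)]


def predict_mean_var(
    model: GPModel, Xstar: np.ndarray, include_noise: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Array version of :func:`predict_gp` (mean, variance)."""
    Xstar = _as_2d(Xstar)
    if Xstar.shape[1] != model.X.shape[1]:
        raise ValidationError(
            f"query dimension {Xstar.shape[1]} != training dimension {model.X.shape[1]}"
        )
    Ks = kernel_matrix(model.spec, model.theta, model.X, Xstar)  # (n, m)
    mean = Ks.T @ model.alpha
    v = solve_triangular(model.L, Ks, lower=True)
    var = kernel_diag(model.spec, model.theta, Xstar) - np.sum(v * v, axis=0)
    if np.any(var < 0):
        if np.any(var < -1e-6):
            warnings.warn(
                "posterior variance significantly negative; clipping",
                RuntimeWarning,
                stacklevel=2,
            )
        var = np.clip(var, 0.0, None)
    if include_noise:
        var = var + model.theta.noise_variance
    return mean, var


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _data_checksum(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()


def gp_to_dict(model: GPModel) -> dict:
    """JSON-ready document: spec, log-theta, training data + checksum."""
    return {
        "tag": SERIALIZATION_TAG,
        "spec": model.spec.to_dict(),
        "theta": model.theta.to_dict(),
        "X": model.X.tolist(),
        "y": model.y.tolist(),
        "checksum": _data_checksum(model.X, model.y),
    }


def gp_from_dict(doc: dict) -> GPModel:
    if doc.get("tag") != SERIALIZATION_TAG:
        raise ValidationError(f"unrecognized model document tag {doc.get('tag')!r}")
    X = np.asarray(doc["X"], dtype=float)
    y = np.asarray(doc["y"], dtype=float)
    if _data_checksum(X, y) != doc["checksum"]:
        raise ValidationError("training-data checksum mismatch")
    spec = KernelSpec.from_dict(doc["spec"])
    theta = Hyperparams.from_dict(doc["theta"])
    return build_gp(X, y, spec, theta)


def save_gp(model: GPModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(gp_to_dict(model), fh)


def load_gp(path) -> GPModel:
    with open(path) as fh:
        return gp_from_dict(json.load(fh))
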
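"""Synthetic bulking episodes and exact-GP samplers.

The episode generator emulates the structure of a full-scale oxidation
ditch record: 213 daily samples, a normal regime near 100 mL/g, onset of
filamentous bulking at sample 101, and a ramp through limited
(165-250 mL/g) into serious (>250 mL/g) bulking by the end of the
record.  Covariates are tied to the latent SVI through declared monotone
links — COD loading and dissolved oxygen decline into bulking, the
settled-volume fractions follow the SV = SVI x MLSS identity, and
temperature follows a seasonal sinusoid — so that the covariate
regression is learnable.  Ground-truth state labels come from the
latent (noise-free) SVI, keeping test oracles unaffected by observation
noise.

Also provides exact draws from a GP prior (for calibration and
parameter-recovery tests) and a stationary AR(1) generator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import ProcessSeries, ValidationError, write_series
from .gpr_core import Hyperparams, KernelSpec, _factorize, kernel_matrix
from .state_monitor import StateThresholds, classify_svi


#: Default per-covariate observation noise (units of the covariate).
DEFAULT_COVARIATE_NOISE = {
    "do": 0.15,        # mg/L
    "cod": 15.0,       # mg/L
    "qin": 8000.0,     # m3/d
    "srt": 0.8,        # d
    "mlss": 80.0,      # mg/L
    "sv_od": 0.004,    # fraction
    "sv_recycle": 0.03,
    "temperature": 0.5,  # degC
}

#: Link-function constants (documented in docs/methods.md).
_COD_BASE = 400.0       # mg/L influent COD in the normal regime
_COD_SLOPE = 0.8        # mg/L drop per mL/g of latent SVI rise
_DO_BASE = 2.5          # mg/L
_DO_SLOPE = 0.004       # mg/L drop per mL/g
_QIN_MEAN = 170000.0    # m3/d
_SRT_MEAN = 18.0        # d
_MLSS_MEAN = 3500.0     # mg/L
_TEMP_MEAN = 18.0       # degC
_TEMP_AMPLITUDE = 6.0   # degC seasonal swing


@dataclass(frozen=True)
class EpisodeConfig:
    """Shape of a synthetic bulking episode (case-study defaults).

    ``wander_amplitudes`` set the smooth quasi-seasonal variation of the
    normal operating regime (mL/g); the wander is tapered out over
    ``wander_taper_days`` once bulking begins, so the post-onset ramp —
    and hence the threshold-crossing indices — are exactly the
    configured ramp.
    """

    n_total: int = 213
    onset_index: int = 101
    baseline_svi: float = 100.0
    peak_svi: float = 290.0
    ramp_shape: str = "linear"
    svi_noise_sd: float = 4.0
    covariate_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_NOISE))
    wander_amplitudes: tuple = (28.0, 14.0)
    wander_periods: tuple = (75.0, 27.0)
    wander_taper_days: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.onset_index < self.n_total):
            raise ValidationError("need 1 <= onset_index < n_total")
        if not (self.baseline_svi < 165.0 < 250.0 < self.peak_svi):
            raise ValidationError("need baseline < 165 < 250 < peak")
        if self.ramp_shape not in ("linear", "logistic"):
            raise ValidationError(f"unknown ramp shape {self.ramp_shape!r}")
        if self.svi_noise_sd < 0:
            raise ValidationError("svi_noise_sd must be non-negative")


@dataclass
class Episode:
    """A generated record plus its noise-free ground truth."""

    series: ProcessSeries
    latent_svi: np.ndarray
    labels: np.ndarray  # state 1..4 from the latent SVI
    crossing_indices: dict  # first index with latent > 165 / > 250 (or None)
    config: EpisodeConfig


def latent_ramp(config: EpisodeConfig) -> np.ndarray:
    """Noise-free SVI trajectory: flat baseline, then the chosen ramp."""
    t = np.arange(config.n_total, dtype=float)
    latent = np.full(config.n_total, config.baseline_svi)
    span = max(config.n_total - 1 - config.onset_index, 1)
    rise = config.peak_svi - config.baseline_svi
    after = t >= config.onset_index
    if config.ramp_shape == "linear":
        latent[after] = config.baseline_svi + rise * (t[after] - config.onset_index) / span
    else:
        mid = config.onset_index + span / 2.0
        k = 10.0 / span
        raw = 1.0 / (1.0 + np.exp(-k * (t[after] - mid)))
        lo = 1.0 / (1.0 + math.exp(k * (mid - config.onset_index)))
        hi = 1.0 / (1.0 + math.exp(-k * (config.n_total - 1 - mid)))
        latent[after] = config.baseline_svi + rise * (raw - lo) / (hi - lo)
    return latent


def _ou_noise(rng: np.random.Generator, n: int, sd: float, rho: float = 0.7) -> np.ndarray:
    """Mean-reverting (AR(1)) noise with stationary sd."""
    e = rng.normal(0.0, sd * math.sqrt(1 - rho**2), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + e[i]
    return out


def _normal_regime_wander(cfg: EpisodeConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth quasi-seasonal SVI variation of the healthy plant.

    A sum of sinusoids with seed-drawn phases, tapered linearly to zero
    over ``wander_taper_days`` after onset so the bulking ramp dominates.
    """
    t = np.arange(cfg.n_total, dtype=float)
    w = np.zeros(cfg.n_total)
    for amp, period in zip(cfg.wander_amplitudes, cfg.wander_periods):
        w += amp * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
    taper = np.clip(1.0 - (t - cfg.onset_index) / max(cfg.wander_taper_days, 1), 0.0, 1.0)
    return w * taper


def generate_episode(config: EpisodeConfig | None = None) -> Episode:
    """Generate one bulking episode with ground-truth labels."""
    cfg = config or EpisodeConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_total
    latent = latent_ramp(cfg) + _normal_regime_wander(cfg, rng)
    sd = cfg.covariate_noise_sd
    excess = latent - cfg.baseline_svi

    temperature = (
        _TEMP_MEAN
        + _TEMP_AMPLITUDE * np.sin(2 * np.pi * np.arange(n) / 365.0)
        + rng.normal(0.0, sd["temperature"], n)
    )
    cod = _COD_BASE - _COD_SLOPE * excess + _ou_noise(rng, n, sd["cod"])
    do = np.clip(_DO_BASE - _DO_SLOPE * excess + rng.normal(0.0, sd["do"], n), 0.3, None)
    qin = _QIN_MEAN + _ou_noise(rng, n, sd["qin"])
    srt = np.clip(_SRT_MEAN + _ou_noise(rng, n, sd["srt"]), 15.0, 22.0)
    mlss = _MLSS_MEAN + _ou_noise(rng, n, sd["mlss"])
    # settled volume fraction: SV = SVI (mL/g) x MLSS (g/L) / 1000 (mL/mL)
    sv_od = np.clip(latent * mlss / 1e6 + rng.normal(0.0, sd["sv_od"], n), 0.02, 0.95)
    sv_recycle = np.clip(1.25 * latent * mlss / 1e6 + rng.normal(0.0, sd["sv_recycle"], n),
                         0.02, 0.98)

    observed = np.clip(latent + rng.normal(0.0, cfg.svi_noise_sd, n), 1.0, None)
    series = ProcessSeries.from_arrays(
        svi=observed,
        covariates={
            "do": do, "cod": cod, "qin": qin, "srt": srt, "mlss": mlss,
            "sv_od": sv_od, "sv_recycle": sv_recycle, "temperature": temperature,
        },
    )
    th = StateThresholds()
    labels = np.array([int(classify_svi(v, th)) for v in latent])
    crossings = {}
    for name, limit in (("limited", th.t_limited), ("serious", th.t_serious)):
        above = np.flatnonzero(latent > limit)
        crossings[name] = int(above[0]) if len(above) else None
    return Episode(series=series, latent_svi=latent, labels=labels,
                   crossing_indices=crossings, config=cfg)


def write_episode(episode: Episode, csv_path, truth_path) -> None:
    """Write the record CSV plus a side-car JSON of the ground truth."""
    write_series(episode.series, csv_path)
    doc = {
        "latent_svi": episode.latent_svi.tolist(),
        "labels": episode.labels.tolist(),
        "crossing_indices": episode.crossing_indices,
        "config": {
            "n_total": episode.config.n_total,
            "onset_index": episode.config.onset_index,
            "baseline_svi": episode.config.baseline_svi,
            "peak_svi": episode.config.peak_svi,
            "ramp_shape": episode.config.ramp_shape,
            "svi_noise_sd": episode.config.svi_noise_sd,
            "seed": episode.config.seed,
        },
    }
    with open(truth_path, "w") as fh:
        json.dump(doc, fh, indent=2)


# ---------------------------------------------------------------------------
# Exact GP samplers
# ---------------------------------------------------------------------------

def sample_gp(
    spec: KernelSpec,
    theta: Hyperparams,
    X: np.ndarray,
    n_draws: int = 1,
    seed: int = 0,
    include_noise: bool = True,
) -> np.ndarray:
    """Zero-mean joint Gaussian draws with covariance K (+ sigma_n^2 I).

    Returns an (n_draws, n) array; deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    K = kernel_matrix(spec, theta, X, X)
    if include_noise:
        K = K + theta.noise_variance * np.eye(K.shape[0])
    if not np.any(np.diag(K) > 0):
        return np.zeros((n_draws, K.shape[0]))
    L, _ = _factorize(K)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, K.shape[0]))
    return z @ L.T


def generate_ar1(phi: float, sigma: float, n: int, seed: int = 0,
                 burn_in: int = 200) -> np.ndarray:
    """Stationary zero-mean AR(1) draw, burn-in discarded."""
    if abs(phi) >= 1:
        raise ValidationError(f"|phi| must be < 1 for stationarity, got {phi}")
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, sigma, size=n + burn_in)
    x = np.empty(n + burn_in)
    x[0] = e[0] if abs(phi) < 1e-12 else rng.normal(
        0.0, sigma / math.sqrt(1 - phi**2)
    )
    for i in range(1, n + burn_in):
        x[i] = phi * x[i - 1] + e[i]
    return x[burn_in:]
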
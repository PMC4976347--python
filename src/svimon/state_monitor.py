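"""Hybrid-automaton monitoring of SVI with graded bulking alarms.

Four sludge-settleability states are defined on SVI (mL/g):

    S1  normal                       0-135
    S2  limited-bulking pre-caution  135-165
    S3  limited filamentous bulking  165-250
    S4  serious filamentous bulking  > 250

The 135/165 guards come from relaxing the conventional 150 mL/g bulking
limit by +/-10% (150 +/- 15 mL/g) to absorb measurement and model
uncertainty; 250 mL/g is kept as a hard limit for serious bulking.

The automaton steps on forecasts, not raw measurements: while in S1/S2
the one-step (OS) covariate model is active and transitions fire on the
upper bound y+ = mean + 2 sigma (the worst case); once y+ exceeds 165
the multi-step (MS) lag model is triggered and S3/S4 guards evaluate the
horizon-maximum y+ against 250.  Upward transitions emit alarms based on
the upper bound; a second, confirming alarm fires when the predictive
mean itself crosses the same threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .data_model import ProcessSeries, SizeError, ValidationError
from .forecasting import (
    BoundedForecastStep,
    ForecastTrajectory,
    MSModel,
    OSModel,
    fit_ms_model,
    fit_os_model,
    ms_forecast,
    os_predict,
)
from .gpr_core import KernelSpec


class State(IntEnum):
    S1 = 1
    S2 = 2
    S3 = 3
    S4 = 4


#: Alarm severity attached to each upward transition.
SEVERITY_OF_STATE = {State.S2: "precaution", State.S3: "limited", State.S4: "serious"}


@dataclass(frozen=True)
class StateThresholds:
    """Guard constants (mL/g) tying the four states together.

    The pre-caution and limited guards are the relaxed band
    ``nominal_limit * (1 -/+ relax_fraction)`` around the conventional
    150 mL/g bulking limit; the serious guard stays a hard 250 mL/g.
    """

    t_precaution: float = 135.0
    t_limited: float = 165.0
    t_serious: float = 250.0
    nominal_limit: float = 150.0
    relax_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.t_precaution < self.t_limited < self.t_serious):
            raise ValidationError("thresholds must satisfy 0 < precaution < limited < serious")
        if abs(self.t_precaution - self.nominal_limit * (1 - self.relax_fraction)) > 1e-9:
            raise ValidationError("t_precaution must equal nominal_limit*(1-relax_fraction)")
        if abs(self.t_limited - self.nominal_limit * (1 + self.relax_fraction)) > 1e-9:
            raise ValidationError("t_limited must equal nominal_limit*(1+relax_fraction)")

    @property
    def band_half_width(self) -> float:
        """Half-width of the relaxed diagnosis band (15 mL/g by default)."""
        return self.nominal_limit * self.relax_fraction

    @classmethod
    def from_nominal(
        cls,
        nominal_limit: float = 150.0,
        relax_fraction: float = 0.10,
        t_serious: float = 250.0,
    ) -> "StateThresholds":
        return cls(
            t_precaution=nominal_limit * (1 - relax_fraction),
            t_limited=nominal_limit * (1 + relax_fraction),
            t_serious=t_serious,
            nominal_limit=nominal_limit,
            relax_fraction=relax_fraction,
        )

    def threshold_of(self, state: State) -> float:
        return {
            State.S2: self.t_precaution,
            State.S3: self.t_limited,
            State.S4: self.t_serious,
        }[state]


def classify_svi(value: float, thresholds: StateThresholds | None = None) -> State:
    """Map an SVI value onto its state interval.

    Intervals are upper-closed: S1 on [0, 135], S2 on (135, 165], S3 on
    (165, 250], S4 on (250, inf) — the "more than 250" reading, matching
    the strict automaton guards.
    """
    th = thresholds or StateThresholds()
    if value < 0:
        raise ValidationError(f"SVI must be non-negative, got {value}")
    if value <= th.t_precaution:
        return State.S1
    if value <= th.t_limited:
        return State.S2
    if value <= th.t_serious:
        return State.S3
    return State.S4


@dataclass(frozen=True)
class AlarmEvent:
    """A graded bulking alarm.

    ``basis`` is ``upper_bound`` when raised by y+ crossing a guard
    (worst case, early) and ``confirmed_mean`` when the predictive mean
    itself crosses the same threshold.
    """

    t: int
    severity: str
    basis: str
    value: float


@dataclass(frozen=True)
class AutomatonStatus:
    """Automaton location plus bookkeeping for hysteresis/confirmation."""

    state: State = State.S1
    last_y: float = float("nan")
    last_y_plus: float = float("nan")
    ms_triggered_at: int | None = None
    confirmed: frozenset = frozenset()
    deescalate_streak: int = 0

    @property
    def active_model(self) -> str:
        """OS in S1/S2, MS in S3/S4 (a structural invariant)."""
        return "OS" if self.state in (State.S1, State.S2) else "MS"


def _step_quantities(step) -> tuple[float, float]:
    """(worst-case mean, worst-case y+) of a step or trajectory."""
    if isinstance(step, BoundedForecastStep):
        return step.mean, step.upper
    if isinstance(step, ForecastTrajectory):
        return step.max_mean, step.max_upper
    raise ValidationError(f"unsupported forecast object {type(step).__name__}")


def automaton_step(
    status: AutomatonStatus,
    step,
    thresholds: StateThresholds | None = None,
    t: int = 0,
    hysteresis: bool = False,
) -> tuple[AutomatonStatus, list[AlarmEvent]]:
    """Advance the automaton by one forecast.

    Guards (strict inequalities; equality holds the state; at most one
    level per step):

        S1 -> S2  iff y+ > 135          S2 -> S1  iff y+ < 135
        S2 -> S3  iff y+ > 165 (triggers the MS model)
        S3 -> S2  iff horizon-max y+ < 165
        S3 -> S4  iff horizon-max y+ > 250
        S4 -> S3  iff every horizon y+ < 250

    With ``hysteresis`` a de-escalation requires its guard to hold on
    two consecutive steps.  Emits an upper-bound alarm on each upward
    transition and a confirming alarm when the mean itself exceeds a
    threshold at or below the current level.
    """
    th = thresholds or StateThresholds()
    expected = BoundedForecastStep if status.active_model == "OS" else ForecastTrajectory
    if not isinstance(step, expected):
        raise ValidationError(
            f"automaton in {status.active_model} mode expects a "
            f"{expected.__name__}, got {type(step).__name__}"
        )
    y, y_plus = _step_quantities(step)
    state = status.state
    alarms: list[AlarmEvent] = []
    new_state = state
    ms_triggered_at = status.ms_triggered_at
    streak = status.deescalate_streak

    up_guard = {
        State.S1: y_plus > th.t_precaution,
        State.S2: y_plus > th.t_limited,
        State.S3: y_plus > th.t_serious,
        State.S4: False,
    }[state]
    down_guard = {
        State.S1: False,
        State.S2: y_plus < th.t_precaution,
        State.S3: y_plus < th.t_limited,
        State.S4: y_plus < th.t_serious,
    }[state]

    if up_guard:
        new_state = State(state + 1)
        streak = 0
        alarms.append(
            AlarmEvent(t=t, severity=SEVERITY_OF_STATE[new_state],
                       basis="upper_bound", value=y_plus)
        )
        if new_state == State.S3 and ms_triggered_at is None:
            ms_triggered_at = t
    elif down_guard:
        streak += 1
        if not hysteresis or streak >= 2:
            new_state = State(state - 1)
            streak = 0
    else:
        streak = 0

    # confirmation by the predictive mean, once per excursion and level
    confirmed = set(status.confirmed)
    confirmed = {s for s in confirmed if s <= new_state}  # reset on de-escalation
    for level in (State.S2, State.S3, State.S4):
        if level <= new_state and level not in confirmed and y > th.threshold_of(level):
            confirmed.add(level)
            alarms.append(
                AlarmEvent(t=t, severity=SEVERITY_OF_STATE[level],
                           basis="confirmed_mean", value=y)
            )

    new_status = AutomatonStatus(
        state=new_state,
        last_y=y,
        last_y_plus=y_plus,
        ms_triggered_at=ms_triggered_at,
        confirmed=frozenset(confirmed),
        deescalate_streak=streak,
    )
    return new_status, alarms


# ---------------------------------------------------------------------------
# Envelope diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvelopeFlags:
    """Interval-based diagnosis of one forecast against the thresholds."""

    in_relaxed_band: bool
    limited_precaution: bool
    serious_precaution: bool
    margin_to_serious: float


def envelope_check(step, thresholds: StateThresholds | None = None) -> EnvelopeFlags:
    """Interval diagnosis flags for a step or trajectory.

    ``in_relaxed_band``: the mean lies in the 150 +/- 15 mL/g band;
    ``limited_precaution``: y+ reaches the band or beyond;
    ``serious_precaution``: any y+ exceeds 250; ``margin_to_serious`` is
    250 minus the worst-case y+.
    """
    th = thresholds or StateThresholds()
    if isinstance(step, BoundedForecastStep):
        means, uppers = np.array([step.mean]), np.array([step.upper])
    elif isinstance(step, ForecastTrajectory):
        means, uppers = step.means, step.uppers
    else:
        raise ValidationError(f"unsupported forecast object {type(step).__name__}")
    max_upper = float(uppers.max())
    return EnvelopeFlags(
        in_relaxed_band=bool(
            np.any((means >= th.t_precaution) & (means <= th.t_limited))
        ),
        limited_precaution=bool(max_upper >= th.t_precaution),
        serious_precaution=bool(max_upper > th.t_serious),
        margin_to_serious=th.t_serious - max_upper,
    )


# ---------------------------------------------------------------------------
# Full-record monitoring
# ---------------------------------------------------------------------------

@dataclass
class MonitorConfig:
    """Everything a monitoring replay needs, with the case-study defaults."""

    n_train: int = 50
    n_lags: int = 7
    horizon: int = 6
    os_spec: KernelSpec = field(default_factory=lambda: KernelSpec(family="additive"))
    ms_spec: KernelSpec = field(default_factory=lambda: KernelSpec(family="additive"))
    thresholds: StateThresholds = field(default_factory=StateThresholds)
    n_restarts: int = 5
    seed: int = 0
    propagation: str = "plugin"
    n_samples: int = 1000
    include_noise: bool = False
    hysteresis: bool = False
    refit_ms: bool = False
    forward_fill: bool = False


@dataclass
class MonitorResult:
    """Chronological state trace, per-step forecasts and the alarm log."""

    trace: pd.DataFrame  # t, state, model, y, y_minus, y_plus
    forecasts: list
    alarms: list[AlarmEvent]
    os_model: OSModel
    ms_model: MSModel | None
    statuses: list[AutomatonStatus]


def monitor_run(series: ProcessSeries, config: MonitorConfig | None = None) -> MonitorResult:
    """Replay a plant record through the state-based forecaster.

    The OS model is fitted on the first ``n_train`` samples; from there
    the automaton steps chronologically on OS one-step forecasts.  When
    the MS model is triggered (y+ > 165) it is fitted on all SVI data
    observed so far, and subsequent steps use H-step recursive
    trajectories.  Deterministic given the config seed.
    """
    cfg = config or MonitorConfig()
    if len(series) < cfg.n_train + 1:
        raise SizeError(f"series length {len(series)} <= n_train={cfg.n_train}")
    os_model = fit_os_model(
        series, n_train=cfg.n_train, spec=cfg.os_spec, n_restarts=cfg.n_restarts,
        seed=cfg.seed, include_noise=cfg.include_noise,
        forward_fill=cfg.forward_fill,
    )
    ms_model: MSModel | None = None
    svi = series.svi
    t_index = series.t
    status = AutomatonStatus()
    statuses = [status]
    rows, forecasts, alarms = [], [], []

    for i in range(cfg.n_train, len(series)):
        t = int(t_index[i])
        if status.active_model == "OS":
            sample = series[i]
            step = os_predict(os_model, sample.covariates)
            y_minus, y_plus, y_mean = step.lower, step.upper, step.mean
        else:
            if ms_model is None or cfg.refit_ms:
                if i < cfg.n_lags + 2:
                    raise SizeError(
                        "MS model triggered before enough history is available"
                    )
                ms_model = fit_ms_model(
                    svi[:i], n_lags=cfg.n_lags, spec=cfg.ms_spec,
                    n_restarts=cfg.n_restarts, seed=cfg.seed,
                    include_noise=cfg.include_noise,
                )
            recent = svi[i - cfg.n_lags - 1 : i]
            step = ms_forecast(
                ms_model, recent, H=cfg.horizon, propagation=cfg.propagation,
                n_samples=cfg.n_samples, seed=cfg.seed + i, origin_t=t - 1,
            )
            first = step.steps[0]
            y_minus, y_plus, y_mean = first.lower, first.upper, first.mean
        status, new_alarms = automaton_step(
            status, step, cfg.thresholds, t=t, hysteresis=cfg.hysteresis
        )
        alarms.extend(new_alarms)
        forecasts.append(step)
        statuses.append(status)
        rows.append(
            {
                "t": t,
                "state": int(status.state),
                "model": "OS" if isinstance(step, BoundedForecastStep) else "MS",
                "y": y_mean,
                "y_minus": y_minus,
                "y_plus": y_plus,
            }
        )
    trace = pd.DataFrame(rows)
    return MonitorResult(trace=trace, forecasts=forecasts, alarms=alarms,
                         os_model=os_model, ms_model=ms_model, statuses=statuses)


def write_trace_csv(result: MonitorResult, path) -> None:
    result.trace.to_csv(path, index=False)


def write_alarms_json(result: MonitorResult, path) -> None:
    doc = [
        {"t": a.t, "severity": a.severity, "basis": a.basis, "value": a.value}
        for a in result.alarms
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
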
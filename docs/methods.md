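# Methods

## The monitoring problem

Filamentous bulking — overgrowth of filamentous bacteria in activated
sludge — degrades settling in the secondary clarifier and is tracked
operationally through the sludge volume index (SVI, mL/g of settled
sludge volume per gram of suspended solids). `svimon` implements a
state-based monitoring scheme: Gaussian process (GP) regression supplies
SVI forecasts with calibrated uncertainty, and a four-state hybrid
automaton turns those forecasts into graded alarms and decides which of
two forecasting models is active.

The four states partition SVI as

| state | SVI (mL/g) | meaning |
|---|---|---|
| S1 | 0–135 | normal |
| S2 | 135–165 | limited-bulking pre-caution |
| S3 | 165–250 | limited filamentous bulking |
| S4 | > 250 | serious filamentous bulking |

The 135/165 guards are the conventional 150 mL/g bulking limit relaxed
by ±10% (150 ± 15 mL/g) so that measurement and model uncertainty do
not flip the diagnosis; 250 mL/g is kept as a hard limit. Guards are
evaluated on the upper forecast bound y⁺ = μ + 2σ rather than on the
mean: the worst case is deliberately the alarming quantity, and a
second, confirming alarm fires only when the mean itself crosses the
same threshold.

## GP regression

The model is `y = f(x) + ε`, `f ~ GP(0, k)`, `ε ~ N(0, σ_n²)`. With
training inputs X (n × d) and targets y, `K_y = K + σ_n² I` and the
posterior at x* is

    μ(x*)  = k*ᵀ K_y⁻¹ y
    σ²(x*) = k(x*, x*) − k*ᵀ K_y⁻¹ k*   (+ σ_n² when predicting a new
                                          noisy measurement)

Hyperparameters maximize the log marginal likelihood
`−½ yᵀK_y⁻¹y − ½ log|K_y| − (n/2) log 2π` by L-BFGS-B in log-parameter
space with analytic gradients `½ tr((ααᵀ − K_y⁻¹) ∂K_y/∂log θ_j)`,
α = K_y⁻¹y. Five restarts by default; the first starts from unit
scales, the rest from log-parameters drawn uniformly on [−2, 2] under
the given seed, so fits are deterministic per seed. Box bounds of ±15
on log-parameters keep the factorization well posed.

Kernel families: squared-exponential (isotropic or per-dimension
length-scales), Matérn (ν = 1/2, 3/2, 5/2; default 3/2), the arcsine
"neural network" kernel, and the additive kernel

    k_add(a, b) = Σ_r σ²_(r) · e_r(z_1, …, z_d),
    z_j = exp(−(a_j − b_j)² / (2 l_j²)),

where e_r is the r-th elementary symmetric polynomial — the weighted
sum of all products of one-dimensional squared-exponential base
kernels, grouped by interaction order r. The e_r are evaluated by the
Newton–Girard recursion on power sums, O(d·R) per entry instead of the
2^d − 1 subset enumeration; a brute-force enumeration oracle checks
this for d ≤ 6 in the tests. For the additive family the per-order
variances σ²_(r) carry the entire signal amplitude (a separate overall
signal variance would be redundant) and each 1-D base has its own
length-scale l_j. `max_order` defaults to d; `max_order = 1` gives the
plain sum-of-1-D-kernels model.

Numerics: K_y receives a jitter of 1e−8 × mean diagonal before Cholesky
factorization, escalated ×10 on failure up to 1e−2, after which a
numerical error reports the smallest-eigenvalue estimate. Posterior
variances are clipped at zero (with a warning when the violation
exceeds round-off). Inputs and the target are z-scored before fitting;
means and variances are mapped back to mL/g afterwards. Predictive
variance is the latent-function variance by default; an
`include_noise` flag adds σ_n², and the monitor's guards use the latent
variance.

## One-step and multi-step forecasting

The one-step (OS) model regresses SVI on the eight daily process
variables: dissolved oxygen, COD, influent flow, solids retention time,
MLSS, settled-volume fractions in the oxidation ditch and recycle line,
and temperature. It is fitted once on the first 50 samples of the
record.

The multi-step (MS) model is an autoregression on the last
`n_lags + 1 = 8` SVI values (lag 7 chosen by ACF/PACF-style reasoning;
the lag is configurable). H-step forecasts use the recursive strategy:
the value just forecast is appended to the lag window and the same
one-step model is applied until the horizon H (default 6 days) is
reached. Uncertainty is propagated two ways:

- **plugin** (default): report the GP's one-step variance at each
  plugged-in input. Cheap, and matches the recursive description the
  scheme is built on, but ignores the uncertainty of the fed-back
  values, so it understates multi-step variance.
- **monte_carlo**: roll `n_samples` (default 1000) trajectories,
  sampling each step from its one-step Gaussian; per-horizon means and
  variances are empirical moments. Dominates the plugin variance for
  h ≥ 2, which the tests assert.

Exact moment-matching propagation of input uncertainty is out of scope.

## The hybrid automaton

While in S1/S2 the automaton steps on OS one-step forecasts; `y⁺ > 135`
escalates S1→S2, `y⁺ < 135` de-escalates, and `y⁺ > 165` escalates
S2→S3 and triggers the MS model, which is then fitted on all SVI
observed so far (i.e. the data before limited bulking occurred). In
S3/S4 the automaton steps on H-step trajectories and the guards use the
horizon-maximum y⁺ against 250 (escalation on any step above,
de-escalation only when every step is below); the symmetric choice for
S3→S2 uses the horizon-maximum against 165. All guards are strict;
equality holds the state; at most one level changes per step. Upward
transitions emit `upper_bound` alarms (precaution / limited / serious);
`confirmed_mean` alarms fire once per excursion when the predictive
mean itself exceeds the level's threshold. Because y⁺ ≥ y, a
confirmation can never precede its upper-bound alarm.

Optional behaviors, both off by default: `hysteresis` requires a
de-escalation guard to hold on two consecutive steps (prevents
chattering on noisy bounds); `refit_ms` refits the MS model as each new
observation arrives instead of once at trigger time.

## The synthetic episode generator

The plant record the scheme was designed around is not public, so the
generator emulates its structure: 213 daily samples, bulking onset at
sample 101, and a ramp from a 100 mL/g baseline to a 290 mL/g peak at
the final sample, which places the 165-crossing at day 139 and the
250-crossing at day 189. The observed SVI adds N(0, 4²) measurement
noise to the latent trajectory.

The normal regime is not flat: real plants wander. The latent SVI
carries a quasi-seasonal wander (two sinusoids, amplitudes 28 and
14 mL/g, periods 75 and 27 d, phases drawn per seed) that is tapered
out over 10 days after onset so that the post-onset ramp — and hence
the threshold-crossing days — remain exactly the configured ramp. This
wander is load-bearing: a GP with a stationary kernel can only predict
responses in the neighborhood of its training range, so the OS model
needs to have seen meaningful SVI variation in its 50 training days
before it can track the early transition, and the ±2σ cap of any
stationary-GP forecast is roughly the training mean plus twice the
training standard deviation. With a flat normal regime no stationary-GP
monitor could ever raise the 165 mL/g trigger.

Covariate links (declared constants, not fitted to anything): COD
declines 0.8 mg/L per mL/g of latent SVI rise from a 400 mg/L base
(low COD loading accompanies bulking), DO declines 0.004 mg/L per mL/g
from 2.5 mg/L, the settled-volume fractions follow the physical
identity SV ≈ SVI × MLSS / 10⁶ (oxidation ditch; recycle line ×1.25),
temperature is an annual sinusoid, and influent flow, SRT and MLSS are
mean-reverting AR(1) noise around plant-typical values (170,000 m³/d,
18 d, 3,500 mg/L). Measurement noise: the oxidation-ditch settled
volume is precise (sd 0.004) — it is the dominant, learnable predictor
— while the recycle-line reading is coarse (sd 0.03); MLSS sd is
80 mg/L. Ground-truth state labels are computed from the latent
(noise-free) SVI so observation noise cannot corrupt test oracles.

What passing tests on this generator do *not* show: the real
covariate–SVI dependencies of any plant. The links claim learnability,
not mechanism. Detection performance is also seed-dependent — under
some wander phases the OS training window spans too little SVI range
and the monitor stalls in the pre-caution state rather than triggering
the MS model; the bundled seed-42 episode exhibits the full
precaution → limited → serious chain with the serious alarm one day
before the true 250-crossing.

## Reference models and metrics

Accuracy is summarized by RMSE `sqrt(mean (y − ŷ)²)` and the Pearson
coefficient r, computed by rolling-origin evaluation: a forecast made h
days earlier is paired with each held-out observation.

ARMA(p, q) is fitted by conditional least squares (pre-sample
innovations zero; q = 0 reduces exactly to OLS on the lags, which a
statsmodels cross-check verifies), with default orders (7, 1) mirroring
the MS lag and an AIC grid search available. Forecasts iterate the
recursion with future innovations set to zero. PLS1 uses scikit-learn's
NIPALS implementation; VIP scores
`VIP_j = sqrt(p Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` are computed
in-package and satisfy Σ VIP² = p. VIP is reported, not enforced — the
OS input set is fixed at the eight process variables. ACF (biased 1/n
normalization) and PACF (Durbin–Levinson) come from statsmodels behind
the package's own validated surface and are cross-checked against
brute-force definitions in the tests.

## Problem sizes and known limitations

The test suite and the acceptance script run on the 213-sample episode,
GP fits of n ≤ 132 rows, 20-replicate recovery studies at n = 80, and
200-replicate calibration studies with 10 held-out points each; these
sizes make every GP fit a sub-second dense-Cholesky problem while
leaving the statistical checks well powered.

Joint recovery of all three squared-exponential hyperparameters
(signal variance, length-scale, noise variance, each within ±0.3 in
log-space) from a single n = 80 draw succeeds in only ~60–70% of
replicates, for any input design: the Cramér–Rao bound at this sample
size puts the standard deviation of both log-variance estimates near
0.22–0.27, so the limitation is informational, not algorithmic. The
length-scale is recovered essentially always, and the noise variance
within a wider ±0.5 band; the tests assert those marginal guarantees.

A stationary-kernel GP cannot extrapolate indefinitely: once inputs
move several training standard deviations beyond the data, the
posterior mean reverts to the training mean and σ to the prior. In the
monitor this is mitigated by the MS model being fitted at trigger time
(its training window then includes the early ramp, and the
maximum-likelihood fit selects long length-scales that extrapolate the
trend), and it is the reason the serious-bulking guard uses y⁺ — the
widening envelope crosses 250 even where the mean saturates below it.
On strongly out-of-range inputs the reference ARMA model, being a
global linear recursion, can out-forecast the GP; the evaluation
subcommand reports both side by side.
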
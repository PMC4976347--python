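import itertools
import math

import numpy as np
import pytest

from svimon.data_model import NumericalError, ValidationError
from svimon.gpr_core import (
    GPModel,
    Hyperparams,
    KernelSpec,
    additive_kernel,
    build_gp,
    default_hyperparams,
    elementary_symmetric,
    fit_gp,
    gp_from_dict,
    gp_to_dict,
    kernel_diag,
    kernel_matrix,
    log_marginal_likelihood,
    pack_log_theta,
    predict_gp,
    predict_mean_var,
    unpack_log_theta,
)

ALL_SPECS = [
    KernelSpec("squared_exp"),
    KernelSpec("squared_exp", ard=True),
    KernelSpec("matern", matern_roughness=1),
    KernelSpec("matern", matern_roughness=3),
    KernelSpec("matern", matern_roughness=5),
    KernelSpec("neural_net"),
    KernelSpec("additive"),
]


def _theta_for(spec, d, rng=None):
    rng = rng or np.random.default_rng(0)
    if spec.family == "additive":
        return Hyperparams(1.0, rng.uniform(0.5, 2.0, d), 0.2,
                           order_variances=rng.uniform(0.1, 1.5, d))
    n_l = d if (spec.family == "squared_exp" and spec.ard) else 1
    return Hyperparams(rng.uniform(0.5, 2.0), rng.uniform(0.5, 2.0, n_l),
                       rng.uniform(0.05, 0.3))


class TestKernelMatrix:
    def test_se_zero_distance_gives_signal_variance(self):
        th = Hyperparams(2.5, 1.0, 0.1)
        K = kernel_matrix(KernelSpec("squared_exp"), th, [[1.0]], [[1.0]])
        assert K[0, 0] == pytest.approx(2.5)

    def test_se_unit_distance_closed_form(self):
        th = Hyperparams(1.0, 1.0, 0.1)
        K = kernel_matrix(KernelSpec("squared_exp"), th, [[0.0]], [[1.0]])
        assert K[0, 0] == pytest.approx(math.exp(-0.5), abs=1e-9)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: f"{s.family}{s.matern_roughness if s.family=='matern' else ''}{'_ard' if s.ard else ''}")
    def test_symmetry_on_self(self, spec, rng):
        X = rng.normal(size=(7, 3))
        K = kernel_matrix(spec, _theta_for(spec, 3), X, X)
        np.testing.assert_allclose(K, K.T, atol=1e-12)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: f"{s.family}{s.matern_roughness if s.family=='matern' else ''}{'_ard' if s.ard else ''}")
    def test_diag_matches_full_matrix(self, spec, rng):
        X = rng.normal(size=(6, 3))
        th = _theta_for(spec, 3)
        np.testing.assert_allclose(
            kernel_diag(spec, th, X), np.diag(kernel_matrix(spec, th, X, X)),
            atol=1e-12,
        )

    def test_dimension_mismatch_is_error(self):
        th = Hyperparams(1.0, 1.0, 0.1)
        with pytest.raises(ValidationError, match="dimension"):
            kernel_matrix(KernelSpec("squared_exp"), th, np.ones((2, 2)),
                          np.ones((2, 3)))

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValidationError):
            Hyperparams(1.0, -1.0, 0.1)


def _enumerated_additive(z, order_variances):
    """Brute-force oracle: sum over every non-empty variable subset."""
    total = 0.0
    for r, w in enumerate(order_variances, start=1):
        for comb in itertools.combinations(range(len(z)), r):
            total += w * np.prod([z[i] for i in comb])
    return total


class TestAdditiveKernel:
    def test_single_dimension_reduces_to_scaled_base(self):
        z = np.array([0.73])
        assert additive_kernel(z[:, None], [2.0])[0] == pytest.approx(2.0 * 0.73)

    def test_matches_subset_enumeration_up_to_d6(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            d = int(rng.integers(1, 7))
            r_max = int(rng.integers(1, d + 1))
            z = rng.uniform(0.0, 1.0, d)
            w = rng.uniform(0.0, 2.0, r_max)
            got = additive_kernel(z[:, None], w)[0]
            assert got == pytest.approx(_enumerated_additive(z, w), rel=1e-12)

    def test_zero_order_variances_give_zero(self):
        z = np.random.default_rng(0).uniform(0, 1, 5)
        assert additive_kernel(z[:, None], np.zeros(5))[0] == 0.0

    def test_order_above_dimension_rejected(self):
        with pytest.raises(ValidationError):
            elementary_symmetric(np.ones((2, 1)), 3)


class TestMarginalLikelihood:
    def test_scalar_closed_form(self):
        # n = 1: lml = -1/2 [y^2/(sf2+sn2) + log(sf2+sn2) + log 2pi]
        th = Hyperparams(1.3, 1.0, 0.4)
        m = build_gp(np.array([[0.0]]), np.array([0.7]), KernelSpec("squared_exp"), th)
        s = 1.3 + 0.4
        expected = -0.5 * (0.7**2 / s + math.log(s) + math.log(2 * math.pi))
        assert m.log_marginal_likelihood_ == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: f"{s.family}{s.matern_roughness if s.family=='matern' else ''}{'_ard' if s.ard else ''}")
    def test_analytic_gradient_matches_finite_differences(self, spec, rng):
        d = 3
        X = rng.normal(size=(6, d))
        y = rng.normal(size=6)
        th = _theta_for(spec, d, rng)
        _, g = log_marginal_likelihood(build_gp(X, y, spec, th))
        vec = pack_log_theta(spec, th, d)
        eps = 1e-6
        for j in range(len(vec)):
            vp, vm = vec.copy(), vec.copy()
            vp[j] += eps
            vm[j] -= eps
            fd = (
                build_gp(X, y, spec, unpack_log_theta(spec, vp, d)).log_marginal_likelihood_
                - build_gp(X, y, spec, unpack_log_theta(spec, vm, d)).log_marginal_likelihood_
            ) / (2 * eps)
            assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_invariant_under_row_permutation(self, rng):
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        spec = KernelSpec("squared_exp")
        th = _theta_for(spec, 2)
        perm = rng.permutation(8)
        a = build_gp(X, y, spec, th).log_marginal_likelihood_
        b = build_gp(X[perm], y[perm], spec, th).log_marginal_likelihood_
        assert a == pytest.approx(b, abs=1e-9)


class TestPrediction:
    def test_interpolation_limit_reproduces_training_targets(self, rng):
        X = np.linspace(0.0, 5.0, 6)[:, None]
        y = np.sin(X[:, 0])
        th = Hyperparams(1.0, 1.0, 1e-10)
        m = build_gp(X, y, KernelSpec("squared_exp"), th)
        mean, var = predict_mean_var(m, X)
        np.testing.assert_allclose(mean, y, atol=1e-4)
        assert np.all(var < 1e-4)

    def test_prior_reversion_far_from_data(self):
        th = Hyperparams(1.7, 0.5, 0.1)
        m = build_gp(np.zeros((3, 1)) + [[0.0], [0.1], [0.2]], np.array([1.0, 1.1, 0.9]),
                     KernelSpec("squared_exp"), th)
        mean, var = predict_mean_var(m, np.array([[50.0]]))
        assert abs(mean[0]) < 1e-8
        assert var[0] == pytest.approx(1.7, abs=1e-8)

    def test_agrees_with_dense_inverse_oracle(self, rng):
        spec = KernelSpec("squared_exp")
        th = Hyperparams(1.2, 0.8, 0.3)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        Xs = rng.normal(size=(4, 2))
        m = build_gp(X, y, spec, th)
        mean, var = predict_mean_var(m, Xs)
        Ky = kernel_matrix(spec, th, X, X) + (0.3 + m.jitter) * np.eye(5)
        Ks = kernel_matrix(spec, th, X, Xs)
        Kinv = np.linalg.inv(Ky)
        np.testing.assert_allclose(mean, Ks.T @ Kinv @ y, atol=1e-8)
        np.testing.assert_allclose(
            var, kernel_diag(spec, th, Xs) - np.sum(Ks * (Kinv @ Ks), axis=0),
            atol=1e-8,
        )

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: f"{s.family}{s.matern_roughness if s.family=='matern' else ''}{'_ard' if s.ard else ''}")
    def test_posterior_variance_never_exceeds_prior(self, spec, rng):
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        th = _theta_for(spec, 3, rng)
        m = build_gp(X, y, spec, th)
        Xs = rng.normal(size=(30, 3)) * 2
        _, var = predict_mean_var(m, Xs)
        assert np.all(var <= kernel_diag(spec, th, Xs) + 1e-10)

    def test_include_noise_adds_noise_variance(self, rng):
        X = rng.normal(size=(5, 1))
        y = rng.normal(size=5)
        m = build_gp(X, y, KernelSpec("squared_exp"), Hyperparams(1.0, 1.0, 0.37))
        _, v0 = predict_mean_var(m, X, include_noise=False)
        _, v1 = predict_mean_var(m, X, include_noise=True)
        np.testing.assert_allclose(v1 - v0, 0.37, atol=1e-12)

    def test_prediction_objects_match_arrays(self, rng):
        X = rng.normal(size=(5, 1))
        y = rng.normal(size=5)
        m = build_gp(X, y, KernelSpec("squared_exp"), Hyperparams(1.0, 1.0, 0.1))
        preds = predict_gp(m, X)
        mean, var = predict_mean_var(m, X)
        assert [p.mean for p in preds] == pytest.approx(list(mean))
        assert [p.variance for p in preds] == pytest.approx(list(var))


class TestFit:
    def test_same_seed_gives_identical_theta(self, rng):
        X = rng.normal(size=(20, 1))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=20)
        spec = KernelSpec("squared_exp")
        a = fit_gp(X, y, spec, n_restarts=3, seed=5)
        b = fit_gp(X, y, spec, n_restarts=3, seed=5)
        np.testing.assert_array_equal(
            pack_log_theta(spec, a.theta, 1), pack_log_theta(spec, b.theta, 1)
        )

    def test_optimum_is_no_worse_than_default_start(self, rng):
        X = rng.normal(size=(20, 1))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=20)
        spec = KernelSpec("squared_exp")
        fitted = fit_gp(X, y, spec, n_restarts=3, seed=5)
        start = build_gp(X, y, spec, default_hyperparams(spec, 1))
        assert fitted.log_marginal_likelihood_ >= start.log_marginal_likelihood_ - 1e-9

    def test_length_scale_and_noise_recovered_from_simulated_gp(self):
        # length-scale and noise are the well-identified hyperparameters;
        # check marginal recovery over seeded replicates
        from svimon.synthetic_data import sample_gp

        spec = KernelSpec("squared_exp")
        true = Hyperparams(1.0, 0.5, 0.01)
        hits_l, hits_n = 0, 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            base = rng.uniform(-15, 15, size=40)
            offs = np.where(np.arange(40) % 2 == 0, 0.03, 0.4)
            X = np.concatenate([base, base + offs])[:, None]
            y = sample_gp(spec, true, X, n_draws=1, seed=200 + rep)[0]
            m = fit_gp(X, y, spec, n_restarts=5, seed=rep)
            hits_l += abs(math.log(m.theta.length_scales[0] / 0.5)) <= 0.3
            hits_n += abs(math.log(m.theta.noise_variance / 0.01)) <= 0.5
        assert hits_l >= 8
        assert hits_n >= 8


class TestSerialization:
    def test_round_trip_reproduces_predictions_exactly(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        spec = KernelSpec("additive")
        th = _theta_for(spec, 3, rng)
        m = build_gp(X, y, spec, th)
        m2 = gp_from_dict(gp_to_dict(m))
        Xs = rng.normal(size=(5, 3))
        a = predict_mean_var(m, Xs)
        b = predict_mean_var(m2, Xs)
        np.testing.assert_allclose(a[0], b[0], atol=1e-12)
        np.testing.assert_allclose(a[1], b[1], atol=1e-12)

    def test_checksum_mismatch_detected(self, rng):
        X = rng.normal(size=(4, 1))
        y = rng.normal(size=4)
        doc = gp_to_dict(build_gp(X, y, KernelSpec("squared_exp"),
                                  Hyperparams(1.0, 1.0, 0.1)))
        doc["y"][0] += 1.0
        with pytest.raises(ValidationError, match="checksum"):
            gp_from_dict(doc)
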
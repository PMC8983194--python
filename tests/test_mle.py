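"""Likelihood, score, information, MLE and interval machinery."""

import numpy as np
import pytest
from scipy import optimize

from gphcs_ge import (
    CensoringPlan,
    GEParams,
    delta_ci_sh,
    delta_gradients,
    fit_ml,
    ge_hazard,
    ge_survival,
    log_likelihood,
    observed_information,
    plugin_sh,
    sample_from_observed,
    score,
    scheme_removals,
    simulate_gphc,
    wald_ci_params,
)

# frozen exact value of the scheme-2 ball-bearing log-likelihood at (4, 0.03),
# computed term by term with symbolic arithmetic
SCHEME2_LL_4_003 = -62.87856621994128


def _fd_gradient(sample, params, h=1e-6):
    a, l = params.alpha, params.lam
    ha, hl = h * max(1, a), h * max(1, l)
    return np.array([
        (log_likelihood(sample, GEParams(a + ha, l))
         - log_likelihood(sample, GEParams(a - ha, l))) / (2 * ha),
        (log_likelihood(sample, GEParams(a, l + hl))
         - log_likelihood(sample, GEParams(a, l - hl))) / (2 * hl),
    ])


def _fd_hessian(sample, params, h=1e-5):
    def g(theta):
        return score(sample, GEParams(theta[0], theta[1]))

    theta0 = np.array([params.alpha, params.lam])
    H = np.empty((2, 2))
    for j in range(2):
        step = np.zeros(2)
        step[j] = h * max(1, abs(theta0[j]))
        H[:, j] = (g(theta0 + step) - g(theta0 - step)) / (2 * step[j])
    return H


def _bare_sample(y=(1.0,), R_star=(0,), R_tau=0):
    """Assemble a minimal sample bypassing plan validation (n=1 designs are
    outside the plan invariants but exercise the bare likelihood algebra)."""
    from gphcs_ge.censoring import GPHCSample, TerminationCase

    sample = GPHCSample.__new__(GPHCSample)
    object.__setattr__(sample, "y", tuple(y))
    object.__setattr__(sample, "R_star", tuple(R_star))
    object.__setattr__(sample, "R_tau", R_tau)
    object.__setattr__(sample, "T_star", y[-1])
    object.__setattr__(sample, "case", TerminationCase.AFTER_M)
    object.__setattr__(sample, "d", len(y))
    object.__setattr__(sample, "plan", None)
    return sample


class TestLogLikelihood:
    def test_single_observation_hand_value(self):
        # l = ln(1) + ln(1) - 1 + 0 = -1 at alpha = lam = 1, y = (1,)
        sample = _bare_sample()
        assert log_likelihood(sample, GEParams(1.0, 1.0)) == pytest.approx(-1.0, abs=1e-14)

    def test_scheme2_matches_symbolic_oracle(self, bb_samples):
        _, s = bb_samples[2]
        assert log_likelihood(s, GEParams(4.0, 0.03)) == pytest.approx(
            SCHEME2_LL_4_003, rel=1e-12
        )

    def test_local_maximality_at_mle(self, bb_samples):
        _, s = bb_samples[1]
        fit = fit_ml(s)
        a, l = fit.params_hat.alpha, fit.params_hat.lam
        ll_hat = fit.loglik
        for da in (-0.01, 0.01):
            for dl in (-0.001, 0.001):
                assert ll_hat >= log_likelihood(s, GEParams(a + da, l + dl))

    def test_underflow_guard_returns_neg_inf(self, bb_samples):
        _, s = bb_samples[2]
        assert log_likelihood(s, GEParams(1.0, 50.0)) == -np.inf


class TestScore:
    def test_zero_at_mle(self, bb_samples):
        _, s = bb_samples[1]
        fit = fit_ml(s)
        g = score(s, fit.params_hat) * np.array(
            [fit.params_hat.alpha, fit.params_hat.lam]
        )
        assert np.max(np.abs(g)) < 1e-6

    def test_matches_finite_differences_on_random_samples(self, simulated_samples):
        rng = np.random.default_rng(0)
        for s in simulated_samples:
            p = GEParams(rng.uniform(0.5, 4.0), rng.uniform(0.4, 3.0))
            np.testing.assert_allclose(
                score(s, p), _fd_gradient(s, p), rtol=1e-5, atol=1e-8
            )

    def test_closed_form_alpha_root_without_removals(self, study_truth):
        # with R* = 0 and R_tau = 0, d l / d alpha = D/alpha + sum ln psi
        # has the closed root alpha = -D / sum ln psi at fixed lam
        n = 30
        plan = CensoringPlan(n, n, n - 1, (0,) * n, 1e9)
        s = simulate_gphc(study_truth, plan, 77)
        lam = 1.0
        lp = np.log(1 - np.exp(-lam * np.asarray(s.y)))
        alpha_closed = -len(s.y) / lp.sum()
        root = optimize.brentq(
            lambda a: score(s, GEParams(a, lam))[0], 1e-3, 100.0
        )
        assert root == pytest.approx(alpha_closed, rel=1e-10)


class TestObservedInformation:
    def test_matches_numerical_hessian_at_mle(self, bb_samples):
        _, s = bb_samples[2]
        fit = fit_ml(s)
        H_num = _fd_hessian(s, fit.params_hat)
        np.testing.assert_allclose(
            observed_information(s, fit.params_hat), -H_num, rtol=1e-4
        )

    def test_matches_numerical_hessian_random(self, simulated_samples):
        rng = np.random.default_rng(1)
        for s in simulated_samples[:10]:
            p = GEParams(rng.uniform(0.8, 3.0), rng.uniform(0.6, 2.0))
            np.testing.assert_allclose(
                observed_information(s, p), -_fd_hessian(s, p), rtol=1e-4
            )

    def test_symmetric_and_positive_definite_at_mle(self, bb_samples):
        _, s = bb_samples[1]
        fit = fit_ml(s)
        info = observed_information(s, fit.params_hat)
        assert info[0, 1] == info[1, 0]
        assert np.all(np.linalg.eigvalsh(info) > 0)


class TestFitML:
    def test_consistency_on_large_complete_sample(self, study_truth):
        n = 5000
        plan = CensoringPlan(n, n, n - 1, (0,) * n, 1e9)
        s = simulate_gphc(study_truth, plan, 2718)
        fit = fit_ml(s)
        se_a, se_l = fit.se
        assert abs(fit.params_hat.alpha - 2.0) < 3 * se_a
        assert abs(fit.params_hat.lam - 1.2) < 3 * se_l

    def test_scale_equivariance(self, bb_samples):
        plan, s = bb_samples[3]
        fit = fit_ml(s)
        c = 37.0
        scaled_plan = CensoringPlan(plan.n, plan.m, plan.k, plan.R, plan.T * c)
        s_scaled = sample_from_observed(np.asarray(s.y) * c, scaled_plan)
        fit_scaled = fit_ml(s_scaled)
        assert fit_scaled.params_hat.alpha == pytest.approx(
            fit.params_hat.alpha, rel=1e-6
        )
        assert fit_scaled.params_hat.lam == pytest.approx(
            fit.params_hat.lam / c, rel=1e-6
        )

    def test_requires_two_failures(self):
        with pytest.raises(ValueError):
            fit_ml(_bare_sample())

    def test_bias_shrinks_with_sample_size(self, study_truth):
        # |EB(alpha)| at (k,m) = (15,30) vs (25,50), T = 1.5, scheme 1
        biases = []
        for k, m in ((15, 30), (25, 50)):
            plan = CensoringPlan(60, m, k, scheme_removals(60, m, k, 1), 1.5)
            a_hats = []
            for i in range(500):
                s = simulate_gphc(study_truth, plan,
                                  np.random.SeedSequence(entropy=55, spawn_key=(m, i)))
                a_hats.append(fit_ml(s).params_hat.alpha)
            biases.append(abs(np.mean(a_hats) - 2.0))
        assert biases[1] < biases[0]


class TestIntervals:
    def test_wald_uses_standard_normal_quantile(self, bb_samples):
        _, s = bb_samples[1]
        fit = fit_ml(s)
        ci_a, _ = wald_ci_params(fit, gamma=0.05)
        half = ci_a.upper - ci_a.point
        assert half == pytest.approx(1.959963985 * np.sqrt(ci_a.variance), rel=1e-8)

    def test_wald_symmetric_and_unclipped(self, bb_samples):
        _, s = bb_samples[1]
        fit = fit_ml(s)
        for iv in wald_ci_params(fit, 0.05):
            assert iv.upper - iv.point == pytest.approx(iv.point - iv.lower, rel=1e-12)

    def test_wald_clipping_flag(self, bb_samples):
        _, s = bb_samples[1]
        fit = fit_ml(s)
        clipped = wald_ci_params(fit, 0.6, clip=True)  # wide gamma, narrow z
        for iv in clipped:
            assert iv.lower >= 0.0

    def test_plugin_equals_distribution_functions(self, bb_samples):
        _, s = bb_samples[3]
        fit = fit_ml(s)
        S, H = plugin_sh(fit, 50.0)
        assert S == ge_survival(50.0, fit.params_hat)
        assert H == ge_hazard(50.0, fit.params_hat)

    def test_delta_gradients_match_finite_differences(self):
        p = GEParams(2.0, 1.2)
        t, h = 0.6, 1e-6
        g = delta_gradients(p, t)
        fd = {
            "dS_dalpha": (ge_survival(t, GEParams(2 + h, 1.2))
                          - ge_survival(t, GEParams(2 - h, 1.2))) / (2 * h),
            "dS_dlam": (ge_survival(t, GEParams(2, 1.2 + h))
                        - ge_survival(t, GEParams(2, 1.2 - h))) / (2 * h),
            "dH_dalpha": (ge_hazard(t, GEParams(2 + h, 1.2))
                          - ge_hazard(t, GEParams(2 - h, 1.2))) / (2 * h),
            "dH_dlam": (ge_hazard(t, GEParams(2, 1.2 + h))
                        - ge_hazard(t, GEParams(2, 1.2 - h))) / (2 * h),
        }
        for name, val in fd.items():
            assert getattr(g, name) == pytest.approx(val, rel=1e-5), name

    def test_delta_s_gradients_vanish_at_origin(self):
        g = delta_gradients(GEParams(2.0, 1.2), 1e-8)
        assert abs(g.dS_dalpha) < 1e-6 and abs(g.dS_dlam) < 1e-6

    def test_delta_variance_is_quadratic_form(self, bb_samples):
        _, s = bb_samples[1]
        fit = fit_ml(s)
        ci_S, ci_H = delta_ci_sh(fit, 50.0, 0.05)
        g = delta_gradients(fit.params_hat, 50.0)
        M1 = np.array([g.dS_dalpha, g.dS_dlam])
        assert ci_S.variance == pytest.approx(float(M1 @ fit.vcov @ M1), rel=1e-12)
        assert ci_S.variance >= 0 and ci_H.variance >= 0
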
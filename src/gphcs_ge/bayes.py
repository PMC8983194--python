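"""Bayesian inference: gamma priors, MH-within-Gibbs, SEL estimates,
credible intervals.

Independent gamma priors ``alpha ~ Gamma(a1, b1)`` and ``lam ~ Gamma(a2, b2)``
(rate parameterization) multiply the GPHC likelihood into a joint posterior
known up to its normalizing constant.  Setting all four hyperparameters to
zero gives the standard noninformative limit ``pi(alpha, lam) ∝ 1/(alpha
lam)`` — improper, and posterior propriety is not verified analytically; the
sampler runs regardless (see docs/methods.md).

Neither full conditional is a standard family, so each Gibbs coordinate is
updated by a Metropolis-Hastings step with a normal random walk whose scale
defaults to the asymptotic standard error from the inverse observed
information at the MLE.  Proposals falling at or below zero are rejected
outright (the positive-support target has zero density there), which
preserves detailed balance without reflection.  The lam update uses the
already-updated alpha (sequential scan).

Point estimates are posterior means under squared error loss; S(t) and H(t)
are transformed *per draw* and then averaged — not evaluated at the averaged
parameters, which would differ by a Jensen gap.  Credible intervals are
symmetric-tail empirical quantiles of the retained draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .censoring import GPHCSample
from .distribution import GEParams, log1mexp
from .mle import ConvergenceError, IntervalEstimate, MLFit, fit_ml

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "log_prior",
    "log_conditional_alpha",
    "log_conditional_lambda",
    "mh_within_gibbs",
    "posterior_point_estimates",
    "credible_intervals",
]

NONINFORMATIVE = (0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class PriorSpec:
    """Gamma hyperparameters ``(a1, b1)`` for alpha and ``(a2, b2)`` for lam.

    All zeros denotes the noninformative prior ``∝ 1/(alpha * lam)``.
    """

    a1: float = 0.0
    b1: float = 0.0
    a2: float = 0.0
    b2: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a1, self.b1, self.a2, self.b2) < 0:
            raise ValueError("gamma hyperparameters must be nonnegative")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length ``N``, burn-in ``B``, seed, and optional proposal scales.

    ``proposal_sd_alpha`` / ``proposal_sd_lambda`` default to the asymptotic
    standard errors at the MLE when left ``None``.
    """

    N: int = 11_000
    B: int = 1_000
    seed: int | None = None
    proposal_sd_alpha: float | None = None
    proposal_sd_lambda: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.B < self.N):
            raise ValueError("need 0 <= B < N")


@dataclass(frozen=True)
class PosteriorDraws:
    """Paired (alpha, lam) chains of length N with burn-in index."""

    alpha_chain: np.ndarray
    lambda_chain: np.ndarray
    burn_in: int
    accept_rate_alpha: float
    accept_rate_lambda: float

    @property
    def retained(self) -> tuple:
        """Post burn-in draws ``(alpha, lam)``, each of length N - B."""
        return (self.alpha_chain[self.burn_in:], self.lambda_chain[self.burn_in:])


def log_prior(params: GEParams, prior: PriorSpec) -> float:
    """Joint log prior density up to normalizing constants."""
    return float(
        (prior.a1 - 1.0) * np.log(params.alpha)
        - prior.b1 * params.alpha
        + (prior.a2 - 1.0) * np.log(params.lam)
        - prior.b2 * params.lam
    )


def _data_arrays(sample: GPHCSample):
    y = np.asarray(sample.y)
    w = np.asarray(sample.R_star, dtype=float)
    if sample.R_tau > 0:
        x = np.append(y, sample.T)
        w = np.append(w, float(sample.R_tau))
    else:
        x = y
    return y, x, w


def log_conditional_alpha(
    alpha: float, lam: float, sample: GPHCSample, prior: PriorSpec
) -> float:
    """Log full conditional of alpha given lam, up to a constant.

    Proportional to the joint posterior at fixed lam; includes the
    ``-b1 * alpha`` prior factor.
    """
    if alpha <= 0:
        return -np.inf
    y, x, w = _data_arrays(sample)
    lp = log1mexp(lam * x)
    cens = log1mexp(-alpha * lp)
    if np.any(np.isneginf(cens[w > 0])):
        return -np.inf
    return float(
        (sample.D_star + prior.a1 - 1.0) * np.log(alpha)
        - prior.b1 * alpha
        + (alpha - 1.0) * lp[: len(y)].sum()
        + np.sum(np.where(w > 0, w * cens, 0.0))
    )


def log_conditional_lambda(
    lam: float, alpha: float, sample: GPHCSample, prior: PriorSpec
) -> float:
    """Log full conditional of lam given alpha, up to a constant."""
    if lam <= 0:
        return -np.inf
    y, x, w = _data_arrays(sample)
    lp = log1mexp(lam * x)
    cens = log1mexp(-alpha * lp)
    if np.any(np.isneginf(cens[w > 0])):
        return -np.inf
    return float(
        (sample.D_star + prior.a2 - 1.0) * np.log(lam)
        - prior.b2 * lam
        - lam * y.sum()
        + (alpha - 1.0) * lp[: len(y)].sum()
        + np.sum(np.where(w > 0, w * cens, 0.0))
    )


def mh_within_gibbs(
    sample: GPHCSample,
    prior: PriorSpec,
    config: MCMCConfig,
    init: GEParams | None = None,
) -> PosteriorDraws:
    """Component-wise Metropolis-Hastings within a Gibbs scan.

    Starts from the MLE unless ``init`` is given (falling back to ``init``
    also when the MLE is unavailable).  Each iteration proposes
    ``alpha* ~ N(alpha, sd_alpha^2)``, accepts with probability
    ``min{1, pi(alpha*|lam) / pi(alpha|lam)}``, then updates lam the same
    way given the updated alpha.  Deterministic given ``config.seed``.
    """
    fit: MLFit | None = None
    if init is None or config.proposal_sd_alpha is None or config.proposal_sd_lambda is None:
        try:
            fit = fit_ml(sample)
        except ConvergenceError as err:
            fit = err.best_fit
        except Exception:
            fit = None
    if init is None:
        if fit is None:
            raise ValueError("MLE unavailable; supply an explicit init")
        init = fit.params_hat
    if config.proposal_sd_alpha is not None:
        sd_a = float(config.proposal_sd_alpha)
    else:
        if fit is None or fit.vcov is None:
            raise ValueError("no proposal sd for alpha and no usable MLE curvature")
        sd_a = float(np.sqrt(fit.vcov[0, 0]))
    if config.proposal_sd_lambda is not None:
        sd_l = float(config.proposal_sd_lambda)
    else:
        if fit is None or fit.vcov is None:
            raise ValueError("no proposal sd for lambda and no usable MLE curvature")
        sd_l = float(np.sqrt(fit.vcov[1, 1]))

    rng = np.random.default_rng(config.seed)
    y, x, w = _data_arrays(sample)
    D = sample.D_star
    y_sum = y.sum()
    n_obs = len(y)
    wpos = w > 0

    def cond_alpha(alpha, lp, sum_lp_obs):
        if alpha <= 0:
            return -np.inf
        cens = log1mexp(-alpha * lp)
        if np.any(np.isneginf(cens[wpos])):
            return -np.inf
        return (
            (D + prior.a1 - 1.0) * np.log(alpha)
            - prior.b1 * alpha
            + (alpha - 1.0) * sum_lp_obs
            + np.sum(w[wpos] * cens[wpos])
        )

    def cond_lambda(lam, alpha):
        if lam <= 0:
            return -np.inf, None, None
        lp = log1mexp(lam * x)
        cens = log1mexp(-alpha * lp)
        if np.any(np.isneginf(cens[wpos])):
            return -np.inf, None, None
        sum_lp_obs = lp[:n_obs].sum()
        val = (
            (D + prior.a2 - 1.0) * np.log(lam)
            - prior.b2 * lam
            - lam * y_sum
            + (alpha - 1.0) * sum_lp_obs
            + np.sum(w[wpos] * cens[wpos])
        )
        return val, lp, sum_lp_obs

    N, B = config.N, config.B
    a_chain = np.empty(N)
    l_chain = np.empty(N)
    a_cur, l_cur = init.alpha, init.lam
    _, lp_cur, sum_lp_cur = cond_lambda(l_cur, a_cur)
    if lp_cur is None:
        raise ValueError("initial point has zero posterior density")
    la_cur = cond_alpha(a_cur, lp_cur, sum_lp_cur)
    acc_a = acc_l = 0

    # draw proposal and uniform streams up front; loop is then pure arithmetic
    eps_a = rng.normal(0.0, sd_a, size=N)
    eps_l = rng.normal(0.0, sd_l, size=N)
    log_u_a = np.log(rng.uniform(size=N))
    log_u_l = np.log(rng.uniform(size=N))

    for i in range(N):
        a_prop = a_cur + eps_a[i]
        la_prop = cond_alpha(a_prop, lp_cur, sum_lp_cur)
        if la_prop - la_cur > log_u_a[i]:
            a_cur, la_cur = a_prop, la_prop
            acc_a += 1

        ll_cur, _, _ = cond_lambda(l_cur, a_cur)
        l_prop = l_cur + eps_l[i]
        ll_prop, lp_prop, sum_lp_prop = cond_lambda(l_prop, a_cur)
        if ll_prop - ll_cur > log_u_l[i]:
            l_cur = l_prop
            lp_cur, sum_lp_cur = lp_prop, sum_lp_prop
            acc_l += 1
            la_cur = cond_alpha(a_cur, lp_cur, sum_lp_cur)

        a_chain[i] = a_cur
        l_chain[i] = l_cur

    rate_a, rate_l = acc_a / N, acc_l / N
    if acc_a == 0 or acc_l == 0:
        warnings.warn(
            f"MH chain never moved (acceptance rates {rate_a:.3f}, {rate_l:.3f}); "
            "check the proposal scales",
            RuntimeWarning,
        )
    return PosteriorDraws(
        alpha_chain=a_chain, lambda_chain=l_chain, burn_in=B,
        accept_rate_alpha=rate_a, accept_rate_lambda=rate_l,
    )


def _transformed_draws(draws: PosteriorDraws, t: float):
    a, l = draws.retained
    # S and H per draw; vectorized over the chain
    lp = log1mexp(l * t)
    log_S = log1mexp(-a * lp)
    S = np.exp(log_S)
    log_f = np.log(a) + np.log(l) - l * t + (a - 1.0) * lp
    H = np.exp(log_f - log_S)
    return a, l, S, H


def posterior_point_estimates(draws: PosteriorDraws, t: float):
    """SEL (posterior mean) estimates of ``(alpha, lam, S(t), H(t))``.

    S and H are computed draw by draw and then averaged.
    """
    if draws.alpha_chain.size - draws.burn_in < 1:
        raise ValueError("no retained draws")
    a, l, S, H = _transformed_draws(draws, t)
    return float(a.mean()), float(l.mean()), float(S.mean()), float(H.mean())


def credible_intervals(draws: PosteriorDraws, t: float, gamma: float = 0.05):
    """Symmetric-tail ``(gamma/2, 1-gamma/2)`` empirical quantile intervals
    for alpha, lam, S(t) and H(t).  Returns four :class:`IntervalEstimate`.

    The ``point`` carried by each interval is the posterior *median*, which
    by construction lies inside a symmetric-tail interval (the SEL posterior
    mean, reported by :func:`posterior_point_estimates`, can escape it for
    strongly skewed posteriors).
    """
    n_ret = draws.alpha_chain.size - draws.burn_in
    if n_ret * gamma / 2.0 < 1.0:
        raise ValueError(
            f"too few retained draws ({n_ret}) for tail probability {gamma / 2}"
        )
    a, l, S, H = _transformed_draws(draws, t)
    out = []
    for v in (a, l, S, H):
        lo, med, hi = np.quantile(v, [gamma / 2.0, 0.5, 1.0 - gamma / 2.0])
        out.append(
            IntervalEstimate(
                point=float(med), lower=float(lo), upper=float(hi),
                level=1.0 - gamma, variance=float(v.var(ddof=1)),
            )
        )
    return tuple(out)
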
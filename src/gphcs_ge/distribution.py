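"""The generalized exponential (exponentiated exponential) distribution.

The GE law has CDF ``F(x) = (1 - exp(-lam * x))**alpha`` for ``x > 0`` with
shape ``alpha > 0`` and rate ``lam > 0`` (units 1/time).  For ``alpha = 1`` it
reduces to the exponential distribution; ``alpha > 1`` gives a unimodal,
upside-down-bathtub-free hazard that increases from 0, ``alpha < 1`` a
decreasing hazard.  All other modules are built on the transform
``psi(x; lam) = 1 - exp(-lam * x)`` and on log-space evaluations of
``psi**alpha`` and ``1 - psi**alpha``, which stay finite where the naive
formulas underflow (x near 0) or cancel (large x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GEParams",
    "log1mexp",
    "psi",
    "log_psi",
    "log_one_minus_psi_pow",
    "ge_pdf",
    "ge_cdf",
    "ge_survival",
    "ge_hazard",
    "ge_quantile",
]


@dataclass(frozen=True)
class GEParams:
    """Shape ``alpha`` and rate ``lam`` of a generalized exponential law."""

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise ValueError(f"alpha must be a positive finite real, got {self.alpha}")
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ValueError(f"lam must be a positive finite real, got {self.lam}")


def _check_nonnegative(x, name: str = "x"):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be nonnegative")
    return x


def log1mexp(z):
    """``log(1 - exp(-z))`` for ``z >= 0``, accurate at both ends.

    Uses ``log(-expm1(-z))`` below ln 2 (avoids cancellation in ``1 - e^-z``)
    and ``log1p(-exp(-z))`` above it (keeps the tiny ``-e^-z`` term that
    ``1 - e^-z`` would round away).
    """
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore"):
        small = np.log(-np.expm1(-np.minimum(z, np.log(2.0))))
        large = np.log1p(-np.exp(-np.maximum(z, np.log(2.0))))
    out = np.where(z < np.log(2.0), small, large)
    return out[()] if out.ndim == 0 else out


def psi(x, params: GEParams):
    """The exponential CDF transform ``1 - exp(-lam * x)``.

    Evaluated via ``expm1`` so that small ``lam * x`` does not cancel.
    """
    x = _check_nonnegative(x)
    return -np.expm1(-params.lam * x)


def log_psi(x, params: GEParams):
    """``log(1 - exp(-lam * x))``; ``-inf`` at ``x = 0``."""
    x = _check_nonnegative(x)
    return log1mexp(params.lam * x)


def log_one_minus_psi_pow(x, params: GEParams):
    """``log(1 - psi(x)**alpha)``, the log-survival function.

    Computed as ``log(-expm1(alpha * log psi))`` so it survives both
    ``psi -> 1`` (where ``psi**alpha`` cancels against 1) and ``psi -> 0``.
    Returns ``-inf`` where ``psi**alpha`` reaches 1 to machine precision.
    """
    return log1mexp(-params.alpha * log_psi(x, params))


def ge_pdf(x, params: GEParams):
    """Density ``alpha * lam * exp(-lam x) * psi(x)**(alpha-1)`` for ``x > 0``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be strictly positive for the density")
    log_f = (
        np.log(params.alpha)
        + np.log(params.lam)
        - params.lam * x
        + (params.alpha - 1.0) * log_psi(x, params)
    )
    return np.exp(log_f)


def ge_cdf(x, params: GEParams):
    """CDF ``psi(x)**alpha``."""
    return np.exp(params.alpha * log_psi(x, params))


def ge_survival(x, params: GEParams):
    """Reliability ``S(x) = 1 - psi(x)**alpha``."""
    return np.exp(log_one_minus_psi_pow(x, params))


def ge_hazard(x, params: GEParams):
    """Hazard ``H(x) = f(x) / S(x)`` for ``x > 0`` with ``S(x) > 0``.

    Raises
    ------
    OverflowError
        If the survival function is zero to machine precision at ``x``
        (the ratio saturates).
    """
    log_s = log_one_minus_psi_pow(x, params)
    if np.any(np.isneginf(log_s)):
        raise OverflowError("survival is numerically zero; hazard saturates")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be strictly positive for the hazard")
    log_f = (
        np.log(params.alpha)
        + np.log(params.lam)
        - params.lam * x
        + (params.alpha - 1.0) * log_psi(x, params)
    )
    return np.exp(log_f - log_s)


def ge_quantile(u, params: GEParams):
    """Inverse CDF: ``-log(1 - u**(1/alpha)) / lam`` for ``u`` in ``[0, 1)``."""
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u must lie in [0, 1)")
    with np.errstate(divide="ignore"):
        log_root = np.log(u) / params.alpha  # log of u^(1/alpha), <= 0
    # two branches keep precision at both ends: near u -> 1 the root is close
    # to 1 and 1 - root needs expm1; for tiny roots -log(1 - root) needs log1p
    one_minus_root = -np.expm1(log_root)
    with np.errstate(divide="ignore"):
        q = np.where(
            log_root < -0.5,
            -np.log1p(-np.exp(log_root)),
            -np.log(np.where(one_minus_root > 0, one_minus_root, 1.0)),
        ) / params.lam
    q = np.where(np.isneginf(log_root), 0.0, q)
    return q[()] if q.ndim == 0 else q
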
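"""Type I generalized progressive hybrid censoring (GPHC).

A progressively Type II censored life test plans ``n`` units, ``m`` observed
failures and removals ``R_1..R_m`` (``sum R = n - m``).  The Type I
*generalized* progressive hybrid scheme adds a threshold time ``T`` and a
guaranteed minimum number of failures ``k < m``; the test terminates at

    ``T* = max{ Y_k, min{ Y_m, T } }``

so at least ``k`` and at most ``m`` failures are observed.  Writing ``d`` for
the number of failures at or before ``T``, the observed count is
``D* = max(k, min(m, d))`` and three cases arise:

* ``BEFORE_K``  (``T < Y_k``): run to the k-th failure; every unit still on
  test at ``Y_k`` is withdrawn there, so the terminal removal exceeds the
  planned ``R_k``.
* ``BETWEEN``  (``Y_k <= T < Y_m``): stop at ``T``; the ``R_tau`` survivors
  still on test are withdrawn at ``T``.
* ``AFTER_M``  (``Y_m <= T``): the plan completes; removals are as planned.

Unit conservation ``D* + sum(R*) + R_tau = n`` holds in every case.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .distribution import GEParams, ge_quantile

__all__ = [
    "CensoringPlan",
    "GPHCSample",
    "TerminationCase",
    "PlanError",
    "validate_plan",
    "scheme_removals",
    "simulate_progressive",
    "apply_type1_gphc",
    "simulate_gphc",
    "sample_from_observed",
]


class PlanError(ValueError):
    """A censoring plan violates its design constraints."""


class TerminationCase(str, enum.Enum):
    BEFORE_K = "BEFORE_K"
    BETWEEN = "BETWEEN"
    AFTER_M = "AFTER_M"


@dataclass(frozen=True)
class CensoringPlan:
    """Design of a Type I GPHC experiment.

    Parameters
    ----------
    n : int
        Units placed on test.
    m : int
        Planned number of observed failures.
    k : int
        Guaranteed minimum number of failures, ``1 <= k < m``.
    R : tuple of int
        Planned removals at each of the ``m`` failures; ``sum(R) = n - m``.
    T : float
        Threshold time, ``T > 0``.
    """

    n: int
    m: int
    k: int
    R: tuple
    T: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", tuple(int(r) for r in self.R))
        validate_plan(self)


def validate_plan(plan: CensoringPlan) -> CensoringPlan:
    """Check all plan invariants; raise :class:`PlanError` on the first violation."""
    if not (1 <= plan.k < plan.m <= plan.n):
        raise PlanError(
            f"need 1 <= k < m <= n, got k={plan.k}, m={plan.m}, n={plan.n}"
        )
    if len(plan.R) != plan.m:
        raise PlanError(f"removal vector has length {len(plan.R)}, expected m={plan.m}")
    if any(r < 0 for r in plan.R):
        raise PlanError("removals must be nonnegative")
    if sum(plan.R) != plan.n - plan.m:
        raise PlanError(
            f"removals sum to {sum(plan.R)}, expected n - m = {plan.n - plan.m}"
        )
    if not (plan.T > 0):
        raise PlanError(f"threshold T must be positive, got {plan.T}")
    return plan


def scheme_removals(n: int, m: int, k: int, which: int) -> tuple:
    """The three benchmark removal patterns used in the simulation study.

    All place mass only at the first, k-th and m-th failure, with
    ``2(n-m)/5`` at two of them and ``(n-m)/5`` at the third:

    * scheme 1: ``R_1 = R_k = 2(n-m)/5``, ``R_m = (n-m)/5``
    * scheme 2: ``R_1 = R_m = 2(n-m)/5``, ``R_k = (n-m)/5``
    * scheme 3: ``R_k = R_m = 2(n-m)/5``, ``R_1 = (n-m)/5``
    """
    if (n - m) % 5 != 0:
        raise PlanError(f"n - m = {n - m} must be divisible by 5 for these schemes")
    heavy, light = 2 * (n - m) // 5, (n - m) // 5
    R = [0] * m
    if which == 1:
        R[0], R[k - 1], R[m - 1] = heavy, heavy, light
    elif which == 2:
        R[0], R[m - 1], R[k - 1] = heavy, heavy, light
    elif which == 3:
        R[k - 1], R[m - 1], R[0] = heavy, heavy, light
    else:
        raise PlanError(f"scheme must be 1, 2 or 3, got {which}")
    return tuple(R)


@dataclass(frozen=True)
class GPHCSample:
    """One observed Type I GPHC dataset with its case bookkeeping.

    ``y`` holds the ``D*`` observed (strictly increasing) failure times,
    ``R_star`` the effective removals applied at each of them, ``R_tau`` the
    survivors withdrawn at ``T`` (nonzero only in the BETWEEN case), and
    ``T_star`` the realized termination time.  ``d`` counts failures at or
    before ``T`` among the observed ones.
    """

    y: tuple
    R_star: tuple
    R_tau: int
    T_star: float
    case: TerminationCase
    d: int
    plan: CensoringPlan

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", tuple(float(v) for v in self.y))
        object.__setattr__(self, "R_star", tuple(int(r) for r in self.R_star))
        y = np.asarray(self.y)
        if y.size < 1 or np.any(np.diff(y) <= 0):
            raise ValueError("observed times must be strictly increasing and nonempty")
        if len(self.R_star) != len(self.y):
            raise ValueError("R_star must align with observed times")
        if self.D_star + sum(self.R_star) + self.R_tau != self.plan.n:
            raise ValueError(
                "unit conservation violated: D* + sum(R*) + R_tau != n "
                f"({self.D_star} + {sum(self.R_star)} + {self.R_tau} != {self.plan.n})"
            )
        if self.y[-1] > self.T_star + 1e-12:
            raise ValueError("observed times exceed the termination time")

    @property
    def D_star(self) -> int:
        return len(self.y)

    @property
    def T(self) -> float:
        return self.plan.T


def simulate_progressive(params: GEParams, plan: CensoringPlan, seed) -> np.ndarray:
    """Draw one progressive Type II censored sample of ``m`` ordered failures.

    Uses the uniform-spacings construction: with ``U_i`` iid uniform and
    ``gamma_i = i + R_m + ... + R_{m-i+1}`` the number of units still on test
    counted from the tail, ``V_i = U_i**(1/gamma_i)`` and the cumulative
    products ``1 - prod V`` are distributed as the progressive uniform order
    statistics, which the GE quantile function maps to failure times.  Exact
    and O(m).
    """
    validate_plan(plan)
    rng = np.random.default_rng(seed)
    m = plan.m
    R = np.asarray(plan.R)
    u = rng.uniform(size=m)
    # gamma_i for i = 1..m counted from the last failure backwards
    gammas = np.arange(1, m + 1) + np.cumsum(R[::-1])
    v = u ** (1.0 / gammas)
    # i-th progressive uniform order statistic: 1 - V_m V_{m-1} ... V_{m-i+1}
    w = 1.0 - np.cumprod(v[::-1])
    return ge_quantile(w, params)


def apply_type1_gphc(times, plan: CensoringPlan) -> GPHCSample:
    """Apply the termination rule ``T* = max{Y_k, min{Y_m, T}}`` to a full
    progressive sample of ``m`` ordered failure times.

    Ties ``Y_i = T`` count as observed, consistent with ``Y_m <= T`` defining
    the completed-plan case.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size != plan.m or np.any(np.diff(times) <= 0):
        raise ValueError("times must be m strictly increasing failure times")
    n, m, k, T = plan.n, plan.m, plan.k, plan.T
    d = int(np.sum(times <= T))

    if T < times[k - 1]:
        # fewer than k failures by T: extend to the k-th failure, then stop;
        # everyone left on test at Y_k is withdrawn there
        y = times[:k]
        R_star = list(plan.R[: k - 1])
        R_star.append(n - k - sum(R_star))
        return GPHCSample(
            y=tuple(y), R_star=tuple(R_star), R_tau=0,
            T_star=float(times[k - 1]), case=TerminationCase.BEFORE_K, d=d, plan=plan,
        )
    if times[m - 1] <= T:
        return GPHCSample(
            y=tuple(times), R_star=plan.R, R_tau=0,
            T_star=float(times[m - 1]), case=TerminationCase.AFTER_M, d=d, plan=plan,
        )
    # Y_k <= T < Y_m: stop at T, withdraw the survivors
    y = times[:d]
    R_star = tuple(plan.R[:d])
    R_tau = n - d - sum(R_star)
    return GPHCSample(
        y=tuple(y), R_star=R_star, R_tau=int(R_tau),
        T_star=float(T), case=TerminationCase.BETWEEN, d=d, plan=plan,
    )


def simulate_gphc(params: GEParams, plan: CensoringPlan, seed) -> GPHCSample:
    """Simulate a full progressive sample and truncate it by the GPHC rule."""
    return apply_type1_gphc(simulate_progressive(params, plan, seed), plan)


def sample_from_observed(y, plan: CensoringPlan) -> GPHCSample:
    """Reconstruct the case bookkeeping from observed times alone.

    Used when loading a dataset file, where only the ``D*`` observed failures
    are available (the unobserved tail of the progressive sample is not).
    The case is identified from the length of ``y`` and its position relative
    to ``T``; ``D*``, ``R*``, ``R_tau`` and ``T*`` are then recomputed.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 1 or np.any(np.diff(y) <= 0):
        raise ValueError("observed times must be strictly increasing and nonempty")
    n, m, k, T = plan.n, plan.m, plan.k, plan.T
    D = y.size
    d = int(np.sum(y <= T))

    if D == k and y[-1] > T:
        R_star = list(plan.R[: k - 1])
        R_star.append(n - k - sum(R_star))
        case, T_star, R_tau = TerminationCase.BEFORE_K, float(y[-1]), 0
    elif D == m and y[-1] <= T:
        R_star, case, T_star, R_tau = list(plan.R), TerminationCase.AFTER_M, float(y[-1]), 0
    elif k <= D < m and y[-1] <= T:
        R_star = list(plan.R[:D])
        R_tau = n - D - sum(R_star)
        case, T_star = TerminationCase.BETWEEN, float(T)
    else:
        raise ValueError(
            f"observed times (D*={D}) are inconsistent with plan "
            f"(k={k}, m={m}, T={T}): no termination case matches"
        )
    return GPHCSample(
        y=tuple(y), R_star=tuple(R_star), R_tau=int(R_tau),
        T_star=T_star, case=case, d=d, plan=plan,
    )
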
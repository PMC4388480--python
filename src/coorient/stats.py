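"""Error propagation and power analysis for the COOP bounds.

The normal range of the COOP is delimited by the uncorrelated bound
``COOP_u = OOP_P * OOP_Q`` and the correlated bound
``COOP_c = min(OOP)/max(OOP)``.  Interpreting a measured COOP requires the
two bounds to be statistically distinguishable given the measurement error
of the OOPs, so this module propagates the OOP standard deviations into the
bounds (first-order delta method) and runs a two-sample Welch t-test on the
null hypothesis COOP_u = COOP_c.  From that test it derives the largest
tolerable OOP error at a fixed sample size and the smallest sample size at
a fixed error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "PowerQuery",
    "sigma_coop_u",
    "sigma_coop_c",
    "bound_separation_test",
    "max_tolerable_error",
    "min_sample_size",
    "max_error_surface",
    "min_sample_size_surface",
]

#: search bracket and absolute tolerance for the max-tolerable-error bisection
_SIGMA_LO, _SIGMA_HI, _SIGMA_TOL = 1e-6, 2.0, 1e-4

#: sample-size cap beyond which min_sample_size reports infinity
_N_CAP = 10**6


@dataclass
class PowerQuery:
    """Inputs for the bound-separation t-test.

    A single OOP measurement error ``sigma_oop`` is shared by both
    constructs (sigma_OOP_P = sigma_OOP_Q), matching the symmetric-error
    assumption under which the power surfaces are defined.
    """

    oop_p: float
    oop_q: float
    sigma_oop: float
    n: int
    alpha: float = 0.05

    def __post_init__(self):
        for name in ("oop_p", "oop_q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sigma_oop <= 0:
            raise ValueError("sigma_oop must be positive")
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def sigma_coop_u(oop_p: float, oop_q: float, sigma_p: float, sigma_q: float) -> float:
    """Delta-method standard deviation of COOP_u = OOP_P * OOP_Q.

    ``sqrt(OOP_Q^2 s_P^2 + OOP_P^2 s_Q^2)``.
    """
    _check_inputs(oop_p, oop_q, sigma_p, sigma_q)
    return math.sqrt((oop_q * sigma_p) ** 2 + (oop_p * sigma_q) ** 2)


def sigma_coop_c(oop_p: float, oop_q: float, sigma_p: float, sigma_q: float) -> float:
    """Delta-method standard deviation of COOP_c = min(OOP)/max(OOP).

    The branch with the larger OOP in the denominator is used; the two
    branches coincide at OOP_P = OOP_Q, where the derivative of min/max does
    not exist but the symmetric estimate remains finite.  Undefined when
    both OOPs are zero.
    """
    _check_inputs(oop_p, oop_q, sigma_p, sigma_q)
    if oop_p == 0.0 and oop_q == 0.0:
        raise ValueError("sigma_coop_c is undefined when both OOPs are zero")
    if oop_p >= oop_q:
        hi, lo, s_hi, s_lo = oop_p, oop_q, sigma_p, sigma_q
    else:
        hi, lo, s_hi, s_lo = oop_q, oop_p, sigma_q, sigma_p
    return math.sqrt((lo / hi**2 * s_hi) ** 2 + (s_lo / hi) ** 2)


def _welch(delta, s_u, s_c, n):
    """Welch t statistic, Satterthwaite dof and two-tailed p (vectorized)."""
    v_u = np.square(s_u) / n
    v_c = np.square(s_c) / n
    se2 = v_u + v_c
    t = delta / np.sqrt(se2)
    dof = np.square(se2) / ((np.square(v_u) + np.square(v_c)) / (n - 1))
    p = 2.0 * _sps.t.sf(np.abs(t), dof)
    return t, dof, p


def bound_separation_test(q: PowerQuery) -> tuple[float, float, float]:
    """Two-sample Welch t-test of the null hypothesis COOP_u = COOP_c.

    Group means are the two bounds computed from the query's OOPs; group
    standard deviations come from the delta-method propagation with
    sigma_OOP_P = sigma_OOP_Q = ``q.sigma_oop``; each group has size
    ``q.n``.  Returns ``(t_value, dof, p_value)`` with Welch-Satterthwaite
    degrees of freedom and a two-tailed p-value.
    """
    cu = q.oop_p * q.oop_q
    hi = max(q.oop_p, q.oop_q)
    cc = 1.0 if hi == 0.0 else min(q.oop_p, q.oop_q) / hi
    s_u = sigma_coop_u(q.oop_p, q.oop_q, q.sigma_oop, q.sigma_oop)
    s_c = sigma_coop_c(q.oop_p, q.oop_q, q.sigma_oop, q.sigma_oop)
    if s_u == 0.0 and s_c == 0.0:
        raise ValueError("test undefined: both propagated deviations are zero")
    t, dof, p = _welch(cc - cu, s_u, s_c, q.n)
    return float(t), float(dof), float(p)


def max_tolerable_error(oop_p: float, oop_q: float, n: int, alpha: float = 0.05) -> float:
    """Largest OOP error still separating COOP_u from COOP_c at level alpha.

    Bisects on sigma_OOP (shared by both constructs) over [1e-6, 2] to
    absolute tolerance 1e-4; returns 0 when the bounds coincide so that no
    error level makes them distinguishable.
    """
    out = max_error_surface(np.array([oop_p]), np.array([oop_q]), n, alpha)
    return float(out[0])


def max_error_surface(oop_p, oop_q, n: int, alpha: float = 0.05) -> np.ndarray:
    """Vectorized ``max_tolerable_error`` over broadcast OOP arrays."""
    op = np.asarray(oop_p, dtype=float)
    oq = np.asarray(oop_q, dtype=float)
    op, oq = np.broadcast_arrays(op, oq)
    shape = op.shape
    op, oq = op.ravel(), oq.ravel()

    cu = op * oq
    hi = np.maximum(op, oq)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(hi > 0, np.minimum(op, oq) / np.where(hi > 0, hi, 1.0), 1.0)
    delta = cc - cu
    # per-unit-sigma propagation factors (both groups share sigma)
    g_u = np.hypot(oq * 1.0, op * 1.0)  # sigma_coop_u / sigma
    lo = np.minimum(op, oq)
    safe_hi = np.where(hi > 0, hi, 1.0)
    g_c = np.hypot(lo / safe_hi**2, 1.0 / safe_hi)  # sigma_coop_c / sigma
    alive = (delta > 0) & (hi > 0)

    lo_b = np.full(op.shape, _SIGMA_LO)
    hi_b = np.full(op.shape, _SIGMA_HI)
    # p(sigma) increases with sigma; find the root p(sigma) = alpha
    while np.max(hi_b - lo_b) > _SIGMA_TOL:
        mid = 0.5 * (lo_b + hi_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            _, _, p = _welch(delta, g_u * mid, g_c * mid, n)
        reject = p < alpha
        lo_b = np.where(reject, mid, lo_b)
        hi_b = np.where(reject, hi_b, mid)
    out = 0.5 * (lo_b + hi_b)
    out[~alive] = 0.0
    return out.reshape(shape)


def min_sample_size(oop_p: float, oop_q: float, sigma_oop: float,
                    alpha: float = 0.05) -> float:
    """Smallest per-group n (>= 2) separating the bounds at level alpha.

    The p-value is monotone decreasing in n, so an exponential search for a
    feasible n is followed by a binary search for the smallest one.  Returns
    ``math.inf`` when no n up to 10^6 achieves significance (the bounds are
    too close relative to the error).
    """
    if sigma_oop <= 0:
        raise ValueError("sigma_oop must be positive")
    hi = max(oop_p, oop_q)
    if hi == 0.0:
        # normal range is [0, 1] but sigma_coop_c has no defined derivative
        return math.inf
    cu = oop_p * oop_q
    cc = min(oop_p, oop_q) / hi
    if cc - cu <= 0:
        return math.inf
    s_u = sigma_coop_u(oop_p, oop_q, sigma_oop, sigma_oop)
    s_c = sigma_coop_c(oop_p, oop_q, sigma_oop, sigma_oop)

    def p_at(n):
        return _welch(cc - cu, s_u, s_c, n)[2]

    n = 2
    while p_at(n) >= alpha:
        if n >= _N_CAP:
            return math.inf
        n = min(2 * n, _N_CAP)
    # smallest feasible n lies in (n//2, n]
    lo, hi_n = max(2, n // 2), n
    while lo < hi_n:
        mid = (lo + hi_n) // 2
        if p_at(mid) < alpha:
            hi_n = mid
        else:
            lo = mid + 1
    return float(lo)


def min_sample_size_surface(oop_p, oop_q, sigma_oop: float, alpha: float = 0.05) -> np.ndarray:
    """Elementwise ``min_sample_size`` over broadcast OOP arrays (inf-flagged)."""
    op, oq = np.broadcast_arrays(np.asarray(oop_p, float), np.asarray(oop_q, float))
    out = np.empty(op.shape, dtype=float)
    it = np.nditer(op, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        out[idx] = min_sample_size(float(op[idx]), float(oq[idx]), sigma_oop, alpha)
    return out


def _check_inputs(oop_p, oop_q, sigma_p, sigma_q):
    for name, v in (("oop_p", oop_p), ("oop_q", oop_q)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if sigma_p < 0 or sigma_q < 0:
        raise ValueError("standard deviations must be non-negative")
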
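"""Synthetic orientation-field generators for validating the COOP.

Each generator emulates one of the study regimes used to characterize the
parameter: perfectly aligned and isotropic fields, truncated-Gaussian angle
distributions of prescribed width, statistically independent pairs (which
realize the uncorrelated bound COOP_u = OOP_P * OOP_Q), noise-coupled pairs
(which realize the correlated bound COOP_c = min(OOP)/max(OOP)), and the
two deliberately pathological constructions: the anti-correlated two-mode
mixture that drives the COOP below COOP_u, and the sorted-pairing
ultra-correlated construction that drives it above COOP_c.

All randomness flows through ``numpy.random.default_rng``; identical spec
plus seed yields bit-identical fields.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats as _sps

from .core import OrientationField, PairedField

__all__ = [
    "TruncatedGaussianSpec",
    "gen_aligned",
    "gen_isotropic",
    "gen_truncated_gaussian",
    "gen_uncorrelated_pair",
    "gen_correlated_pair",
    "gen_anticorrelated_pair",
    "gen_ultracorrelated_pair",
    "pair_from_fields",
    "expected_oop",
    "sigma_for_oop",
    "expected_anticorrelated",
    "expected_ultracorrelated",
]


@dataclass
class TruncatedGaussianSpec:
    """Gaussian angle distribution truncated to ``mean +/- half_width``.

    The default half-width of pi/2 spans the full axial period, making the
    truncated density a proper distribution over orientations.  Samples are
    truncated first and then wrapped into [0, pi).
    """

    mean: float = 0.0
    sigma: float = 0.3
    half_width: float = math.pi / 2
    n: int = 10**6
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.half_width <= math.pi / 2:
            raise ValueError("half_width must lie in (0, pi/2]")
        if self.n < 1:
            raise ValueError("n must be at least 1")


def gen_aligned(n: int, angle: float = 0.0, seed: int | None = None) -> OrientationField:
    """Perfectly aligned field: ``n`` copies of one angle (OOP = 1)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return OrientationField(np.full(n, float(angle)), label="aligned")


def gen_isotropic(n: int, seed: int = 0) -> OrientationField:
    """Isotropic field: ``n`` i.i.d. uniform draws on [0, pi)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    return OrientationField(rng.uniform(0.0, math.pi, size=n), label="isotropic")


def _truncnorm_draw(sigma: float, half_width: float, n: int, rng) -> np.ndarray:
    a = -half_width / sigma
    return _sps.truncnorm.rvs(a, -a, loc=0.0, scale=sigma, size=n, random_state=rng)


def gen_truncated_gaussian(spec: TruncatedGaussianSpec) -> OrientationField:
    """Sample a truncated-Gaussian orientation field per its spec."""
    rng = np.random.default_rng(spec.seed)
    angles = spec.mean + _truncnorm_draw(spec.sigma, spec.half_width, spec.n, rng)
    return OrientationField(angles, label=f"truncnorm(mean={spec.mean}, sigma={spec.sigma})")


def expected_oop(sigma: float, half_width: float = math.pi / 2) -> float:
    """Population OOP of a centered truncated Gaussian: E[cos 2t].

    By symmetry the director is the distribution mean and the order
    parameter reduces to the expectation of cos(2t) over the truncated
    density; evaluated by quadrature.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = half_width / sigma
    norm = _sps.norm(0.0, sigma)
    z = 2.0 * norm.cdf(half_width) - 1.0
    val, _ = integrate.quad(lambda t: math.cos(2 * t) * norm.pdf(t), -half_width, half_width)
    return val / z


def sigma_for_oop(target_oop: float, half_width: float = math.pi / 2,
                  tol: float = 1e-6) -> float:
    """Truncated-Gaussian width whose population OOP equals ``target_oop``.

    E[cos 2t] decreases monotonically in sigma from 1 towards the uniform
    limit sin(2w)/(2w) on +/- w, so a bisection suffices.  The target must
    exceed that flat-limit OOP (which is 0 for the full half-width pi/2).
    """
    flat = math.sin(2 * half_width) / (2 * half_width)
    if not flat < target_oop < 1.0:
        raise ValueError(f"target OOP must lie in ({flat:.4g}, 1) for half_width={half_width:.4g}")
    lo, hi = 1e-4, 50.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if expected_oop(mid, half_width) > target_oop:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pair_from_fields(p: OrientationField, q: OrientationField,
                     weights=None) -> PairedField:
    """Zip two index-aligned orientation fields into a PairedField."""
    return PairedField(p.angles, q.angles, weights=weights,
                       coords=p.coords if p.coords is not None else None)


def gen_uncorrelated_pair(spec_p: TruncatedGaussianSpec, spec_q: TruncatedGaussianSpec,
                          n: int, seed: int = 0) -> PairedField:
    """Statistically independent P and Q drawn from their own distributions.

    As n grows the COOP converges to the uncorrelated bound
    OOP_P * OOP_Q.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_p, rng_q = (np.random.default_rng(s) for s in ss)
    p = spec_p.mean + _truncnorm_draw(spec_p.sigma, spec_p.half_width, n, rng_p)
    q = spec_q.mean + _truncnorm_draw(spec_q.sigma, spec_q.half_width, n, rng_q)
    return PairedField(p, q)


def gen_correlated_pair(spec_p: TruncatedGaussianSpec, target_oop_q: float,
                        n: int, seed: int = 0) -> PairedField:
    """Noise-coupled pair: Q = P + independent noise hitting a target OOP.

    P is drawn from ``spec_p``; the noise is a centered truncated Gaussian
    whose width is calibrated so that the population OOP of Q equals
    ``target_oop_q`` (the noise attenuates order multiplicatively:
    OOP_Q = OOP_P * E[cos 2(noise)]).  The resulting COOP converges to the
    correlated bound min(OOP)/max(OOP) as n grows.  The target must not
    exceed the empirical OOP of the generated P sample.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_p, rng_noise = (np.random.default_rng(s) for s in ss)
    p = spec_p.mean + _truncnorm_draw(spec_p.sigma, spec_p.half_width, n, rng_p)
    from .core import oop as _oop

    oop_p, _ = _oop(p)
    if target_oop_q > oop_p:
        raise ValueError(
            f"infeasible target: OOP_Q={target_oop_q} exceeds the generated OOP_P={oop_p:.4f} "
            "(P must be the better-organized construct)")
    atten = target_oop_q / oop_p
    if atten >= 1.0 - 1e-12:
        noise = np.zeros(n)
    else:
        noise_sigma = sigma_for_oop(atten)
        noise = _truncnorm_draw(noise_sigma, math.pi / 2, n, rng_noise)
    return PairedField(p, p + noise)


_DEGENERATE_STEP = math.pi / 4


def gen_anticorrelated_pair(alpha: float, n: int) -> PairedField:
    """Two-mode anti-correlated construction with exact COOP = 0.

    Half the pairs are (alpha, alpha + pi/2) — perpendicular — and half are
    (-alpha, -alpha) — parallel — so the relative-angle vectors cancel in
    the mean tensor exactly while the uncorrelated bound
    |cos(2 alpha) sin(2 alpha)| stays positive for generic alpha.  ``n`` is
    the total pair count and must be even.
    """
    if n < 2 or n % 2:
        raise ValueError("n must be an even count >= 2 (equal copies of the two pair types)")
    if math.isclose(alpha % _DEGENERATE_STEP, 0.0, abs_tol=1e-12) or \
            math.isclose(alpha % _DEGENERATE_STEP, _DEGENERATE_STEP, abs_tol=1e-12):
        warnings.warn("alpha on a multiple of pi/4: COOP_u vanishes and the "
                      "construction is degenerate", stacklevel=2)
    m = n // 2
    p = np.concatenate([np.full(m, alpha), np.full(m, -alpha)])
    q = np.concatenate([np.full(m, alpha + math.pi / 2), np.full(m, -alpha)])
    return PairedField(p, q)


def expected_anticorrelated(alpha: float) -> dict:
    """Analytic expectations for the anti-correlated construction."""
    return {
        "coop": 0.0,
        "oop_p": abs(math.cos(2 * alpha)),
        "oop_q": abs(math.sin(2 * alpha)),
        "coop_u": abs(math.cos(2 * alpha) * math.sin(2 * alpha)),
    }


def gen_ultracorrelated_pair(alphas, theta: float) -> PairedField:
    """Sorted-pairing ultra-correlated construction (COOP >= COOP_c).

    For base angles ``a_i`` in [0, pi/2] the pairs are the mirrored sets
    (a_i, a_i + theta) and (-a_i, -a_i - theta): the constant offset is
    applied with matched sign, pairing the largest P angles with the
    largest Q angles.  Validity requires sum cos(2 a_i) >= 0 and
    sum cos(2 a_i + 2 theta) >= 0 (both OOP sums non-negative) and theta in
    [0, pi/2]; then COOP - COOP_c = sum sin(2a_i) sin(2 theta) / sum
    cos(2a_i) >= 0, strict whenever some a_i != 0 and theta != 0.
    """
    a = np.atleast_1d(np.asarray(alphas, dtype=float))
    if a.size == 0:
        raise ValueError("alphas must be non-empty")
    if np.any(a < 0) or np.any(a > math.pi / 2):
        raise ValueError("alphas must lie in [0, pi/2]")
    if not 0.0 <= theta <= math.pi / 2:
        raise ValueError("theta must lie in [0, pi/2]")
    if math.cos(2 * theta) < 0:
        # the constant-offset tensor form assumes sum cos(2 theta_i) >= 0
        raise ValueError("invalid construction: cos(2 theta) < 0 (theta must not exceed pi/4)")
    if np.sum(np.cos(2 * a)) < 0:
        raise ValueError("invalid construction: sum cos(2 alpha_i) < 0")
    if np.sum(np.cos(2 * (a + theta))) < 0:
        raise ValueError("invalid construction: sum cos(2 alpha_i + 2 theta) < 0")
    p = np.concatenate([a, -a])
    q = np.concatenate([a + theta, -a - theta])
    return PairedField(p, q)


def expected_ultracorrelated(alphas, theta: float) -> dict:
    """Analytic OOPs, bounds and COOP of the ultra-correlated construction."""
    a = np.atleast_1d(np.asarray(alphas, dtype=float))
    oop_p = float(np.mean(np.cos(2 * a)))
    oop_q = float(np.mean(np.cos(2 * (a + theta))))
    coop = abs(math.cos(2 * theta))
    hi = max(oop_p, oop_q)
    coop_c = 1.0 if hi == 0 else min(oop_p, oop_q) / hi
    return {
        "coop": coop,
        "oop_p": oop_p,
        "oop_q": oop_q,
        "coop_u": oop_p * oop_q,
        "coop_c": coop_c,
    }
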
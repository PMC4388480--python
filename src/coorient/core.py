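"""Order-tensor mathematics for axial (period-pi) orientation fields.

The orientational order parameter (OOP) of a set of pseudo-vectors
``k_i = (cos t_i, sin t_i)`` is the maximum eigenvalue of the mean order
tensor ``T = 2<k k^T> - I``; it is 0 for an isotropic field and 1 for a
perfectly aligned one.  The co-orientational order parameter (COOP) applies
the same construction to the field of relative-angle vectors
``f_i = (cos(b_i - a_i), sin(b_i - a_i))`` built from two index-paired
constructs P and Q, and so measures how consistently the two constructs are
oriented *relative to each other*, independent of any global rotation.

All angles are axial: ``t`` and ``t + pi`` denote the same orientation.
Canonical storage is in ``[0, pi)`` but every formula acts on unit
pseudo-vectors, so the representative chosen is unobservable (the full
sign-flip symmetry group is exercised in the test-suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrientationField",
    "PairedField",
    "OrderTensor",
    "CoopResult",
    "order_tensor",
    "oop",
    "pair_field",
    "coop",
    "coop_uncorrelated",
    "coop_correlated",
    "normalized_coop",
    "director_to_angle",
    "classify_regime",
    "canonical_angle",
]

#: absolute tolerance below which the normal range [COOP_u, COOP_c] is
#: considered collapsed and the normalized COOP undefined
DEGENERATE_TOL = 1e-9

#: tolerance used when classifying a COOP value relative to its bounds
REGIME_TOL = 1e-6


def canonical_angle(angles):
    """Map axial angles onto their canonical representatives in ``[0, pi)``."""
    return np.asarray(angles, dtype=float) % np.pi


def _validate_weights(weights, n):
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must be index-aligned (expected {n}, got {w.shape})")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must have a positive sum")
    return w / total


@dataclass
class OrientationField:
    """A set of axial angles, optionally located at 2D pixel coordinates."""

    angles: np.ndarray
    coords: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.angles = canonical_angle(np.atleast_1d(np.asarray(self.angles, dtype=float)))
        if self.angles.size == 0:
            raise ValueError("an orientation field must contain at least one angle")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
            if len(self.coords) != len(self.angles):
                raise ValueError("coords must be index-aligned with angles")

    def __len__(self):
        return len(self.angles)

    def rotated(self, offset: float) -> "OrientationField":
        """Return a copy with every angle rotated by ``offset`` (axial wrap)."""
        return OrientationField(self.angles + offset, coords=self.coords, label=self.label)


@dataclass
class PairedField:
    """Index-aligned angles of two co-localized constructs P and Q."""

    p_angles: np.ndarray
    q_angles: np.ndarray
    weights: np.ndarray | None = None
    coords: np.ndarray | None = None

    def __post_init__(self):
        self.p_angles = canonical_angle(np.atleast_1d(np.asarray(self.p_angles, dtype=float)))
        self.q_angles = canonical_angle(np.atleast_1d(np.asarray(self.q_angles, dtype=float)))
        if self.p_angles.shape != self.q_angles.shape or self.p_angles.size == 0:
            raise ValueError("p_angles and q_angles must be non-empty and of equal length")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            _validate_weights(self.weights, len(self.p_angles))
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
            if len(self.coords) != len(self.p_angles):
                raise ValueError("coords must be index-aligned with angles")

    def __len__(self):
        return len(self.p_angles)

    def swapped(self) -> "PairedField":
        return PairedField(self.q_angles, self.p_angles, weights=self.weights, coords=self.coords)


@dataclass
class OrderTensor:
    """2x2 symmetric traceless mean order tensor with its eigen-structure.

    For ``T = [[a, b], [b, -a]]`` the eigenvalues are ``+/- sqrt(a^2 + b^2)``;
    the closed form avoids any dependence on an iterative eigensolver.
    """

    components: np.ndarray
    max_eigenvalue: float = field(init=False)
    director: np.ndarray = field(init=False)

    def __post_init__(self):
        t = np.asarray(self.components, dtype=float)
        if t.shape != (2, 2):
            raise ValueError("order tensor must be 2x2")
        if abs(t[0, 0] + t[1, 1]) > 1e-12 or abs(t[0, 1] - t[1, 0]) > 1e-12:
            raise ValueError("order tensor must be symmetric and traceless")
        self.components = t
        a, b = t[0, 0], t[0, 1]
        lam = math.hypot(a, b)
        self.max_eigenvalue = lam
        self.director = _eigvec_max(a, b, lam)


def _eigvec_max(a: float, b: float, lam: float) -> np.ndarray:
    """Unit eigenvector of [[a,b],[b,-a]] for eigenvalue +lam, canonical sign."""
    if lam == 0.0:
        # zero tensor: every direction is an eigenvector; pick the x-axis
        return np.array([1.0, 0.0])
    # (lam + a, b) solves (T - lam I) v = 0; switch form near cancellation
    if lam + a >= lam - a:
        v = np.array([lam + a, b])
    else:
        v = np.array([b, lam - a])
    v /= np.linalg.norm(v)
    return _canonical_director(v)


def _canonical_director(v: np.ndarray) -> np.ndarray:
    """Fix the +/- ambiguity: first nonzero component made positive."""
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        return -v
    return v


def _mean_tensor_entries(vx, vy, weights=None):
    """Entries (a, b) of 2<v v^T> - I for unit vectors v, optionally weighted."""
    n = len(vx)
    if weights is not None:
        w = _validate_weights(weights, n)
        a = 2.0 * float(np.dot(w, vx * vx)) - 1.0
        b = 2.0 * float(np.dot(w, vx * vy))
    else:
        a = 2.0 * float(np.mean(vx * vx)) - 1.0
        b = 2.0 * float(np.mean(vx * vy))
    return a, b


def order_tensor(angles, weights=None) -> OrderTensor:
    """Mean order tensor ``2<k k^T> - I`` of an axial angle set.

    Parameters
    ----------
    angles : array-like of float
        Axial angles in radians (period pi).
    weights : array-like of float, optional
        Non-negative weights with positive sum, index-aligned with *angles*.
    """
    t = np.atleast_1d(np.asarray(angles, dtype=float))
    if t.size == 0:
        raise ValueError("order_tensor requires at least one angle")
    kx, ky = np.cos(t), np.sin(t)
    a, b = _mean_tensor_entries(kx, ky, weights)
    return OrderTensor(np.array([[a, b], [b, -a]]))


def oop(angles, weights=None) -> tuple[float, np.ndarray]:
    """Orientational order parameter and director of an axial angle set.

    Returns ``(value, director)`` where value is the maximum eigenvalue of
    the mean order tensor, in ``[0, 1]``.
    """
    t = order_tensor(angles, weights)
    return min(t.max_eigenvalue, 1.0), t.director


def pair_field(p, q) -> np.ndarray:
    """Relative-orientation unit vectors ``f_i`` of two paired angle sets.

    ``f_i = (p_i . q_i, p_i x q_i) = (cos(b_i - a_i), sin(b_i - a_i))`` for
    unit pseudo-vectors at angles ``a_i`` (construct P) and ``b_i``
    (construct Q).  Any pi-flip of an input angle only flips the sign of
    ``f_i``, which the downstream tensor average is blind to.
    """
    a = np.atleast_1d(np.asarray(p, dtype=float))
    b = np.atleast_1d(np.asarray(q, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired angle lists must have equal length")
    d = b - a
    return np.column_stack([np.cos(d), np.sin(d)])


def coop_uncorrelated(oop_p: float, oop_q: float) -> float:
    """COOP of two statistically independent constructs: ``OOP_P * OOP_Q``."""
    _check_unit_interval(oop_p, "oop_p")
    _check_unit_interval(oop_q, "oop_q")
    return oop_p * oop_q


def coop_correlated(oop_p: float, oop_q: float) -> float:
    """COOP of maximally (noise-)correlated constructs: ``min(OOP)/max(OOP)``.

    When both OOPs are zero the normal range is the whole interval [0, 1],
    so the bound is 1 by convention; when exactly one is zero it is 0.
    """
    _check_unit_interval(oop_p, "oop_p")
    _check_unit_interval(oop_q, "oop_q")
    hi = max(oop_p, oop_q)
    lo = min(oop_p, oop_q)
    if hi == 0.0:
        return 1.0
    return lo / hi


def normalized_coop(coop_value: float, coop_u: float, coop_c: float) -> float:
    """Position of the COOP within its normal range ``[COOP_u, COOP_c]``.

    ``(COOP - COOP_u) / (COOP_c - COOP_u)``: negative means anti-correlated,
    0 uncorrelated, 1 correlated, >1 ultra-correlated.  Returns NaN when the
    normal range is degenerate (``COOP_c ~ COOP_u``).
    """
    for name, v in (("coop", coop_value), ("coop_u", coop_u), ("coop_c", coop_c)):
        _check_unit_interval(v, name)
    if abs(coop_c - coop_u) < DEGENERATE_TOL:
        return math.nan
    return (coop_value - coop_u) / (coop_c - coop_u)


def classify_regime(coop_value: float, coop_u: float, coop_c: float,
                    tol: float = REGIME_TOL) -> str:
    """Label a COOP value relative to its analytic bounds."""
    if abs(coop_c - coop_u) < DEGENERATE_TOL:
        return "degenerate"
    if coop_value < coop_u - tol:
        return "anti-correlated"
    if coop_value > coop_c + tol:
        return "ultra-correlated"
    return "normal"


_BRANCH_COS = math.cos(math.pi / 4.0)


def director_to_angle(director, reference_director=None) -> float:
    """Convert a director to its mean inter-construct angle ``theta_0``.

    The four symmetry-equivalent angles ``{t, -t, pi - t, t - pi}`` are
    collapsed onto one canonical branch chosen by the *reference* director:
    when the reference points near the y-axis the angle is reported in
    ``(0, pi)`` via arccos of the x-component, otherwise in
    ``(-pi/2, pi/2]`` via arcsin of the y-component.  This keeps a set of
    nearly-parallel directors from straddling a wrap-around (e.g. averaging
    -5 deg with 175 deg).  The reference defaults to the director itself.
    """
    d = np.asarray(director, dtype=float).reshape(2)
    if abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise ValueError("director must be a unit vector")
    ref = d if reference_director is None else np.asarray(reference_director, dtype=float).reshape(2)
    if abs(ref[0]) < _BRANCH_COS:
        # reference near-vertical: report in (0, pi)
        dx = d[0] if d[1] >= 0 else -d[0]
        return float(math.acos(min(1.0, max(-1.0, dx))))
    dy = d[1] if d[0] >= 0 else -d[1]
    return float(math.asin(min(1.0, max(-1.0, dy))))


@dataclass
class CoopResult:
    """Full COOP summary for one pair of constructs."""

    coop: float
    director: np.ndarray
    theta0: float
    oop_p: float
    oop_q: float
    coop_u: float
    coop_c: float
    normalized_coop: float  # NaN when the normal range is degenerate
    regime: str
    n: int

    def to_dict(self) -> dict:
        return {
            "coop": self.coop,
            "director": [float(self.director[0]), float(self.director[1])],
            "theta0": self.theta0,
            "oop_p": self.oop_p,
            "oop_q": self.oop_q,
            "coop_u": self.coop_u,
            "coop_c": self.coop_c,
            "normalized_coop": None if math.isnan(self.normalized_coop) else self.normalized_coop,
            "regime": self.regime,
            "n": self.n,
        }


def coop(pf: PairedField) -> CoopResult:
    """Co-orientational order parameter of a paired field.

    Builds the relative-orientation vectors ``f_i``, averages their outer
    products into the mean tensor ``T_PQ = 2<f f^T> - I`` (weighted, if the
    paired field carries weights) and takes the maximum eigenvalue.  The
    OOPs of P and Q, the analytic bounds, the normalized COOP, the regime
    label and the mean inter-construct angle are filled in alongside.
    """
    f = pair_field(pf.p_angles, pf.q_angles)
    a, b = _mean_tensor_entries(f[:, 0], f[:, 1], pf.weights)
    tensor = OrderTensor(np.array([[a, b], [b, -a]]))
    value = min(tensor.max_eigenvalue, 1.0)
    oop_p, _ = oop(pf.p_angles, pf.weights)
    oop_q, _ = oop(pf.q_angles, pf.weights)
    cu = coop_uncorrelated(oop_p, oop_q)
    cc = coop_correlated(oop_p, oop_q)
    return CoopResult(
        coop=value,
        director=tensor.director,
        theta0=director_to_angle(tensor.director),
        oop_p=oop_p,
        oop_q=oop_q,
        coop_u=cu,
        coop_c=cc,
        normalized_coop=normalized_coop(value, cu, cc),
        regime=classify_regime(value, cu, cc),
        n=len(pf),
    )


def _check_unit_interval(value: float, name: str) -> None:
    if not (-1e-12 <= value <= 1.0 + 1e-12):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
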
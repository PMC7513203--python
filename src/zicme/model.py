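"""Schlögl-class reaction network: parameters, propensities, rate law, attractors.

The network is the one-species trimolecular scheme

    3X <-> 2X   (rates k1, k2)
    X  <-> 0    (rates k3, k4)

with the two reservoir species absorbed into the effective birth constants
k2 and k4.  At volume ``V`` the molecule count ``X`` performs a birth-death
random walk with propensities

    W+(X) = (k2/V) X (X-1) + k4 V
    W-(X) = (k1/V**2) X (X-1) (X-2) + k3 X

while the concentration ``x = X/V`` obeys the macroscopic cubic rate law

    dx/dt = -k1 x**3 + k2 x**2 - k3 x + k4.

The stochastic model uses falling-factorial combinatorics ``X(X-1)(X-2)``
whereas the deterministic one uses plain powers ``x**3``; the two are kept
literally distinct throughout and never interconverted — the mismatch is a
real, finite-size effect, not a bug.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KineticParameters",
    "Distribution",
    "AttractorSet",
    "propensity_birth",
    "propensity_death",
    "deterministic_rhs",
    "find_attractors",
    "SCHLOGL_REFERENCE_PARAMS",
]

logger = logging.getLogger(__name__)

#: Reference kinetic constants (k1, k2, k3) for the bistability study.
SCHLOGL_REFERENCE_PARAMS = (0.42, 70.0, 3150.0)


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and volume for one Schlögl-class network instance.

    Parameters
    ----------
    k1 : float
        Trimolecular decay constant (concentration^-2 time^-1).
    k2 : float
        Bimolecular birth constant (concentration^-1 time^-1).
    k3 : float
        Linear decay constant (time^-1).
    k4 : float
        Zeroth-order birth constant (concentration time^-1); absorbs the
        reservoir concentration.
    V : float
        System volume, the count scale factor relating X and x = X/V.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    V: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not math.isfinite(self.V) or self.V <= 0:
            raise ValueError(f"V must be finite and > 0, got {self.V}")

    @classmethod
    def schlogl(cls, k4: float, V: float = 1.0) -> "KineticParameters":
        """The reference parameter set (k1, k2, k3) = (0.42, 70, 3150)."""
        k1, k2, k3 = SCHLOGL_REFERENCE_PARAMS
        return cls(k1=k1, k2=k2, k3=k3, k4=k4, V=V)


class Distribution:
    """Probability mass function on the truncated lattice 0..xmax.

    Stored in log space so that probabilities far below the double-precision
    underflow threshold of a linear-space representation remain meaningful
    (valley and secondary-peak masses shrink roughly exponentially with the
    volume).  ``p`` is the normalized linear-space view.
    """

    __slots__ = ("log_p",)

    def __init__(self, log_p: np.ndarray, *, normalized: bool = False):
        log_p = np.asarray(log_p, dtype=float)
        if log_p.ndim != 1 or log_p.size == 0:
            raise ValueError("log_p must be a non-empty 1-D array")
        if np.any(np.isnan(log_p)) or np.any(log_p == np.inf):
            raise ValueError("log_p contains NaN or +inf")
        if not normalized:
            log_p = log_p - logsumexp(log_p)
        self.log_p = log_p

    @classmethod
    def from_p(cls, p: np.ndarray) -> "Distribution":
        p = np.asarray(p, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        s = p.sum()
        if s <= 0:
            raise ValueError("total mass must be positive")
        with np.errstate(divide="ignore"):
            return cls(np.log(p / s), normalized=True)

    @property
    def xmax(self) -> int:
        return self.log_p.size - 1

    @property
    def p(self) -> np.ndarray:
        return np.exp(self.log_p)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.log_p.size)

    def mean(self) -> float:
        return float(self.support @ self.p)

    def tail_mass(self) -> float:
        """Probability of the last retained state — the truncation diagnostic."""
        return float(np.exp(self.log_p[-1]))

    def is_normalized(self, tol: float = 1e-12) -> bool:
        return abs(self.p.sum() - 1.0) <= tol

    def __len__(self) -> int:
        return self.log_p.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Distribution(xmax={self.xmax}, mean={self.mean():.4g})"


@dataclass(frozen=True)
class AttractorSet:
    """Real nonnegative fixed points of the rate law with their stability."""

    roots: tuple[float, ...]
    stability: tuple[str, ...]  # "stable" | "unstable" | "marginal"

    @property
    def stable_roots(self) -> tuple[float, ...]:
        return tuple(r for r, s in zip(self.roots, self.stability) if s == "stable")

    @property
    def bistable(self) -> bool:
        return len(self.stable_roots) == 2

    @property
    def largest(self) -> float:
        return self.roots[-1]


def _validate_counts(X) -> np.ndarray:
    Xa = np.asarray(X)
    if not np.issubdtype(Xa.dtype, np.number):
        raise TypeError("X must be numeric")
    if np.any(Xa < 0) or np.any(Xa != np.floor(Xa)):
        raise ValueError("X must be a nonnegative integer molecule count")
    return Xa.astype(float)


def propensity_birth(X, params: KineticParameters):
    """Birth propensity W+(X) = (k2/V) X (X-1) + k4 V.

    Accepts scalars or arrays of nonnegative integer counts.
    """
    Xa = _validate_counts(X)
    out = (params.k2 / params.V) * Xa * (Xa - 1.0) + params.k4 * params.V
    return out if out.ndim else float(out)


def propensity_death(X, params: KineticParameters):
    """Death propensity W-(X) = (k1/V^2) X (X-1) (X-2) + k3 X."""
    Xa = _validate_counts(X)
    out = (params.k1 / params.V**2) * Xa * (Xa - 1.0) * (Xa - 2.0) + params.k3 * Xa
    return out if out.ndim else float(out)


def deterministic_rhs(x, params: KineticParameters):
    """Macroscopic rate law dx/dt = -k1 x^3 + k2 x^2 - k3 x + k4 at concentration x."""
    xa = np.asarray(x, dtype=float)
    out = -params.k1 * xa**3 + params.k2 * xa**2 - params.k3 * xa + params.k4
    return out if out.ndim else float(out)


def _rhs_derivative(x: float, params: KineticParameters) -> float:
    return -3.0 * params.k1 * x**2 + 2.0 * params.k2 * x - params.k3


def find_attractors(params: KineticParameters, *, polish_tol: float = 1e-10) -> AttractorSet:
    """Real nonnegative roots of the cubic rate law, classified by stability.

    Roots come from the companion-matrix eigenvalue solve (``numpy.roots``)
    followed by one Newton polish each; this stays robust near fold points
    where two roots collide.  Stability follows the sign of the derivative of
    the rate law at the root: negative slope is stable, positive unstable, and
    a numerically zero slope (fold bifurcation) is flagged "marginal".
    Negative real roots are unphysical concentrations and discarded.
    """
    coeffs = [-params.k1, params.k2, -params.k3, params.k4]
    # strip leading zeros for degenerate (non-cubic) parameter sets
    while coeffs and coeffs[0] == 0.0:
        coeffs = coeffs[1:]
    if not coeffs or all(c == 0.0 for c in coeffs):
        raise ValueError("all-zero parameter set has no defined attractors")
    if len(coeffs) == 1:
        raise ValueError("rate law is a nonzero constant; no fixed point exists")

    raw = np.roots(coeffs)
    scale = max(abs(r) for r in raw) or 1.0
    real_roots = sorted(
        float(r.real) for r in raw if abs(r.imag) <= 1e-8 * scale
    )

    roots: list[float] = []
    stability: list[str] = []
    # scale for deciding "numerically zero" slope at a fold point
    dscale = 3 * params.k1 * scale**2 + 2 * params.k2 * scale + params.k3 or 1.0
    for r in real_roots:
        # one Newton polish; skip when the slope is (near) zero
        d = _rhs_derivative(r, params)
        if d != 0.0:
            step = deterministic_rhs(r, params) / d
            if abs(step) <= abs(r) * 0.5 + polish_tol * scale:
                r = r - step
        if r < 0.0:
            if r > -1e-9 * scale:
                r = 0.0
            else:
                logger.debug("discarding negative root %g", r)
                continue
        if roots and abs(r - roots[-1]) <= polish_tol * scale:
            continue  # collapsed double root already recorded
        d = _rhs_derivative(r, params)
        if abs(d) <= 1e-9 * dscale:
            flag = "marginal"
        else:
            flag = "stable" if d < 0 else "unstable"
        roots.append(float(r))
        stability.append(flag)

    if not roots:
        raise ValueError("no real nonnegative fixed point found")
    return AttractorSet(roots=tuple(roots), stability=tuple(stability))
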
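"""Factorial moments and the linear moment-equation hierarchy.

For a birth-death walk with polynomial propensities the time derivative of
the m-th *factorial* moment

    {X_m} = E[ X! / (X-m)! ]

is a linear combination of factorial moments:

    d mu / dt = A mu + A' mu' + mu0

where ``mu = ({X_1}, .., {X_Psi})`` collects the lower-order moments,
``mu'`` the two higher orders (Psi+1, Psi+2) dragged in by the third-order
death propensity, and ``mu0`` the constant (order-zero) source.  Because the
hierarchy never terminates on its own, this system is the input to the
zero-information closure.

The generation is combinatorial rather than via a generating function: the
forward difference of a falling factorial is ``(X+1)_m - (X)_m = m (X)_{m-1}``
and the backward one ``(X-1)_m - (X)_m = -m (X-1)_{m-1}``, so

    d{X_m}/dt = E[ m (X)_{m-1} W+(X) ] - E[ m (X-1)_{m-1} W-(X) ],

and the right-hand side is re-expanded exactly in the falling-factorial
basis with sympy.  Coefficients are exact rationals in the four volume-scaled
symbols k1/V^2, k2/V, k3, k4*V, so the symbolic output can be compared
bit-exactly against an independently derived system; numbers enter only when
a concrete parameter set is substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import sympy as sp

from .model import Distribution, KineticParameters

__all__ = [
    "MomentVector",
    "MomentSystem",
    "falling_factorial_values",
    "factorial_moment",
    "build_moment_system",
    "build_moment_system_symbolic",
]

# volume-scaled rate symbols: g1 = k1/V^2, g2 = k2/V, g3 = k3, g4 = k4*V
_G = sp.symbols("g1 g2 g3 g4", positive=True)
_X = sp.symbols("x")


@dataclass(frozen=True)
class MomentVector:
    """Factorial moments {X_1}..{X_psi} of a distribution ({X_0} == 1 implied)."""

    values: tuple[float, ...]

    @property
    def psi(self) -> int:
        return len(self.values)

    def __getitem__(self, m: int) -> float:
        if m == 0:
            return 1.0
        return self.values[m - 1]


def falling_factorial_values(x: np.ndarray, m: int) -> np.ndarray:
    """(x)_m = x (x-1) ... (x-m+1) evaluated elementwise; 1 for m == 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    for i in range(m):
        out = out * (x - i)
    return out


def factorial_moment(dist: Distribution, m: int) -> float:
    """m-th factorial moment  {X_m} = sum_X X!/(X-m)! p(X).

    The falling factorial vanishes for X < m, so the truncated sum is exact
    for any pmf supported on 0..xmax.
    """
    if not isinstance(m, (int, np.integer)) or m < 0:
        raise ValueError(f"moment order must be a nonnegative integer, got {m!r}")
    if m == 0:
        return 1.0
    X = dist.support
    return float(falling_factorial_values(X, m) @ dist.p)


def factorial_moments(dist: Distribution, orders: int) -> MomentVector:
    """Factorial moments of orders 1..orders as a MomentVector."""
    return MomentVector(tuple(factorial_moment(dist, m) for m in range(1, orders + 1)))


def _to_falling_basis(expr: sp.Expr) -> dict[int, sp.Expr]:
    """Exact coefficients c_j with expr = sum_j c_j (x)_j, by top-down peeling."""
    expr = sp.expand(expr)
    coeffs: dict[int, sp.Expr] = {}
    poly = sp.Poly(expr, _X)
    while True:
        deg = poly.degree()
        if deg < 0 or poly.is_zero:
            break
        c = poly.LC()
        coeffs[deg] = sp.simplify(c)
        expr = sp.expand(expr - c * sp.ff(_X, deg))
        poly = sp.Poly(expr, _X)
        if deg == 0:
            break
    return {j: c for j, c in coeffs.items() if c != 0}


@lru_cache(maxsize=None)
def _symbolic_rows(psi: int):
    """Rows m=1..psi of the moment hierarchy in the falling-factorial basis."""
    g1, g2, g3, g4 = _G
    Wp = g2 * _X * (_X - 1) + g4
    Wm = g1 * _X * (_X - 1) * (_X - 2) + g3 * _X
    rows = []
    for m in range(1, psi + 1):
        expr = m * sp.ff(_X, m - 1) * Wp - m * sp.ff(_X - 1, m - 1) * Wm
        coeffs = _to_falling_basis(expr)
        assert max(coeffs) <= m + 2, "death propensity raises order by at most 2"
        rows.append(coeffs)
    return tuple(rows)


def build_moment_system_symbolic(psi: int):
    """Symbolic (A, A', mu0) at closure order psi.

    Entries are exact sympy expressions in k1, k2, k3, k4, V.  A is psi x psi
    on orders 1..psi, A' is psi x 2 on orders psi+1 and psi+2, mu0 is the
    length-psi constant vector.
    """
    if not isinstance(psi, (int, np.integer)) or psi < 1:
        raise ValueError(f"closure order psi must be an integer >= 1, got {psi!r}")
    k1, k2, k3, k4, V = sp.symbols("k1 k2 k3 k4 V", positive=True)
    subs = {
        _G[0]: k1 / V**2,
        _G[1]: k2 / V,
        _G[2]: k3,
        _G[3]: k4 * V,
    }
    rows = _symbolic_rows(int(psi))
    A = sp.zeros(psi, psi)
    A_prime = sp.zeros(psi, 2)
    mu0 = sp.zeros(psi, 1)
    for i, coeffs in enumerate(rows):
        for j, c in coeffs.items():
            c = sp.expand(c.subs(subs))
            if j == 0:
                mu0[i] = c
            elif j <= psi:
                A[i, j - 1] = c
            else:
                A_prime[i, j - psi - 1] = c
    return A, A_prime, mu0


@dataclass(frozen=True)
class MomentSystem:
    """Numeric moment-equation system  d mu/dt = A mu + A' mu' + mu0."""

    psi: int
    A: np.ndarray        # (psi, psi), coefficients on orders 1..psi
    A_prime: np.ndarray  # (psi, 2),   coefficients on orders psi+1, psi+2
    mu0: np.ndarray      # (psi,)

    def rhs(self, mu: np.ndarray, mu_prime: np.ndarray) -> np.ndarray:
        """Evaluate d mu/dt for given lower/higher factorial moments."""
        return self.A @ np.asarray(mu) + self.A_prime @ np.asarray(mu_prime) + self.mu0

    def rhs_from_distribution(self, dist: Distribution) -> np.ndarray:
        mv = factorial_moments(dist, self.psi + 2)
        return self.rhs(mv.values[: self.psi], mv.values[self.psi :])


def build_moment_system(params: KineticParameters, psi: int) -> MomentSystem:
    """Instantiate the moment hierarchy numerically for one parameter set."""
    if not isinstance(psi, (int, np.integer)) or psi < 1:
        raise ValueError(f"closure order psi must be an integer >= 1, got {psi!r}")
    psi = int(psi)
    g = (
        params.k1 / params.V**2,
        params.k2 / params.V,
        params.k3,
        params.k4 * params.V,
    )
    rows = _symbolic_rows(psi)
    A = np.zeros((psi, psi))
    A_prime = np.zeros((psi, 2))
    mu0 = np.zeros(psi)
    gsubs = dict(zip(_G, g))
    for i, coeffs in enumerate(rows):
        for j, c in coeffs.items():
            val = float(c.subs(gsubs))
            if j == 0:
                mu0[i] = val
            elif j <= psi:
                A[i, j - 1] = val
            else:
                A_prime[i, j - psi - 1] = val
    return MomentSystem(psi=psi, A=A, A_prime=A_prime, mu0=mu0)
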
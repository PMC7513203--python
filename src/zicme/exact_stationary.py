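"""Exact stationary distribution of the one-species birth-death CME.

A one-dimensional birth-death chain satisfies detailed balance at
stationarity, W+(X-1) p(X-1) = W-(X) p(X), which telescopes into the
product form

    log p(X) - log p(0) = sum_{y=1..X} [ log W+(y-1) - log W-(y) ].

Everything is accumulated in log space with extended-precision partial sums
and normalized with log-sum-exp.  This matters: the linear-space product
overflows/underflows the double range once the volume grows past a few tens
(probability at X=0 falls roughly like exp(-c V)), which is exactly the
regime the closure scheme is meant to reach.  A deliberately naive
linear-space variant is retained (private) to demonstrate that failure mode.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .model import Distribution, KineticParameters, find_attractors, propensity_birth, propensity_death

__all__ = ["stationary_distribution_exact", "default_xmax"]


class TruncationError(RuntimeError):
    """Raised when the truncated lattice cannot hold the stationary mass."""


def default_xmax(params: KineticParameters) -> int:
    """Default truncation: 3 x V x (largest deterministic root), min 50."""
    xbar = find_attractors(params).largest
    return max(50, int(np.ceil(3.0 * params.V * xbar)))


def _log_weights(params: KineticParameters, xmax: int) -> np.ndarray:
    y = np.arange(1, xmax + 1)
    wp = propensity_birth(y - 1, params)
    wm = propensity_death(y, params)
    if np.any(wm <= 0.0):
        raise ZeroDivisionError(
            "death propensity vanishes at an interior state; the chain is "
            "singular (requires k3 > 0 or k1 > 0 with support above 2)"
        )
    steps = np.log(wp) - np.log(wm)
    # compensated accumulation: extended precision for the running sum
    log_r = np.cumsum(steps.astype(np.longdouble)).astype(float)
    return np.concatenate([[0.0], log_r])


def stationary_distribution_exact(
    params: KineticParameters,
    xmax: int | None = None,
    *,
    tail_tol: float = 1e-14,
    max_grow: int = 12,
) -> Distribution:
    """Exact stationary pmf on 0..xmax via the birth-death product formula.

    When ``xmax`` is omitted it starts from :func:`default_xmax` and grows
    geometrically until the boundary mass p(xmax) falls below ``tail_tol``.
    An explicit ``xmax`` is honoured but still checked against ``tail_tol``.

    Raises
    ------
    TruncationError
        If the tail mass cannot be brought below ``tail_tol``.
    ZeroDivisionError
        If a death propensity vanishes at an interior state.
    """
    if params.k2 == 0.0 and params.k4 == 0.0:
        # no births: X=0 is absorbing and the chain settles there
        log_p = np.full(2 if xmax is None else xmax + 1, -np.inf)
        log_p[0] = 0.0
        return Distribution(log_p, normalized=True)

    grow = xmax is None
    n = default_xmax(params) if xmax is None else int(xmax)
    for _ in range(max_grow):
        log_p = _log_weights(params, n)
        log_p = log_p - logsumexp(log_p)
        if log_p[-1] < np.log(tail_tol):
            return Distribution(log_p, normalized=True)
        if not grow:
            break
        n = int(np.ceil(n * 1.5))
    raise TruncationError(
        f"tail mass {np.exp(log_p[-1]):.3g} at xmax={n} exceeds tail_tol={tail_tol:g}; "
        "increase xmax"
    )


def _stationary_distribution_naive(params: KineticParameters, xmax: int) -> np.ndarray:
    """Linear-space product formula — the textbook evaluation, kept only to
    demonstrate its numerical range exhaustion at moderate volumes.

    Returns the unnormalized weights r(X) = prod W+/W-; overflow produces
    inf and the subsequent normalization NaNs, which is the point.
    """
    y = np.arange(1, xmax + 1)
    ratios = propensity_birth(y - 1, params) / propensity_death(y, params)
    with np.errstate(over="ignore", invalid="ignore"):
        r = np.concatenate([[1.0], np.cumprod(ratios)])
        return r / r.sum()
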
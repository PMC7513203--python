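"""Zero-information (maximum-entropy) closure of the stationary moment hierarchy.

The closure postulates that the stationary pmf is the one of maximum Shannon
entropy among all pmfs matching the first Psi factorial moments.  By the
Lagrange-multiplier construction that pmf has the exponential-family form

    p(X) = exp( - sum_{i=0..Psi} lambda_i X!/(X-i)! ),

with lambda_0 acting as the log-normalization.  The unknown multipliers are
chosen so that the stationary moment equations

    A mu(lambda) + A' mu'(lambda) + mu0 = 0     (Psi equations)

hold for the induced, normalized pmf.  A damped Newton-Raphson iteration
solves this square system; the Jacobian is available in closed form because
d mu_j / d lambda_i = -Cov(f_j, f_i) under the current pmf, the covariance
of falling-factorial basis functions.

Conditioning is the practical crux: raw factorial moments span tens of
orders of magnitude, so the iteration runs on volume-scaled basis functions
b_i(X) = (X)_i / s^i with s = V * xbar (xbar the largest deterministic
root), equivalently on scaled multipliers lambda_i s^i, and on row-scaled
residuals.  The reported multipliers are always on the raw, unscaled basis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp, xlogy

from .exact_stationary import stationary_distribution_exact
from .model import Distribution, KineticParameters, find_attractors
from .moment_system import (
    MomentSystem,
    MomentVector,
    build_moment_system,
    falling_factorial_values,
)

__all__ = [
    "LagrangeMultipliers",
    "MaxEntSolution",
    "SolverOptions",
    "maxent_pmf",
    "entropy",
    "steady_state_residual",
    "solve_zi_closure",
]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the requested residual tolerance."""

    def __init__(self, msg: str, solution: "MaxEntSolution | None" = None):
        super().__init__(msg)
        self.solution = solution


@dataclass(frozen=True)
class LagrangeMultipliers:
    """Multipliers lambda_0..lambda_psi of the max-entropy exponential family."""

    lambdas: tuple[float, ...]

    def __post_init__(self):
        if len(self.lambdas) < 1:
            raise ValueError("need at least lambda_0")

    @property
    def psi(self) -> int:
        return len(self.lambdas) - 1

    def __getitem__(self, i: int) -> float:
        return self.lambdas[i]


@dataclass(frozen=True)
class SolverOptions:
    """Knobs of the Newton solver.

    tol is on the row-scaled residual max-norm; step_tol on the scaled Newton
    step; xmax=None applies the 3*V*xbar rule grown until the boundary mass
    drops below tail_tol.
    """

    tol: float = 1e-10
    step_tol: float = 1e-12
    max_iter: int = 200
    max_halvings: int = 30
    xmax: int | None = None
    tail_tol: float = 1e-14


@dataclass(frozen=True)
class MaxEntSolution:
    """Converged (or diagnostic) output of the closure solve."""

    lambdas: LagrangeMultipliers
    dist: Distribution
    moments: MomentVector  # orders 1..psi+2
    entropy: float
    residual_norm: float
    iterations: int
    converged: bool
    psi: int
    xmax: int


def maxent_pmf(lambdas: LagrangeMultipliers, xmax: int) -> Distribution:
    """Normalized pmf p(X) = exp(-sum_i lambda_i (X)_i) on 0..xmax.

    Evaluated wholly in log space; the returned distribution is normalized,
    with any constant offset folded into the effective lambda_0.

    Raises
    ------
    ValueError
        If the unnormalized log-pmf is still increasing at the truncation
        boundary (divergent tail — raise xmax or reconsider the multipliers).
    """
    X = np.arange(int(xmax) + 1)
    log_q = np.zeros(X.size)
    for i, lam in enumerate(lambdas.lambdas):
        if lam != 0.0:
            log_q -= lam * falling_factorial_values(X, i)
    if log_q.size >= 2 and log_q[-1] > log_q[-2]:
        raise ValueError(
            "max-ent exponent increases at the truncation boundary; the pmf "
            "diverges — raise xmax or check the sign of the leading multiplier"
        )
    return Distribution(log_q)


def entropy(dist: Distribution) -> float:
    """Shannon entropy S = -sum_X p(X) ln p(X) in nats, with 0 ln 0 := 0."""
    p = dist.p
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("distribution must be normalized")
    return float(-np.sum(xlogy(p, p)))


def steady_state_residual(
    lambdas: LagrangeMultipliers, system: MomentSystem, xmax: int
) -> np.ndarray:
    """Stationary residual A mu + A' mu' + mu0 of the max-ent pmf (length Psi)."""
    if lambdas.psi != system.psi:
        raise ValueError(f"psi mismatch: lambdas {lambdas.psi} vs system {system.psi}")
    dist = maxent_pmf(lambdas, xmax)
    return system.rhs_from_distribution(dist)


# ---------------------------------------------------------------------------
# Newton machinery (scaled variables)
# ---------------------------------------------------------------------------


def _scaled_state(t: np.ndarray, B: np.ndarray):
    """log-pmf, pmf and scaled moments for scaled multipliers t (len psi)."""
    psi = t.size
    log_q = -B[:, :psi] @ t
    log_z = logsumexp(log_q)
    log_p = log_q - log_z
    p = np.exp(log_p)
    mu = B.T @ p  # orders 1..psi+2, scaled
    return log_p, p, mu, log_z


def _scaled_system(system: MomentSystem, s: float):
    psi = system.psi
    j = np.arange(1, psi + 1)
    m = np.arange(1, psi + 1)
    At = system.A * (s ** j)[None, :] / (s ** m)[:, None]
    jp = np.arange(psi + 1, psi + 3)
    Apt = system.A_prime * (s ** jp)[None, :] / (s ** m)[:, None]
    mu0t = system.mu0 / (s ** m)
    row_scale = np.maximum.reduce(
        [np.abs(At).max(axis=1), np.abs(Apt).max(axis=1), np.abs(mu0t)]
    )
    row_scale[row_scale == 0.0] = 1.0
    return At, Apt, mu0t, row_scale


def _residual_and_jacobian(t, B, At, Apt, mu0t, row_scale):
    psi = t.size
    log_p, p, mu, _ = _scaled_state(t, B)
    R = (At @ mu[:psi] + Apt @ mu[psi:] + mu0t) / row_scale
    # covariance C[j, i] = E[b_j b_i] - mu_j mu_i ; d mu_j / d t_i = -C[j, i]
    Bw = B * p[:, None]
    C = B.T @ Bw - np.outer(mu, mu)
    J = -(At @ C[:psi, :psi] + Apt @ C[psi:, :psi]) / row_scale[:, None]
    return R, J, log_p, mu


def _residual_only(t, B, At, Apt, mu0t, row_scale):
    psi = t.size
    _, _, mu, _ = _scaled_state(t, B)
    return (At @ mu[:psi] + Apt @ mu[psi:] + mu0t) / row_scale


def _gaussian_init_scaled(center: float, var: float, s: float, psi: int) -> np.ndarray:
    """Scaled multipliers of a discrete-Gaussian-like exponent at the given
    count-space center and variance: only lambda_1, lambda_2 are nonzero."""
    lam2 = 1.0 / (2.0 * var)
    lam1 = lam2 - center / var
    t = np.zeros(psi)
    t[0] = lam1 * s
    if psi >= 2:
        t[1] = lam2 * s**2
    return t


def _newton(t0, B, At, Apt, mu0t, row_scale, opts: SolverOptions):
    """Damped Newton on the scaled residual. Returns (t, norm, iters, ok).

    Step acceptance uses an Armijo condition on the least-squares merit
    0.5 ||R||^2 (the standard globalization), additionally accepting any
    step that lowers the residual max-norm — the latter rescues directions
    that are descent for the max-norm but not for the 2-norm merit.
    """
    t = t0.copy()
    R, J, _, _ = _residual_and_jacobian(t, B, At, Apt, mu0t, row_scale)
    norm = np.abs(R).max()
    it = 0
    while it < opts.max_iter:
        if norm < opts.tol:
            return t, norm, it, True
        try:
            step = np.linalg.solve(J, -R)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -R, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            return t, norm, it, False
        merit = 0.5 * (R @ R)
        slope = (J.T @ R) @ step  # directional derivative of the merit
        alpha = 1.0
        accepted = False
        for _ in range(opts.max_halvings + 1):
            t_new = t + alpha * step
            with np.errstate(over="ignore"):
                R_new = _residual_only(t_new, B, At, Apt, mu0t, row_scale)
            if np.all(np.isfinite(R_new)):
                armijo = (
                    slope < 0
                    and 0.5 * (R_new @ R_new) <= merit + 1e-4 * alpha * slope
                )
                if armijo or np.abs(R_new).max() < norm:
                    accepted = True
                    break
            alpha *= 0.5
        it += 1
        if not accepted:
            return t, norm, it, norm < opts.tol
        t = t_new
        R, J, _, _ = _residual_and_jacobian(t, B, At, Apt, mu0t, row_scale)
        norm = np.abs(R).max()
        if np.abs(alpha * step).max() < opts.step_tol:
            return t, norm, it, norm < opts.tol * 10
    return t, norm, it, norm < opts.tol


def _initial_scaled(
    init, params: KineticParameters, psi: int, s: float, xmax: int
) -> np.ndarray:
    """Translate an init strategy into scaled multipliers of length psi."""
    if isinstance(init, LagrangeMultipliers):
        lam = np.zeros(psi)
        src = np.array(init.lambdas[1:])
        lam[: min(psi, src.size)] = src[:psi]
        return lam * (s ** np.arange(1, psi + 1))
    if isinstance(init, np.ndarray):
        return init.copy()

    att = find_attractors(params)
    if isinstance(init, tuple) and len(init) == 2:
        kind, center = init
        if kind == "delta":
            return _gaussian_init_scaled(float(center), 0.25, s, psi)
        if kind == "poisson":
            return _gaussian_init_scaled(float(center), max(float(center), 1.0), s, psi)
        raise ValueError(f"unknown init strategy {init!r}")
    if init == "delta":
        center = params.V * att.largest
        return _gaussian_init_scaled(center, 0.25, s, psi)
    if init in ("poisson", "auto"):
        # centre on the dominant attractor according to the exact oracle
        # when the chain admits one, else on the largest stable root
        center = params.V * att.largest
        if init == "auto" and params.k3 > 0:
            try:
                ex = stationary_distribution_exact(params, xmax, tail_tol=1e-9)
                center = float(np.argmax(ex.log_p))
                if center < 1.0:
                    center = max(1.0, params.V * att.largest)
            except Exception:  # oracle unavailable; fall back to the root
                pass
        var = max(center, 1.0)
        return _gaussian_init_scaled(center, var, s, psi)
    raise ValueError(f"unknown init strategy {init!r}")


def _basis(xmax: int, psi: int, s: float) -> np.ndarray:
    X = np.arange(xmax + 1)
    B = np.empty((X.size, psi + 2))
    for i in range(1, psi + 3):
        B[:, i - 1] = falling_factorial_values(X, i) / s**i
    return B


def _solve_fixed_lattice(params, psi, t0, B, s, opts):
    """Direct Newton, then psi-continuation ladder. Returns (t, norm, iters, ok)."""
    system = build_moment_system(params, psi)
    At, Apt, mu0t, row_scale = _scaled_system(system, s)
    t, norm, iters, ok = _newton(t0, B, At, Apt, mu0t, row_scale, opts)
    if ok:
        return t, norm, iters, ok

    # psi-continuation ladder: solve even orders 2, 4, ... warm-started, then
    # (for odd targets) one final solve at psi itself
    logger.debug("direct solve failed (norm=%.3g); trying psi ladder", norm)
    total_iters = iters
    prev = None
    sub_orders = list(range(2, psi + 1, 2))
    if psi % 2 == 1 or psi == 1:
        sub_orders = sub_orders + [psi]
    for p_sub in sub_orders:
        t_start = np.zeros(p_sub)
        src = prev if prev is not None else t0
        t_start[: min(p_sub, src.size)] = src[:p_sub]
        sys_sub = build_moment_system(params, p_sub)
        At_s, Apt_s, mu0_s, rs_s = _scaled_system(sys_sub, s)
        t_sub, n_sub, i_sub, ok_sub = _newton(
            t_start, B[:, : p_sub + 2], At_s, Apt_s, mu0_s, rs_s, opts
        )
        total_iters += i_sub
        if not ok_sub:
            return t, norm, total_iters, False
        prev = t_sub
    return prev, n_sub, total_iters, True


def _anchor_k4(params: KineticParameters) -> float:
    """A k4 beyond the upper fold where the rate law is monostable-right —
    the easiest regime for the Newton solve, used as continuation anchor."""
    k4 = max(params.k4, 1.0)
    for _ in range(60):
        k4 *= 1.25
        if len(find_attractors(replace(params, k4=k4)).roots) == 1:
            return k4 * 1.1
    return k4


def solve_zi_closure(
    params: KineticParameters,
    psi: int = 10,
    init="auto",
    opts: SolverOptions | None = None,
) -> MaxEntSolution:
    """Solve the stationary ZI-closure problem at closure order psi.

    Parameters
    ----------
    params : KineticParameters
    psi : int
        Closure order (number of constrained factorial moments).  Even
        orders are strongly preferred: with an odd leading order the
        exponential family is non-normalizable on the half-line whenever the
        leading multiplier is negative, and the truncated solve can become
        boundary-dominated.  An odd psi triggers a warning.  Ten moments are
        the empirical default for bimodal Schlögl distributions.
    init : {"auto", "poisson", "delta"} or LagrangeMultipliers
        Initial guess strategy.  "auto"/"poisson" start from a moment-matched
        Gaussian-like exponent at the dominant attractor (chosen with the
        exact birth-death oracle when available), "delta" from a narrow
        spike at the largest root (the classical choice), and a
        LagrangeMultipliers instance warm-starts from a previous solution
        (the workhorse for parameter sweeps).
    opts : SolverOptions

    Returns
    -------
    MaxEntSolution
        With converged=True when the row-scaled stationary residual max-norm
        is below ``opts.tol``.

    Raises
    ------
    ConvergenceError
        When the damped Newton solve, the psi-continuation ladder and the
        k4-continuation fallback all fail to reach tolerance; the best
        iterate is attached for diagnosis.

    Notes
    -----
    The solution is independent of the initial guess (a tested property, not
    an assumption): distinct inits converge to multiplier vectors agreeing to
    solver precision.  Robustness comes from a three-stage fallback: damped
    Newton from the init; a continuation ladder in the closure order
    (2, 4, ..., psi); and continuation in k4 from an automatically chosen
    monostable-right anchor value, warm-starting each step.
    """
    if not isinstance(psi, (int, np.integer)) or psi < 1:
        raise ValueError(f"closure order psi must be an integer >= 1, got {psi!r}")
    psi = int(psi)
    if psi % 2 == 1:
        warnings.warn(
            f"odd closure order psi={psi}: the leading-order exponent makes the "
            "max-ent family non-normalizable for negative multipliers; even "
            "orders are recommended",
            stacklevel=2,
        )
    opts = opts or SolverOptions()

    att = find_attractors(params)
    s = max(params.V * att.largest, 1.0)
    xmax = opts.xmax
    if xmax is None:
        xmax = max(50, int(np.ceil(3.0 * params.V * att.largest)))

    for _attempt in range(6):
        B = _basis(xmax, psi, s)
        t0 = _initial_scaled(init, params, psi, s, xmax)
        t, norm, iters, ok = _solve_fixed_lattice(params, psi, t0, B, s, opts)

        if not ok:
            # k4-continuation from a monostable-right anchor down/up to the
            # target, on a lattice and scale wide enough for the anchor too
            anchor = _anchor_k4(params)
            p_anchor = replace(params, k4=anchor)
            anchor_reach = params.V * find_attractors(p_anchor).largest
            s_c = max(s, anchor_reach, 1.0)
            xmax_c = max(xmax, int(np.ceil(3.0 * anchor_reach)))
            B_c = _basis(xmax_c, psi, s_c)
            t0a = _initial_scaled("poisson", p_anchor, psi, s_c, xmax_c)
            t_c, n_c, i_c, ok_c = _solve_fixed_lattice(p_anchor, psi, t0a, B_c, s_c, opts)
            iters += i_c
            n_steps = max(8, int(abs(anchor - params.k4) / max(params.k4 * 0.0125, 1.0)))
            for k4_step in np.linspace(anchor, params.k4, n_steps + 1)[1:]:
                p_step = replace(params, k4=float(k4_step))
                At_s, Apt_s, mu0_s, rs_s = _scaled_system(
                    build_moment_system(p_step, psi), s_c
                )
                # keep marching on near-converged iterates; only the target
                # k4 must actually reach tolerance
                t_c, n_c, i_c, ok_c = _newton(t_c, B_c, At_s, Apt_s, mu0_s, rs_s, opts)
                iters += i_c
            if ok_c or n_c < norm:
                t, norm, ok = t_c, n_c, ok_c
                s, xmax, B = s_c, xmax_c, B_c

        log_p, p_arr, mu_scaled, log_z = _scaled_state(t, B)
        tail = np.exp(log_p[-1])
        if ok and tail > opts.tail_tol and opts.xmax is None:
            xmax = int(np.ceil(xmax * 1.5))
            lam_raw = t / (s ** np.arange(1, psi + 1))
            init = LagrangeMultipliers((0.0, *lam_raw))  # warm restart, larger lattice
            continue
        break

    lam_raw = t / (s ** np.arange(1, psi + 1))
    lam0 = float(log_z)  # normalization constant of the exponential family
    lambdas = LagrangeMultipliers((lam0, *lam_raw))
    dist = Distribution(log_p, normalized=True)
    mu_raw = tuple(mu_scaled * (s ** np.arange(1, psi + 3)))
    sol = MaxEntSolution(
        lambdas=lambdas,
        dist=dist,
        moments=MomentVector(mu_raw),
        entropy=entropy(dist),
        residual_norm=float(norm),
        iterations=int(iters),
        converged=bool(ok),
        psi=psi,
        xmax=xmax,
    )
    if not ok:
        raise ConvergenceError(
            f"ZI closure did not converge: scaled residual {norm:.3g} after "
            f"{iters} iterations (psi={psi}, xmax={xmax})",
            solution=sol,
        )
    return sol
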
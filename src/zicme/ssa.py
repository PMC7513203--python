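"""Gillespie-type exact stochastic simulation of the birth-death network.

The direct method is all that is needed for a two-reaction network: draw an
exponential waiting time at total rate W+(X) + W-(X), then pick birth or
death with probability proportional to each propensity.  Random numbers come
from numpy's counter-based Philox bit generator so that streams are
reproducible across platforms for a given integer seed.

Histograms are *time*-weighted (each state weighted by the dwell time spent
in it), which is what makes them unbiased occupancy estimates; per-bin
standard errors come from batch means over equal time slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Distribution, KineticParameters, propensity_birth, propensity_death

__all__ = ["Trajectory", "HistogramResult", "simulate_trajectory", "stationary_histogram", "default_burn_in"]

_BLOCK = 8192  # random numbers drawn per refill


@dataclass(frozen=True)
class Trajectory:
    """One SSA realization: event times and the states entered at them.

    ``times[0] == 0`` with ``states[0] == x0``; the final entry is the state
    at ``t_end`` (time is clamped there).  ``absorbed`` flags a walk that
    reached a state with zero total propensity before ``t_end``.
    """

    times: np.ndarray
    states: np.ndarray
    seed: int
    params: KineticParameters
    t_end: float
    absorbed: bool = False

    def __post_init__(self):
        if np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be nondecreasing")

    def state_at_end(self) -> int:
        return int(self.states[-1])


def default_burn_in(params: KineticParameters) -> float:
    """Heuristic relaxation allowance: 10x the slowest linear timescale."""
    from .model import find_attractors

    xbar = find_attractors(params).largest
    t_relax = 1.0 / params.k3 if params.k3 > 0 else 0.0
    if params.k4 > 0:
        t_relax = max(t_relax, params.V * xbar / (params.k4 * params.V))
    if t_relax == 0.0:
        t_relax = 1.0
    return 10.0 * t_relax


def simulate_trajectory(
    params: KineticParameters, x0: int, t_end: float, seed: int
) -> Trajectory:
    """Exact direct-method SSA run from count ``x0`` until time ``t_end``.

    Identical arguments (including seed) give byte-identical trajectories.
    A state with zero total propensity terminates the walk early and is
    flagged as absorbing.
    """
    if x0 < 0 or x0 != int(x0):
        raise ValueError(f"x0 must be a nonnegative integer, got {x0!r}")
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end!r}")
    rng = np.random.Generator(np.random.Philox(int(seed)))

    # hot loop: propensities inlined on local floats, records in growable
    # buffers, randoms drawn in blocks and converted to python floats once
    c_birth = params.k2 / params.V
    c_death3 = params.k1 / (params.V * params.V)
    k3 = params.k3
    k4V = params.k4 * params.V
    t_end = float(t_end)

    cap = 65536
    times_buf = np.empty(cap)
    states_buf = np.empty(cap, dtype=np.int64)
    times_buf[0] = 0.0
    states_buf[0] = int(x0)
    n = 1

    t = 0.0
    x = int(x0)
    absorbed = False
    i = _BLOCK
    exp_block = uni_block = None
    while True:
        xf = float(x)
        wp = c_birth * xf * (xf - 1.0) + k4V
        total = wp + c_death3 * xf * (xf - 1.0) * (xf - 2.0) + k3 * xf
        if total <= 0.0:
            absorbed = True
            break
        if i == _BLOCK:
            exp_block = rng.standard_exponential(_BLOCK).tolist()
            uni_block = rng.random(_BLOCK).tolist()
            i = 0
        t_next = t + exp_block[i] / total
        if t_next >= t_end:
            break
        t = t_next
        x = x + 1 if uni_block[i] * total < wp else x - 1
        i += 1
        if n == cap:
            cap *= 2
            times_buf = np.resize(times_buf, cap)
            states_buf = np.resize(states_buf, cap)
        times_buf[n] = t
        states_buf[n] = x
        n += 1

    times = np.empty(n + 1)
    states = np.empty(n + 1, dtype=np.int64)
    times[:n] = times_buf[:n]
    states[:n] = states_buf[:n]
    times[n] = t_end  # close the record at t_end (state persists there)
    states[n] = x
    return Trajectory(
        times=times,
        states=states,
        seed=int(seed),
        params=params,
        t_end=t_end,
        absorbed=absorbed,
    )


@dataclass(frozen=True)
class HistogramResult:
    """Time-weighted occupancy estimate with batch-means standard errors."""

    dist: Distribution
    stderr: np.ndarray
    total_time: float
    n_batches: int


def _dwell_times(traj: Trajectory, t_from: float, xmax: int) -> np.ndarray:
    """Per-state dwell time of one trajectory after ``t_from``."""
    t = np.maximum(traj.times, t_from)
    dt = np.diff(t)
    occ = np.zeros(xmax + 1)
    states = traj.states[:-1]
    keep = dt > 0
    np.add.at(occ, states[keep], dt[keep])
    return occ


def stationary_histogram(
    trajectories,
    burn_in: float = 0.0,
    n_batches: int = 10,
) -> HistogramResult:
    """Time-weighted occupancy histogram of one or more trajectories.

    The first ``burn_in`` time units of each trajectory are discarded.  The
    remaining time is cut into ``n_batches`` equal slices per trajectory;
    the per-bin standard error is the standard error of the batch occupancy
    fractions across all slices.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    post = [tr.t_end - burn_in for tr in trajectories]
    if min(post) <= 0:
        raise ValueError("burn-in leaves no post-burn-in time on some trajectory")
    xmax = int(max(tr.states.max() for tr in trajectories))

    total = float(sum(post))
    occ = np.zeros(xmax + 1)
    batches = []
    for tr, dur in zip(trajectories, post):
        occ += _dwell_times(tr, burn_in, xmax)
        edges = burn_in + np.linspace(0.0, dur, n_batches + 1)
        for lo, hi in zip(edges[:-1], edges[1:]):
            # dwell inside [lo, hi): clamp event times into the window
            t = np.clip(tr.times, lo, hi)
            dt = np.diff(t)
            b = np.zeros(xmax + 1)
            keep = dt > 0
            np.add.at(b, tr.states[:-1][keep], dt[keep])
            batches.append(b / (hi - lo))
    batch_arr = np.vstack(batches)
    nb = batch_arr.shape[0]
    stderr = batch_arr.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.zeros(xmax + 1)
    return HistogramResult(
        dist=Distribution.from_p(occ / total),
        stderr=stderr,
        total_time=total,
        n_batches=nb,
    )
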
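"""NESS sweep drivers: entropy vs k4, critical k4, bimodal range, collapse.

These reproduce the volume/kinetic-constant phenomenology of the bistable
network: the entropy of the non-equilibrium steady state traced over k4 has
a maximum where the two peaks have comparable height; the k4-interval of
bimodality narrows as the volume grows; and at fixed k4 the secondary basin
mass collapses with volume, with different k4 values handing dominance to
different attractors.

Two interchangeable engines produce the stationary pmf per grid point:
"exact" (the birth-death product formula — the default, it is fast and
exact for this one-species model class) and "zi" (the max-ent closure,
warm-started along the grid).  Per-point failures are recorded in the
output table and the sweep continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exact_stationary import stationary_distribution_exact
from .model import Distribution, KineticParameters, find_attractors
from .passage_times import DEFAULT_MODE_THRESHOLD, find_modes
from .zi_closure import ConvergenceError, entropy, solve_zi_closure

__all__ = [
    "SweepRecord",
    "BimodalRange",
    "entropy_sweep",
    "critical_k4",
    "bimodal_range",
    "collapse_profile",
]

logger = logging.getLogger(__name__)

_COLUMNS = [
    "V",
    "k4",
    "entropy",
    "n_modes",
    "peak_left",
    "peak_right",
    "valley",
    "left_mass",
    "right_mass",
    "peak_height_left",
    "peak_height_right",
    "dominant",
    "solver",
    "converged",
    "error",
]


@dataclass(frozen=True)
class SweepRecord:
    """One NESS summary row (see ``_COLUMNS`` for the tabular form)."""

    V: float
    k4: float
    entropy: float
    n_modes: int
    peak_left: int
    peak_right: int | None
    valley: int | None
    left_mass: float
    right_mass: float
    peak_height_left: float
    peak_height_right: float
    dominant: str
    solver: str
    converged: bool
    error: str = ""


@dataclass(frozen=True)
class BimodalRange:
    """Endpoints of the k4 interval with two modes at a given volume."""

    V: float
    k4_low: float | None
    k4_high: float | None

    @property
    def present(self) -> bool:
        return self.k4_low is not None

    @property
    def width(self) -> float:
        return (self.k4_high - self.k4_low) if self.present else 0.0


def _classify(
    dist: Distribution,
    params: KineticParameters,
    threshold: float,
    solver: str,
    converged: bool = True,
    error: str = "",
) -> SweepRecord:
    S = entropy(dist)
    modes = find_modes(dist, threshold)
    if modes.bimodal:
        left_mass, right_mass = modes.basin_masses
        hl, hr = modes.peak_heights
        dominant = "left" if left_mass >= right_mass else "right"
        return SweepRecord(
            V=params.V, k4=params.k4, entropy=S, n_modes=2,
            peak_left=modes.a, peak_right=modes.c, valley=modes.valley,
            left_mass=left_mass, right_mass=right_mass,
            peak_height_left=hl, peak_height_right=hr,
            dominant=dominant, solver=solver, converged=converged, error=error,
        )
    # unimodal: attribute the whole mass to the side of the nearest stable root
    att = find_attractors(params)
    stable = att.stable_roots or att.roots
    nearest = min(stable, key=lambda r: abs(modes.a / params.V - r))
    side = "left" if len(stable) > 1 and nearest == min(stable) else (
        "right" if len(stable) > 1 else "single"
    )
    return SweepRecord(
        V=params.V, k4=params.k4, entropy=S, n_modes=1,
        peak_left=modes.a, peak_right=None, valley=None,
        left_mass=1.0 if side == "left" else 0.0,
        right_mass=1.0 if side == "right" else 0.0,
        peak_height_left=modes.peak_heights[0] if modes.peak_heights else 0.0,
        peak_height_right=0.0,
        dominant=side, solver=solver, converged=converged, error=error,
    )


def _records_to_frame(records: list[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=_COLUMNS)


def entropy_sweep(
    V: float,
    k4_grid,
    engine: str = "exact",
    *,
    base: KineticParameters | None = None,
    psi: int = 10,
    threshold: float = DEFAULT_MODE_THRESHOLD,
) -> pd.DataFrame:
    """NESS entropy and mode structure for each k4 on an ascending grid.

    With ``engine="zi"`` each solve warm-starts from its grid neighbour's
    multipliers (continuation), which is what makes dense sweeps affordable
    and keeps the solver on the physical branch.  Individual failures are
    recorded per row (``converged=False``) and the sweep continues.
    """
    k4_grid = np.asarray(k4_grid, dtype=float)
    if k4_grid.size == 0:
        raise ValueError("k4 grid must be nonempty")
    if np.any(np.diff(k4_grid) < 0):
        raise ValueError("k4 grid must be ascending")
    if engine not in ("exact", "zi"):
        raise ValueError(f"engine must be 'exact' or 'zi', got {engine!r}")

    base = base or KineticParameters.schlogl(k4_grid[0], V)
    records: list[SweepRecord] = []
    warm = None
    for k4 in k4_grid:
        params = replace(base, k4=float(k4), V=float(V))
        try:
            if engine == "exact":
                dist = stationary_distribution_exact(params)
            else:
                sol = solve_zi_closure(
                    params, psi=psi, init=warm if warm is not None else "auto"
                )
                warm = sol.lambdas
                dist = sol.dist
            records.append(_classify(dist, params, threshold, engine))
        except (ConvergenceError, ValueError, RuntimeError, ZeroDivisionError) as exc:
            logger.warning("sweep point V=%g k4=%g failed: %s", V, k4, exc)
            warm = None
            records.append(
                SweepRecord(
                    V=V, k4=float(k4), entropy=np.nan, n_modes=0,
                    peak_left=-1, peak_right=None, valley=None,
                    left_mass=np.nan, right_mass=np.nan,
                    peak_height_left=np.nan, peak_height_right=np.nan,
                    dominant="", solver=engine, converged=False, error=str(exc),
                )
            )
    return _records_to_frame(records)


def critical_k4(
    V: float,
    bracket: tuple[float, float],
    resolution: float,
    engine: str = "exact",
    *,
    base: KineticParameters | None = None,
    psi: int = 10,
) -> tuple[float, bool]:
    """k4 maximizing the NESS entropy over ``bracket``.

    Scans a grid of step ``resolution``, then refines the argmax by a
    bounded golden-section search inside one grid step on either side.
    Returns ``(k4_star, edge_warning)``; the warning flags an argmax at the
    bracket edge (bracket too small, or entropy monotone as for the linear
    network where no interior maximum exists).
    """
    lo, hi = bracket
    if hi < lo:
        raise ValueError("bracket must be (low, high)")
    grid = np.arange(lo, hi + 0.5 * resolution, resolution)
    df = entropy_sweep(V, grid, engine=engine, base=base, psi=psi)
    S = df["entropy"].to_numpy()
    if np.all(np.isnan(S)):
        raise RuntimeError("no sweep point converged in the bracket")
    i = int(np.nanargmax(S))
    edge = i == 0 or i == grid.size - 1
    if edge or grid.size < 3:
        logger.warning("entropy maximum at bracket edge k4=%g", grid[i])
        return float(grid[i]), True

    base_p = base or KineticParameters.schlogl(grid[i], V)

    def neg_entropy(k4: float) -> float:
        params = replace(base_p, k4=float(k4), V=float(V))
        if engine == "exact":
            dist = stationary_distribution_exact(params)
        else:
            dist = solve_zi_closure(params, psi=psi).dist
        return -entropy(dist)

    res = minimize_scalar(
        neg_entropy,
        bounds=(grid[i] - resolution, grid[i] + resolution),
        method="bounded",
        options={"xatol": resolution / 2.0},
    )
    return float(res.x), False


def bimodal_range(
    V: float,
    k4_grid,
    threshold: float = DEFAULT_MODE_THRESHOLD,
    engine: str = "exact",
    *,
    base: KineticParameters | None = None,
    psi: int = 10,
) -> BimodalRange:
    """Smallest and largest grid k4 with a two-mode stationary pmf."""
    df = entropy_sweep(V, k4_grid, engine=engine, base=base, psi=psi, threshold=threshold)
    bim = df[df["n_modes"] == 2]
    if bim.empty:
        return BimodalRange(V=V, k4_low=None, k4_high=None)
    return BimodalRange(
        V=V, k4_low=float(bim["k4"].min()), k4_high=float(bim["k4"].max())
    )


def collapse_profile(
    k4: float,
    V_grid,
    engine: str = "exact",
    *,
    base: KineticParameters | None = None,
    psi: int = 10,
    threshold: float = DEFAULT_MODE_THRESHOLD,
) -> pd.DataFrame:
    """Mode structure and basin masses along a volume grid at fixed k4.

    The returned frame carries a ``secondary_mass`` column (mass of the
    non-dominant basin, 0 where unimodal); the volume beyond which it falls
    below ``threshold`` is where bimodality is numerically destroyed.
    """
    V_grid = np.asarray(V_grid, dtype=float)
    if V_grid.size == 0:
        raise ValueError("volume grid must be nonempty")
    records = []
    warm = None
    for V in V_grid:
        params = (
            replace(base, k4=float(k4), V=float(V))
            if base is not None
            else KineticParameters.schlogl(float(k4), float(V))
        )
        try:
            if engine == "exact":
                dist = stationary_distribution_exact(params)
            else:
                sol = solve_zi_closure(
                    params, psi=psi, init=warm if warm is not None else "auto"
                )
                warm = sol.lambdas
                dist = sol.dist
            records.append(_classify(dist, params, threshold, engine))
        except (ConvergenceError, ValueError, RuntimeError, ZeroDivisionError) as exc:
            logger.warning("collapse point k4=%g V=%g failed: %s", k4, V, exc)
            warm = None
            records.append(
                SweepRecord(
                    V=float(V), k4=float(k4), entropy=np.nan, n_modes=0,
                    peak_left=-1, peak_right=None, valley=None,
                    left_mass=np.nan, right_mass=np.nan,
                    peak_height_left=np.nan, peak_height_right=np.nan,
                    dominant="", solver=engine, converged=False, error=str(exc),
                )
            )
    df = _records_to_frame(records)
    df["secondary_mass"] = np.where(
        df["n_modes"] == 2, np.minimum(df["left_mass"], df["right_mass"]), 0.0
    )
    return df
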
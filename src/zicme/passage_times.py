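"""Mode detection and mean first passage times on birth-death chains.

For a stationary bimodal pmf p with left peak a and right peak c, the mean
passage times between the peaks are the classical double sums

    T_ac = sum_{x=a}^{c-1}  1/(W+(x) p(x)) * sum_{y=0}^{x}    p(y)
    T_ca = sum_{x=a+1}^{c}  1/(W-(x) p(x)) * sum_{y=x}^{inf}  p(y)

(the infinite upper limit is truncated at xmax, harmless once the tail mass
is below ~1e-14).  The terms involve 1/p(x) at the valley, where p underflows
linearly — all sums are therefore assembled in log space from the stored
log-pmf, with an optional extended-precision (mpmath) mode for volumes where
even the log-stabilized valley terms lose significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .model import Distribution, KineticParameters, propensity_birth, propensity_death

__all__ = ["ModeStructure", "PassageTimes", "find_modes", "mean_passage_times"]

#: Basin mass below which a local maximum is not counted as a mode ("numerically
#: absent" secondary peaks; the concrete stand-in for "below computer accuracy").
DEFAULT_MODE_THRESHOLD = 1e-12


@dataclass(frozen=True)
class ModeStructure:
    """Peaks of a pmf after thresholding away numerically absent basins.

    ``a`` is the (leftmost) dominant-side peak state, ``c`` the right peak
    when bimodal (else None), ``valley`` the probability minimum between
    them.  ``n_modes`` counts surviving local maxima.
    """

    a: int
    c: int | None
    valley: int | None
    n_modes: int
    peak_heights: tuple[float, ...] = ()
    basin_masses: tuple[float, ...] = ()

    @property
    def bimodal(self) -> bool:
        return self.n_modes == 2


@dataclass(frozen=True)
class PassageTimes:
    """Mean first passage times between the two peaks of a bimodal pmf."""

    t_ac: float
    t_ca: float
    log_t_ac: float
    log_t_ca: float

    @property
    def ratio(self) -> float:
        """t_ca / t_ac, computed from the log values (overflow-safe)."""
        return float(np.exp(self.log_t_ca - self.log_t_ac))

    @property
    def log_ratio(self) -> float:
        return self.log_t_ca - self.log_t_ac


def _local_maxima(p: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus resolve to their leftmost
    index (documented, arbitrary tie-break)."""
    n = p.size
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and p[j + 1] == p[i]:
            j += 1
        left_ok = i == 0 or p[i - 1] < p[i]
        right_ok = j == n - 1 or p[j + 1] < p[i]
        if left_ok and right_ok and p[i] > 0:
            maxima.append(i)
        i = j + 1
    return maxima


def find_modes(
    dist: Distribution, threshold: float = DEFAULT_MODE_THRESHOLD
) -> ModeStructure:
    """Locate pmf modes, discarding peaks whose basin mass is below threshold.

    A basin is the probability mass between the minima flanking a peak.
    Peaks are pruned weakest-basin-first until all survivors exceed the
    threshold; with more than two survivors (not expected for this model
    class) the two with the largest basins define (a, c).
    """
    p = dist.p
    if not dist.is_normalized(1e-9):
        raise ValueError("distribution must be normalized")
    maxima = _local_maxima(p)
    if not maxima:  # fully flat pmf; call the leftmost state the mode
        return ModeStructure(a=0, c=None, valley=None, n_modes=1)

    def basin_mass(idx: list[int]) -> list[float]:
        # split points: argmin between consecutive peaks
        cuts = [0]
        for l, r in zip(idx[:-1], idx[1:]):
            cuts.append(l + int(np.argmin(p[l : r + 1])))
        cuts.append(p.size)
        return [float(p[lo:hi].sum()) for lo, hi in zip(cuts[:-1], cuts[1:])]

    while len(maxima) > 1:
        masses = basin_mass(maxima)
        weakest = int(np.argmin(masses))
        if masses[weakest] >= threshold:
            break
        maxima.pop(weakest)

    masses = basin_mass(maxima)
    if len(maxima) == 1:
        return ModeStructure(
            a=int(maxima[0]),
            c=None,
            valley=None,
            n_modes=1,
            peak_heights=(float(p[maxima[0]]),),
            basin_masses=(masses[0],),
        )
    # keep the two largest basins as (a, c)
    if len(maxima) > 2:
        order = np.argsort(masses)[-2:]
        keep = sorted(int(maxima[i]) for i in order)
    else:
        keep = [int(m) for m in maxima]
    a, c = keep
    valley = a + int(np.argmin(p[a : c + 1]))
    return ModeStructure(
        a=a,
        c=c,
        valley=valley,
        n_modes=len(maxima),
        peak_heights=(float(p[a]), float(p[c])),
        basin_masses=(float(p[:valley].sum()), float(p[valley + 1 :].sum())),
    )


def mean_passage_times(
    dist: Distribution,
    params: KineticParameters,
    modes: ModeStructure,
    precision: str = "double",
) -> PassageTimes:
    """Mean first passage times a->c and c->a from the stationary pmf.

    ``dist`` must be the stationary distribution of ``params`` (the double
    sums are exact only then).  ``precision="extended"`` re-evaluates the
    sums with 40-digit mpmath arithmetic for volumes where the valley terms
    exhaust double precision even in log space.

    Raises
    ------
    ValueError
        If ``modes`` is not bimodal or p vanishes exactly on the summation
        range (raise xmax or use extended precision).
    """
    if not modes.bimodal or modes.c is None:
        raise ValueError("mean passage times need a bimodal mode structure")
    a, c = modes.a, modes.c
    log_p = dist.log_p
    if np.any(np.isneginf(log_p[a : c + 1])):
        raise ValueError(
            "stationary pmf vanishes between the peaks; increase xmax or use "
            "a finer (extended-precision) stationary solution"
        )

    x_ac = np.arange(a, c)  # a .. c-1
    x_ca = np.arange(a + 1, c + 1)  # a+1 .. c
    log_wp = np.log(propensity_birth(x_ac, params))
    log_wm = np.log(propensity_death(x_ca, params))

    if precision == "extended":
        import mpmath as mp

        with mp.workdps(40):
            pm = [mp.e ** mp.mpf(float(v)) for v in log_p]
            F = []
            run = mp.mpf(0)
            for v in pm:
                run += v
                F.append(run)
            G = []
            run = mp.mpf(0)
            for v in reversed(pm):
                run += v
                G.append(run)
            G = G[::-1]
            t_ac = sum(F[x] / (mp.e ** mp.mpf(float(lw)) * pm[x]) for x, lw in zip(x_ac, log_wp))
            t_ca = sum(G[x] / (mp.e ** mp.mpf(float(lw)) * pm[x]) for x, lw in zip(x_ca, log_wm))
            return PassageTimes(
                t_ac=float(t_ac),
                t_ca=float(t_ca),
                log_t_ac=float(mp.log(t_ac)),
                log_t_ca=float(mp.log(t_ca)),
            )
    elif precision != "double":
        raise ValueError(f"precision must be 'double' or 'extended', got {precision!r}")

    # log-cumulative masses: F(x) = sum_{y<=x} p, G(x) = sum_{y>=x} p
    log_F = np.logaddexp.accumulate(log_p)
    log_G = np.logaddexp.accumulate(log_p[::-1])[::-1]

    terms_ac = log_F[x_ac] - log_wp - log_p[x_ac]
    terms_ca = log_G[x_ca] - log_wm - log_p[x_ca]
    log_t_ac = float(logsumexp(terms_ac))
    log_t_ca = float(logsumexp(terms_ca))
    with np.errstate(over="ignore"):
        return PassageTimes(
            t_ac=float(np.exp(log_t_ac)),
            t_ca=float(np.exp(log_t_ca)),
            log_t_ac=log_t_ac,
            log_t_ca=log_t_ca,
        )
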
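import numpy as np
import pytest

from zicme import KineticParameters


@pytest.fixture
def schlogl():
    """Reference bistable parameter set at the entropy-critical k4, V=1."""
    return KineticParameters.schlogl(4.21e4, 1.0)


@pytest.fixture
def linear_params():
    """Pure birth-death (k1=k2=0): stationary law is Poisson(k4 V / k3)."""
    return KineticParameters(k1=0.0, k2=0.0, k3=3150.0, k4=1e4, V=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20180906)


def brute_force_moment_rhs(p, params, m):
    """Independent oracle: d{X_m}/dt as a direct expectation over the CME
    generator, E[(Delta ff_m) W+] + E[(Delta' ff_m) W-], by plain summation.
    """
    from zicme.model import propensity_birth, propensity_death
    from zicme.moment_system import falling_factorial_values

    X = np.arange(p.size)
    ffm = falling_factorial_values(X, m)
    ff_up = falling_factorial_values(X + 1, m)
    ff_dn = falling_factorial_values(X - 1, m)
    wp = propensity_birth(X, params)
    wm = propensity_death(X, params)
    return float(np.sum(p * (wp * (ff_up - ffm) + wm * (ff_dn - ffm))))


def mfpt_absorbing_oracle(log_p, params, source, target, xmax):
    """Independent oracle: mean hitting time of `target` from `source` for
    the birth-death chain — the absorbing-state tridiagonal linear system
    W+(x)(tau(x+1)-tau(x)) + W-(x)(tau(x-1)-tau(x)) = -1, tau(target)=0,
    reflecting at 0 and xmax, solved by exact forward/backward elimination
    of the per-step hitting times (numerically stable where a generic
    banded factorization of the same system loses all precision at large
    mean passage times).  Uses only the propensities, never the pmf.
    """
    from zicme.model import propensity_birth, propensity_death

    X = np.arange(xmax + 1)
    wp = propensity_birth(X, params).astype(float)
    wm = propensity_death(X, params).astype(float)
    if source < target:
        # g(x) = E_x[T_{x+1}]; eliminating upward from the reflecting 0
        g = np.zeros(xmax + 1)
        g[0] = 1.0 / wp[0]
        for x in range(1, target):
            g[x] = 1.0 / wp[x] + wm[x] / wp[x] * g[x - 1]
        return float(g[source:target].sum())
    # h(x) = E_x[T_{x-1}]; eliminating downward from the reflecting xmax
    h = np.zeros(xmax + 1)
    h[xmax] = 1.0 / wm[xmax]
    for x in range(xmax - 1, target, -1):
        h[x] = 1.0 / wm[x] + wp[x] / wm[x] * h[x + 1]
    return float(h[target + 1 : source + 1].sum())
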
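import numpy as np
import pytest

from zicme import (
    KineticParameters,
    LagrangeMultipliers,
    SolverOptions,
    build_moment_system,
    entropy,
    factorial_moment,
    make_fixture_pmf,
    maxent_pmf,
    solve_zi_closure,
    stationary_distribution_exact,
    steady_state_residual,
)
from zicme.model import propensity_birth, propensity_death


class TestMaxEntPmf:
    def test_order_zero_multiplier_gives_uniform(self):
        n = 8
        d = maxent_pmf(LagrangeMultipliers((np.log(n),)), xmax=n - 1)
        assert d.p == pytest.approx(np.full(n, 1.0 / n))

    def test_linear_exponent_gives_geometric(self):
        t = 0.3
        d = maxent_pmf(LagrangeMultipliers((0.0, t)), xmax=120)
        ref = make_fixture_pmf("geometric", ratio=np.exp(-t), xmax=120)
        assert 0.5 * np.abs(d.p - ref.p).sum() < 1e-14

    def test_divergent_tail_raises(self):
        # negative linear multiplier: exp(+t X) diverges on the lattice
        with pytest.raises(ValueError):
            maxent_pmf(LagrangeMultipliers((0.0, -0.5)), xmax=50)

    def test_moment_fitted_family_approximates_poisson(self):
        # solve the closure for the linear network whose solution is exactly
        # Poisson in moments; the induced pmf must be close in TV
        params = KineticParameters(0.0, 0.0, 3150.0, 3150.0 * 10, 1.0)
        sol = solve_zi_closure(params, psi=10)
        ref = make_fixture_pmf("poisson", mean=10.0, xmax=sol.dist.xmax)
        assert 0.5 * np.abs(sol.dist.p - ref.p).sum() < 0.01


class TestEntropy:
    def test_delta_has_zero_entropy(self):
        assert entropy(make_fixture_pmf("delta", at=7)) == 0.0

    def test_two_equal_masses_give_ln_two(self):
        d = make_fixture_pmf("two_point", a=2, b=9, w=0.5)
        assert entropy(d) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_uniform_entropy_is_log_cardinality(self):
        assert entropy(make_fixture_pmf("uniform", n=10)) == pytest.approx(
            np.log(10.0), abs=1e-12
        )

    def test_unnormalized_input_rejected(self):
        from zicme.model import Distribution

        bad = Distribution(np.log([0.5, 0.2]), normalized=True)
        with pytest.raises(ValueError):
            entropy(bad)


class TestSteadyStateResidual:
    def test_zero_rates_give_zero_residual(self):
        params = KineticParameters(0.0, 0.0, 0.0, 0.0, 1.0)
        system = build_moment_system(params, 2)
        lam = LagrangeMultipliers((0.0, 0.1, 0.05))
        r = steady_state_residual(lam, system, xmax=40)
        assert r == pytest.approx(np.zeros(2))

    def test_first_component_is_the_net_birth_death_balance(self, schlogl):
        # residual row 1 must equal (k2/V){X2} + k4 V - (k1/V^2){X3} - k3{X}
        # computed by direct summation over the induced pmf
        lam = LagrangeMultipliers((0.0, 0.02, 0.001))
        system = build_moment_system(schlogl, 2)
        r = steady_state_residual(lam, system, xmax=300)
        d = maxent_pmf(lam, xmax=300)
        X = d.support
        direct = float(
            np.sum(d.p * (propensity_birth(X, schlogl) - propensity_death(X, schlogl)))
        )
        assert r[0] == pytest.approx(direct, rel=1e-12, abs=1e-9 * schlogl.k4)

    def test_psi_mismatch_rejected(self, schlogl):
        system = build_moment_system(schlogl, 4)
        with pytest.raises(ValueError):
            steady_state_residual(LagrangeMultipliers((0.0, 1.0)), system, 50)


class TestSolver:
    def test_invalid_closure_order_rejected(self, schlogl):
        with pytest.raises(ValueError):
            solve_zi_closure(schlogl, psi=0)

    def test_odd_order_warns(self, linear_params):
        with pytest.warns(UserWarning, match="odd closure order"):
            solve_zi_closure(linear_params, psi=3)

    def test_linear_network_reproduces_poisson_moments(self, linear_params):
        # closed form: {X_m} = (k4 V / k3)^m
        sol = solve_zi_closure(linear_params, psi=4)
        nu = linear_params.k4 * linear_params.V / linear_params.k3
        assert sol.converged
        for m in range(1, 5):
            assert sol.moments[m] == pytest.approx(nu**m, rel=1e-6)

    def test_entropy_reported_consistently_with_pmf(self, schlogl):
        sol = solve_zi_closure(schlogl, psi=10)
        assert sol.entropy == pytest.approx(entropy(sol.dist), abs=1e-12)

    def test_moments_reported_consistently_with_pmf(self, schlogl):
        sol = solve_zi_closure(schlogl, psi=10)
        for m in (1, 2, 5, 10):
            assert sol.moments[m] == pytest.approx(
                factorial_moment(sol.dist, m), rel=1e-9
            )

    def test_initial_condition_independence(self, schlogl):
        # delta-like inits at each stable attractor must reach the same
        # stationary solution (ergodicity of the closure fixed point);
        # pin xmax so both runs share one lattice, and tighten the residual
        # so multiplier error stays below the TV comparison scale
        opts = SolverOptions(xmax=330, tol=1e-12)
        lo = solve_zi_closure(schlogl, psi=10, init=("delta", 26.4), opts=opts)
        hi = solve_zi_closure(schlogl, psi=10, init=("delta", 103.6), opts=opts)
        assert lo.converged and hi.converged
        assert 0.5 * np.abs(lo.dist.p - hi.dist.p).sum() < 1e-8

    def test_solution_locally_maximizes_entropy_on_constraint_manifold(
        self, schlogl, rng
    ):
        # among pmfs sharing the solution's first psi factorial moments,
        # random in-manifold perturbations must not raise the entropy
        from zicme.moment_system import falling_factorial_values

        psi = 6
        sol = solve_zi_closure(schlogl, psi=psi)
        p = sol.dist.p
        X = sol.dist.support
        # constraint matrix: normalization + psi factorial moments
        C = np.vstack(
            [np.ones_like(X, dtype=float)]
            + [falling_factorial_values(X, m) for m in range(1, psi + 1)]
        )
        # null-space directions of the active constraints, restricted to
        # well-populated states so the perturbation stays far from p = 0
        # (the entropy gradient diverges at the boundary)
        mask = p > 1e-4
        Cm = C[:, mask]
        _, _, Vt = np.linalg.svd(Cm, full_matrices=True)
        null = Vt[Cm.shape[0]:]
        S0 = entropy(sol.dist)
        from zicme.model import Distribution

        p_floor = p[mask].min()
        for _ in range(10):
            z = rng.standard_normal(null.shape[0])
            direction = z @ null
            eps = 1e-3 * p_floor / np.abs(direction).max()
            q = p.copy()
            q[mask] = p[mask] + eps * direction
            q /= q.sum()
            assert entropy(Distribution.from_p(q)) <= S0 + 1e-9

    def test_bimodal_solution_matches_exact_oracle_shape(self):
        # at the critical point the closure reproduces the exact pmf to the
        # documented psi=10 accuracy (a few 1e-3 in TV)
        params = KineticParameters.schlogl(4.21e4, 1.0)
        sol = solve_zi_closure(params, psi=10)
        ex = stationary_distribution_exact(params, xmax=sol.xmax)
        assert 0.5 * np.abs(sol.dist.p - ex.p).sum() < 5e-3
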
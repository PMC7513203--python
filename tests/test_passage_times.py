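import numpy as np
import pytest

from conftest import mfpt_absorbing_oracle
from zicme import (
    KineticParameters,
    find_attractors,
    find_modes,
    make_fixture_pmf,
    mean_passage_times,
    stationary_distribution_exact,
)
from zicme.model import Distribution
from zicme.passage_times import ModeStructure


class TestFindModes:
    def test_constructed_two_peak_pmf(self):
        p = np.array([0.0, 0.1, 0.2, 0.3, 0.1, 0.02, 0.03, 0.05, 0.1, 0.2, 0.05, 0.0])
        p /= p.sum()
        m = find_modes(Distribution.from_p(p))
        assert (m.a, m.c, m.n_modes) == (3, 9, 2)
        assert m.valley == 5
        assert m.a < m.valley < m.c

    def test_decreasing_geometric_is_unimodal_at_origin(self):
        m = find_modes(make_fixture_pmf("geometric", ratio=0.5, xmax=40))
        assert (m.n_modes, m.a, m.c) == (1, 0, None)

    def test_plateau_resolves_to_leftmost_index(self):
        p = np.array([0.1, 0.3, 0.3, 0.3, 0.1])
        m = find_modes(Distribution.from_p(p))
        assert (m.n_modes, m.a) == (1, 1)

    def test_threshold_prunes_numerically_absent_peak(self):
        p = np.array([0.1, 0.6, 0.1, 1e-15, 2e-15, 1e-16])
        m_loose = find_modes(Distribution.from_p(p), threshold=1e-18)
        m_tight = find_modes(Distribution.from_p(p), threshold=1e-12)
        assert m_loose.n_modes == 2
        assert m_tight.n_modes == 1

    def test_exact_critical_distribution_peaks_near_attractors(self):
        params = KineticParameters.schlogl(4.21e4, 1.0)
        m = find_modes(stationary_distribution_exact(params))
        att = find_attractors(params)
        lo, hi = att.stable_roots
        assert m.n_modes == 2
        # O(1)-count discrete shift; measured within 8 counts at V=1
        assert abs(m.a - params.V * lo) <= 8
        assert abs(m.c - params.V * hi) <= 8


class TestMeanPassageTimes:
    def test_requires_bimodal_modes(self, schlogl):
        d = stationary_distribution_exact(schlogl)
        uni = ModeStructure(a=10, c=None, valley=None, n_modes=1)
        with pytest.raises(ValueError):
            mean_passage_times(d, schlogl, uni)

    def test_mirror_symmetric_chain_has_equal_times(self):
        # formula-level reflection identity: on a chain with constant rates
        # and flat stationary pmf (W+(x) = W-(2M - x) = c), the two double
        # sums coincide for peaks placed symmetrically about the midpoint
        M, c = 10, 3.0
        p = np.full(2 * M + 1, 1.0 / (2 * M + 1))
        a, cc = 2, 2 * M - 2
        F = np.cumsum(p)
        G = np.cumsum(p[::-1])[::-1]
        t_ac = sum(F[x] / (c * p[x]) for x in range(a, cc))
        t_ca = sum(G[x] / (c * p[x]) for x in range(a + 1, cc + 1))
        assert t_ac == pytest.approx(t_ca, rel=1e-12)

    def test_hand_evaluated_four_state_chain(self):
        # chain on 0..3 with W+(x)=k4=2 and W-(x)=k3*x, k3=1; stationary pmf
        # by the product formula: p(x) ~ 2^x / x!
        params = KineticParameters(0.0, 0.0, 1.0, 2.0, 1.0)
        w = np.array([1.0, 2.0, 2.0, 8.0 / 6.0])
        p = w / w.sum()
        d = Distribution.from_p(p)
        modes = ModeStructure(a=0, c=3, valley=1, n_modes=2)
        pt = mean_passage_times(d, params, modes)
        # hand arithmetic of the double sums:
        # T_03 = sum_{x=0..2} F(x)/(W+(x) p(x)); W+ = 2 everywhere
        F = np.cumsum(p)
        G = np.cumsum(p[::-1])[::-1]
        t03 = F[0] / (2 * p[0]) + F[1] / (2 * p[1]) + F[2] / (2 * p[2])
        # T_30 = sum_{x=1..3} G(x)/(W-(x) p(x)); W-(x) = x
        t30 = G[1] / (1 * p[1]) + G[2] / (2 * p[2]) + G[3] / (3 * p[3])
        assert pt.t_ac == pytest.approx(t03, rel=1e-12)
        assert pt.t_ca == pytest.approx(t30, rel=1e-12)

    @pytest.mark.parametrize("V", [1.0, 4.0, 10.0, 16.0])
    def test_matches_absorbing_chain_linear_solve(self, V):
        # the summation formula and the fundamental-matrix first-passage
        # solve are algebraically identical for birth-death chains
        params = KineticParameters.schlogl(4e4, V)
        d = stationary_distribution_exact(params)
        m = find_modes(d)
        assert m.bimodal
        pt = mean_passage_times(d, params, m)
        t_ac_ref = mfpt_absorbing_oracle(d.log_p, params, m.a, m.c, d.xmax)
        t_ca_ref = mfpt_absorbing_oracle(d.log_p, params, m.c, m.a, d.xmax)
        assert pt.t_ac == pytest.approx(t_ac_ref, rel=1e-6)
        assert pt.t_ca == pytest.approx(t_ca_ref, rel=1e-6)

    def test_extended_precision_agrees_with_double(self):
        params = KineticParameters.schlogl(4e4, 3.0)
        d = stationary_distribution_exact(params)
        m = find_modes(d)
        pt_d = mean_passage_times(d, params, m, precision="double")
        pt_e = mean_passage_times(d, params, m, precision="extended")
        assert pt_e.t_ac == pytest.approx(pt_d.t_ac, rel=1e-10)
        assert pt_e.t_ca == pytest.approx(pt_d.t_ca, rel=1e-10)

    def test_invariant_to_truncation_once_tail_negligible(self):
        params = KineticParameters.schlogl(4e4, 2.0)
        d1 = stationary_distribution_exact(params)
        d2 = stationary_distribution_exact(params, xmax=d1.xmax + 200)
        m1, m2 = find_modes(d1), find_modes(d2)
        p1 = mean_passage_times(d1, params, m1)
        p2 = mean_passage_times(d2, params, m2)
        assert p1.t_ac == pytest.approx(p2.t_ac, rel=1e-12)
        assert p1.t_ca == pytest.approx(p2.t_ca, rel=1e-12)

    def test_ratio_grows_loglinearly_with_volume(self):
        # the right->left over left->right time ratio grows exponentially in
        # V; its log is increasing and near-linear
        logs = []
        for V in range(1, 13):
            params = KineticParameters.schlogl(4e4, float(V))
            d = stationary_distribution_exact(params)
            m = find_modes(d)
            logs.append(mean_passage_times(d, params, m).log_ratio)
        logs = np.array(logs)
        assert np.all(np.diff(logs) > 0)
        Vs = np.arange(1, 13, dtype=float)
        r = np.corrcoef(Vs, logs)[0, 1]
        assert r**2 > 0.95
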
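"""Transfer curves, currents and drift of the mean-field equations."""

import numpy as np
import pytest
from scipy.optimize import bisect

import dmfsim as d
from dmfsim.model import excitatory_rate, inhibitory_rate


class TestTransferRate:
    def test_threshold_limit_is_inverse_shape(self, params):
        # at I = Ithr the removable singularity evaluates to 1/dE = 6.25 Hz
        assert excitatory_rate(params.IthrE, params) == pytest.approx(6.25)

    def test_matches_independent_bisection_inverse(self, params):
        # find the current whose rate is 3.4 Hz with a brute bisection on
        # the raw formula, then check the forward map
        f = lambda I: (params.gE * (I - params.IthrE)
                       / (1 - np.exp(-params.dE * params.gE * (I - params.IthrE)))
                       - 3.4)
        I_star = bisect(f, 0.2, 0.4029, xtol=1e-12)
        assert I_star == pytest.approx(0.3805, abs=5e-4)
        assert excitatory_rate(I_star, params) == pytest.approx(3.4, abs=1e-9)

    def test_asymptotically_linear(self, params):
        # far above threshold the exponential term is negligible
        assert excitatory_rate(1.0, params) == pytest.approx(
            params.gE * (1.0 - params.IthrE), rel=1e-10)
        assert excitatory_rate(1.0, params) == pytest.approx(185.07, abs=1e-2)

    def test_continuous_across_threshold(self, params):
        lo = excitatory_rate(params.IthrE - 1e-9, params)
        hi = excitatory_rate(params.IthrE + 1e-9, params)
        assert abs(lo - 1 / params.dE) < 1e-4
        assert abs(hi - 1 / params.dE) < 1e-4

    def test_monotone_nonnegative(self, params):
        I = np.linspace(-0.5, 1.5, 2001)
        r = excitatory_rate(I, params)
        assert np.all(r >= 0)
        assert np.all(np.diff(r) >= 0)

    def test_nonfinite_current_rejected(self, params):
        with pytest.raises(FloatingPointError):
            excitatory_rate(np.nan, params)
        with pytest.raises(ValueError):
            d.transfer_rate(0.4, gain=-1.0, threshold=0.4, shape=0.16)


class TestNodeStrength:
    def test_row_sums(self):
        c = d.Connectome(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert d.node_strength(c).tolist() == [1.0, 1.0]

    def test_halving(self):
        c = d.Connectome(np.array([[0, 2, 0], [2, 0, 4], [0, 4, 0.0]]))
        assert d.node_strength(c, halve=True).tolist() == [1.0, 3.0, 2.0]

    def test_empty_graph(self):
        c = d.Connectome(np.zeros((4, 4)))
        assert np.all(d.node_strength(c) == 0)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            d.Connectome(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            d.Connectome(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            d.Connectome(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestSynapticCurrents:
    def test_baseline_only(self, params):
        conn = d.Connectome(np.zeros((1, 1)))
        state = d.StateVector(S_E=[0.0], S_I=[0.0])
        I_E, I_I = d.synaptic_currents(state, conn,
                                       d.CouplingConfig(G=0.0, J=[1.3]), params)
        assert I_E[0] == pytest.approx(0.382)
        assert I_I[0] == pytest.approx(0.2674)

    def test_consistent_with_moment_solution(self, params):
        # at the analytic uncoupled moment point the excitatory current
        # reproduces the inverse-transfer value
        m = d.solve_uncoupled_moments(params)
        J_unc = (params.W_E * params.I0
                 + params.w_plus * params.J_NMDA * m.E_SE - m.E_IE) / m.E_SI
        conn = d.Connectome(np.zeros((1, 1)))
        state = d.StateVector(S_E=[m.E_SE], S_I=[m.E_SI])
        I_E, _ = d.synaptic_currents(state, conn,
                                     d.CouplingConfig(G=0.0, J=[J_unc]), params)
        assert I_E[0] == pytest.approx(m.E_IE, abs=1e-12)
        assert I_E[0] == pytest.approx(0.3805, abs=5e-4)

    def test_two_region_coupling(self, params):
        conn = d.Connectome(np.array([[0.0, 1.0], [1.0, 0.0]]))
        state = d.StateVector(S_E=[0.1, 0.2], S_I=[0.0, 0.0])
        I_E, _ = d.synaptic_currents(state, conn,
                                     d.CouplingConfig(G=2.0, J=[1.0, 1.0]),
                                     params)
        # 0.382 + 1.4*0.15*0.1 + 2*0.15*0.2
        assert I_E[0] == pytest.approx(0.463)

    def test_uncoupled_equals_block_independent(self, params):
        # with G=0 a permutation of regions permutes the currents exactly
        rng = np.random.default_rng(0)
        n = 6
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        conn = d.Connectome(w)
        S_E, S_I = rng.uniform(0, 0.5, n), rng.uniform(0, 0.1, n)
        J = rng.uniform(0.5, 2, n)
        I_E, I_I = d.synaptic_currents(d.StateVector(S_E, S_I), conn,
                                       d.CouplingConfig(G=0.0, J=J), params)
        perm = rng.permutation(n)
        conn_p = d.Connectome(w[np.ix_(perm, perm)])
        I_Ep, I_Ip = d.synaptic_currents(
            d.StateVector(S_E[perm], S_I[perm]), conn_p,
            d.CouplingConfig(G=0.0, J=J[perm]), params)
        np.testing.assert_allclose(I_Ep, I_E[perm], rtol=0, atol=0)
        np.testing.assert_allclose(I_Ip, I_I[perm], rtol=0, atol=0)

    def test_dimension_mismatch(self, params):
        conn = d.Connectome(np.zeros((2, 2)))
        state = d.StateVector(S_E=[0.1], S_I=[0.1])
        with pytest.raises(ValueError):
            d.synaptic_currents(state, conn, d.CouplingConfig(G=0.0, J=[1.0]),
                                params)


class TestDrift:
    def test_origin_fixed_point(self, params):
        state = d.StateVector(S_E=[0.0], S_I=[0.0])
        dS_E, dS_I = d.drift(state, np.array([0.0]), np.array([0.0]), params)
        assert dS_E[0] == 0.0
        assert dS_I[0] == 0.0

    def test_gating_fixed_point_at_target_rate(self, params):
        # S* = gamma*tau*r/(1+gamma*tau*r) zeroes the excitatory drift
        r = 3.4
        S = d.expected_gating(r, params)
        dS_E, _ = d.drift(d.StateVector(S_E=[S], S_I=[0.0]),
                          np.array([r]), np.array([0.0]), params)
        assert abs(dS_E[0]) < 1e-6

    def test_inhibitory_balance(self, params):
        # S_I = tau_GABA * r_I zeroes the inhibitory drift
        _, dS_I = d.drift(d.StateVector(S_E=[0.0], S_I=[0.034]),
                          np.array([0.0]), np.array([3.4]), params)
        assert dS_I[0] == pytest.approx(0.0, abs=1e-12)

    def test_drift_norm_small_at_moment_point(self, params):
        m = d.solve_uncoupled_moments(params)
        dS_E, dS_I = d.drift(d.StateVector(S_E=[m.E_SE], S_I=[m.E_SI]),
                             np.array([m.E_rE]), np.array([m.E_rI]), params)
        assert np.hypot(dS_E[0], dS_I[0]) < 1e-6
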
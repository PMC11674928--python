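"""Integration pipeline: determinism, streaming contract, hemodynamics."""

import numpy as np
import pytest

import dmfsim as d
from dmfsim.integrate import RateStream


@pytest.fixture(scope="module")
def small_conn():
    rng = np.random.default_rng(21)
    w = rng.uniform(0, 0.2, (5, 5))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0)
    return d.Connectome(w)


class TestConfigValidation:
    def test_step_divisibility(self):
        with pytest.raises(ValueError):
            d.IntegrationConfig(duration=20, dt_dmf=3e-4, dt_bk=1e-3)
        with pytest.raises(ValueError):
            d.IntegrationConfig(duration=20, TR=2.5, dt_bk=1e-3 * 3)
        with pytest.raises(ValueError):
            d.IntegrationConfig(duration=5.0, transient_discard=10.0)

    def test_bold_column_count(self):
        cfg = d.IntegrationConfig(duration=130.0)
        assert cfg.n_tr_samples == 60


class TestDeterminismAndNoise:
    def test_same_seed_identical_bold(self, params, hemo, small_conn):
        coup = d.CouplingConfig(G=0.3, J=np.ones(5))
        cfg = d.IntegrationConfig(duration=30.0, transient_discard=5.0, seed=5)
        a = d.run_simulation(params, hemo, small_conn, coup, cfg)
        b = d.run_simulation(params, hemo, small_conn, coup, cfg)
        np.testing.assert_array_equal(a.bold, b.bold)
        c = d.run_simulation(params, hemo, small_conn, coup,
                             d.IntegrationConfig(duration=30.0,
                                                 transient_discard=5.0, seed=6))
        assert not np.array_equal(a.bold, c.bold)

    def test_one_step_increment_variance(self, params):
        # Euler-Maruyama contract: far from the gating bounds the one-step
        # increment variance is sigma^2 * (dt / 1 ms) under the per-sqrt-ms
        # noise convention
        conn = d.Connectome(np.zeros((1, 1)))
        cfg = d.IntegrationConfig(duration=20.0, transient_discard=1.0,
                                  seed=9, buffer_capacity=200_000)
        stream = d.simulate_rates(params, conn,
                                  d.CouplingConfig(G=0.0, J=[1.0]), cfg)
        traj = []
        for _, rates in stream:
            traj.append(stream._gate[:rates.shape[0]].copy())
        g = np.concatenate(traj)[:, 0]
        inc = np.diff(g[5000:])
        expected = params.sigma ** 2 * (cfg.dt_dmf * 1000.0)
        # drift contributes ~dt^2 to the variance; allow 10%
        assert np.var(inc) == pytest.approx(expected, rel=0.1)

    def test_sigma_zero_converges_to_drift_fixed_point(self, hemo):
        from scipy.optimize import brentq
        from dmfsim.model import excitatory_rate, inhibitory_rate
        par = d.DMFParameters(sigma=1e-300)
        conn = d.Connectome(np.zeros((1, 1)))
        cfg = d.IntegrationConfig(duration=40.0, transient_discard=30.0, seed=1)
        stream = d.simulate_rates(par, conn, d.CouplingConfig(G=0.0, J=[1.0]),
                                  cfg)
        for _ in stream:
            pass
        S_E, S_I = stream.S_E[0], stream.S_I[0]
        rE = excitatory_rate(par.W_E * par.I0 + par.w_plus * par.J_NMDA * S_E
                             - S_I, par)
        dS_E = -S_E / par.tau_NMDA + (1 - S_E) * par.gamma_kin * rE
        assert abs(dS_E) < 1e-8
        # independent root-finder on the uncoupled drift
        def fp(r):
            S = par.gamma_kin * par.tau_NMDA * r / (1 + par.gamma_kin * par.tau_NMDA * r)
            SI = brentq(lambda x: par.tau_GABA * inhibitory_rate(
                par.W_I * par.I0 + par.J_NMDA * S - x, par) - x, 0, 1)
            return excitatory_rate(par.W_E * par.I0 + par.w_plus * par.J_NMDA * S
                                   - SI, par) - r
        r_star = brentq(fp, 0.1, 10)
        assert rE == pytest.approx(r_star, abs=1e-6)


class TestStreamingContract:
    def test_streaming_vs_monolithic_equivalence(self, params, hemo, small_conn):
        coup = d.CouplingConfig(G=0.3, J=np.ones(5))
        small = d.IntegrationConfig(duration=30.0, transient_discard=5.0,
                                    seed=5, buffer_capacity=4000)
        big = d.IntegrationConfig(duration=30.0, transient_discard=5.0,
                                  seed=5, buffer_capacity=400_000)
        a = d.run_simulation(params, hemo, small_conn, coup, small)
        b = d.run_simulation(params, hemo, small_conn, coup, big)
        np.testing.assert_array_equal(a.bold, b.bold)
        # summary accumulators add in different partial orders per block,
        # so they agree to roundoff rather than bit-exactly
        np.testing.assert_allclose(a.rate_mean, b.rate_mean, atol=1e-10)

    def test_live_samples_flat_in_duration(self, params, hemo, small_conn):
        coup = d.CouplingConfig(G=0.0, J=np.ones(5))
        peaks = []
        for dur in (15.0, 30.0):
            cfg = d.IntegrationConfig(duration=dur, transient_discard=5.0,
                                      seed=2, buffer_capacity=5000)
            res = d.run_simulation(params, hemo, small_conn, coup, cfg)
            peaks.append(res.peak_buffered_samples)
            assert res.peak_buffered_samples <= 2 * 5000 * 5
        assert peaks[0] == peaks[1]

    def test_block_views_never_exceed_capacity(self, params, small_conn):
        cfg = d.IntegrationConfig(duration=12.0, transient_discard=2.0,
                                  seed=3, buffer_capacity=3000)
        stream = d.simulate_rates(params, small_conn,
                                  d.CouplingConfig(G=0.0, J=np.ones(5)), cfg)
        for _, rates in stream:
            assert rates.shape[0] <= 3000


class TestBalloonWindkessel:
    def test_rest_state_gives_zero_bold(self, hemo):
        # every parenthesis of the BOLD readout vanishes at q = v = 1
        q = v = np.ones(3)
        bold = hemo.V0 * (hemo.k1 * (1 - q) + hemo.k2 * (1 - q / v)
                          + hemo.k3 * (1 - v))
        np.testing.assert_array_equal(bold, 0.0)

    def test_steady_inflow_matches_algebra(self, hemo):
        # constant rate r: at steady state s=0 and f = 1 + (0.5 r + 3)/gamma
        cfg = d.IntegrationConfig(duration=300.0, transient_discard=0.0,
                                  TR=2.0)
        r = 3.0
        rates = np.full((300_000, 1), r)
        bold = d.balloon_windkessel(rates, hemo, cfg)
        assert bold.shape == (1, 150)
        from dmfsim.integrate import HemodynamicState, _kernels
        # re-run retaining final state
        state = HemodynamicState.resting(1)
        v_out = np.empty((300_001, 1)); q_out = np.empty((300_001, 1))
        _kernels.bk_consume(rates, state.s, state.f, state.v, state.q,
                            hemo.kappa, hemo.gamma_BW, hemo.tau_BW,
                            1 / hemo.alpha_BW, hemo.rho, cfg.dt_bk, 0,
                            cfg.bk_steps_per_tr, v_out, q_out)
        f_star = 1 + (0.5 * r + 3) / hemo.gamma_BW
        assert state.f[0] == pytest.approx(f_star, rel=1e-3)
        assert abs(state.s[0]) < 1e-3

    def test_column_count_after_transient(self, params, hemo):
        conn = d.Connectome(np.zeros((1, 1)))
        cfg = d.IntegrationConfig(duration=130.0, seed=0)
        res = d.run_simulation(params, hemo, conn,
                               d.CouplingConfig(G=0.0, J=[1.0]), cfg)
        assert res.bold.shape == (1, 60)


class TestDivergence:
    def test_hyperexcitation_reported_with_context(self, params, hemo,
                                                   tiny_connectome):
        # absurdly high coupling with no feedback inhibition must blow up
        coup = d.CouplingConfig(G=50.0, J=np.zeros(20))
        cfg = d.IntegrationConfig(duration=30.0, transient_discard=5.0, seed=1)
        with pytest.raises(d.DivergenceError) as exc:
            d.run_simulation(params, hemo, tiny_connectome, coup, cfg)
        assert exc.value.max_rate is not None
        assert exc.value.max_rate > 20
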
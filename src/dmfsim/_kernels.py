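"""Numba-compiled inner loops for the Euler-Maruyama and hemodynamic steps.

Kept free of Python objects: plain float64 arrays and scalars in, arrays
mutated in place. fastmath is off so streams are bit-reproducible across
runs on the same platform.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SINGULARITY_BAND = 1e-6


@njit(cache=True, fastmath=False)
def _fi_curve(x, shape):
    # x = gain*(I - Ithr); removable singularity at x = 0
    if abs(x) < _SINGULARITY_BAND:
        return (1.0 + shape * x / 2.0) / shape
    return x / (1.0 - np.exp(-shape * x))


@njit(cache=True, fastmath=False)
def dmf_block(S_E, S_I, W, G, J,
              I0, W_E, W_I, w_plus, J_NMDA,
              gE, gI, IthrE, IthrI, dE, dI,
              gamma_kin, tau_NMDA, tau_GABA,
              dt, sigma_sqrt_dt,
              noise_E, noise_I, rates_out, gating_out):
    """Integrate `steps` Euler-Maruyama steps, recording excitatory rates.

    S_E, S_I are updated in place; rates_out[t, n] receives r_E at step t
    computed from the pre-update state, gating_out[t, n] receives S_E
    before the update (so averages of the two series align).
    """
    steps = noise_E.shape[0]
    N = S_E.shape[0]
    dS_E = np.empty(N)
    dS_I = np.empty(N)
    for t in range(steps):
        for n in range(N):
            acc = 0.0
            for p in range(N):
                acc += W[n, p] * S_E[p]
            I_E = (W_E * I0 + w_plus * J_NMDA * S_E[n]
                   + G * J_NMDA * acc - J[n] * S_I[n])
            I_I = W_I * I0 + J_NMDA * S_E[n] - S_I[n]
            r_E = _fi_curve(gE * (I_E - IthrE), dE)
            r_I = _fi_curve(gI * (I_I - IthrI), dI)
            rates_out[t, n] = r_E
            gating_out[t, n] = S_E[n]
            dS_E[n] = (-S_E[n] / tau_NMDA
                       + (1.0 - S_E[n]) * gamma_kin * r_E)
            dS_I[n] = -S_I[n] / tau_GABA + r_I
        for n in range(N):
            se = S_E[n] + dt * dS_E[n] + sigma_sqrt_dt * noise_E[t, n]
            si = S_I[n] + dt * dS_I[n] + sigma_sqrt_dt * noise_I[t, n]
            S_E[n] = min(max(se, 0.0), 1.0)
            S_I[n] = min(max(si, 0.0), 1.0)


@njit(cache=True, fastmath=False)
def bk_consume(rates_ms, s, f, v, q,
               kappa, gamma_BW, tau_BW, inv_alpha, rho,
               dt, ms_offset, steps_per_tr, v_out, q_out):
    """Advance the Balloon-Windkessel states over a block of ms-mean rates.

    Snapshots (v, q) at every TR boundary into v_out/q_out; returns the
    number of BOLD samples emitted, or -(step+1) on loss of positivity.
    """
    M, N = rates_ms.shape
    emitted = 0
    for m in range(M):
        for n in range(N):
            r = rates_ms[m, n]
            fn = f[n]
            vn = v[n]
            ds = 0.5 * r + 3.0 - kappa * s[n] - gamma_BW * (fn - 1.0)
            df = s[n]
            outflow = vn ** inv_alpha
            dv = (fn - outflow) / tau_BW
            dq = (fn * (1.0 - (1.0 - rho) ** (1.0 / fn)) / rho
                  - q[n] * outflow / vn) / tau_BW
            s[n] += dt * ds
            f[n] += dt * df
            v[n] += dt * dv
            q[n] += dt * dq
            if f[n] <= 0.0 or v[n] <= 0.0 or q[n] <= 0.0:
                return -(ms_offset + m + 1)
        if (ms_offset + m + 1) % steps_per_tr == 0:
            for n in range(N):
                v_out[emitted, n] = v[n]
                q_out[emitted, n] = q[n]
            emitted += 1
    return emitted
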
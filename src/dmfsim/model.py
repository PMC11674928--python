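"""Dynamic mean-field model equations.

Each brain region is modeled by one excitatory and one inhibitory neural
mass with NMDA/GABA synaptic gating variables ``S_E``, ``S_I``. Regions
are coupled through their excitatory populations only, scaled by a global
coupling ``G`` and the structural connectivity matrix. The functions here
are pure — state in, currents/rates/drift out — so they can be verified
independently of any integrator.

The excitatory input current to region ``n`` is

    I_E[n] = W_E*I0 + w_plus*J_NMDA*S_E[n]
             + G*J_NMDA*sum_p C[n,p]*S_E[p] - J[n]*S_I[n]

and the inhibitory one

    I_I[n] = W_I*I0 + J_NMDA*S_E[n] - S_I[n]

with sigmoid-free F-I transfer curves of the form
``F(I) = g*(I - Ithr) / (1 - exp(-d*g*(I - Ithr)))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome
from .params import DMFParameters

# below this |g*(I - Ithr)| the F-I curve is evaluated by its series
# expansion around the removable singularity
_SINGULARITY_BAND = 1e-6


@dataclass
class CouplingConfig:
    """Global coupling and the per-region inhibitory feedback vector.

    ``alpha`` and ``c`` record the linear-rule parameters when ``J`` was
    produced by :func:`dmfsim.fic.linear_fic`; they are informational here.
    """

    G: float
    J: np.ndarray
    alpha: float | None = None
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.G < 0:
            raise ValueError("G must be nonnegative")
        self.J = np.atleast_1d(np.asarray(self.J, dtype=float))
        if np.any(self.J < 0):
            raise ValueError("J must be nonnegative")


@dataclass
class StateVector:
    """Synaptic gating state of all regions (dimensionless, in [0, 1])."""

    S_E: np.ndarray
    S_I: np.ndarray

    def __post_init__(self) -> None:
        self.S_E = np.atleast_1d(np.asarray(self.S_E, dtype=float))
        self.S_I = np.atleast_1d(np.asarray(self.S_I, dtype=float))
        if self.S_E.shape != self.S_I.shape:
            raise ValueError("S_E and S_I must have the same shape")


def transfer_rate(current, gain: float, threshold: float, shape: float):
    """F-I curve: firing rate (Hz) as a function of input current (nA).

    Continuous and monotone nondecreasing; at ``current == threshold``
    the removable singularity is evaluated by its limit ``1/shape``.

    Parameters
    ----------
    current : float or ndarray
        Input current, nA.
    gain : float
        Slope of the asymptote, 1/nC.
    threshold : float
        Current threshold, nA.
    shape : float
        Curvature constant around threshold, s.
    """
    if shape <= 0 or gain <= 0:
        raise ValueError("gain and shape must be positive")
    current = np.asarray(current, dtype=float)
    if not np.all(np.isfinite(current)):
        raise FloatingPointError("non-finite input current (numerical blow-up upstream?)")
    x = gain * (current - threshold)
    out = np.empty_like(x)
    near = np.abs(x) < _SINGULARITY_BAND
    # x/(1-e^{-d x}) = 1/d * 1/(1 - d x/2 + ...) ≈ (1 + d x/2)/d near x=0
    out[near] = (1.0 + shape * x[near] / 2.0) / shape
    xf = x[~near]
    out[~near] = xf / (1.0 - np.exp(-shape * xf))
    return out if out.ndim else float(out)


def excitatory_rate(current, params: DMFParameters):
    """F_E applied with the excitatory constants."""
    return transfer_rate(current, params.gE, params.IthrE, params.dE)


def inhibitory_rate(current, params: DMFParameters):
    """F_I applied with the inhibitory constants."""
    return transfer_rate(current, params.gI, params.IthrI, params.dI)


def synaptic_currents(
    state: StateVector,
    connectome: Connectome,
    coupling: CouplingConfig,
    params: DMFParameters = DMFParameters(),
) -> tuple[np.ndarray, np.ndarray]:
    """Input currents (I_E, I_I) in nA for the current gating state."""
    n = connectome.n_regions
    if state.S_E.shape[0] != n or coupling.J.shape[0] != n:
        raise ValueError("state/coupling dimensions do not match connectome")
    net = connectome.weights @ state.S_E
    I_E = (params.W_E * params.I0
           + params.w_plus * params.J_NMDA * state.S_E
           + coupling.G * params.J_NMDA * net
           - coupling.J * state.S_I)
    I_I = params.W_I * params.I0 + params.J_NMDA * state.S_E - state.S_I
    return I_E, I_I


def drift(
    state: StateVector,
    r_E: np.ndarray,
    r_I: np.ndarray,
    params: DMFParameters = DMFParameters(),
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic part of the gating SDE (noise excluded by contract).

    dS_E/dt = -S_E/tau_NMDA + (1 - S_E)*gamma*r_E
    dS_I/dt = -S_I/tau_GABA + r_I
    """
    r_E = np.asarray(r_E, dtype=float)
    r_I = np.asarray(r_I, dtype=float)
    if r_E.shape != state.S_E.shape or r_I.shape != state.S_I.shape:
        raise ValueError("rates must match state dimensions")
    dS_E = -state.S_E / params.tau_NMDA + (1.0 - state.S_E) * params.gamma_kin * r_E
    dS_I = -state.S_I / params.tau_GABA + r_I
    return dS_E, dS_I
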
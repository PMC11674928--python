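"""Model parameter containers.

All quantities are kept in a single canonical unit system: seconds, Hz and
nA. Literature values quoted in ms (the NMDA/GABA time constants) are
converted once, at construction, so downstream code never mixes scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class DMFParameters:
    """Constants of the two-population (E/I) dynamic mean-field model.

    Defaults are the standard reduced Wong-Wang parameter set used across
    the whole-brain modeling literature.

    Attributes
    ----------
    I0 : float
        External (background) current, nA.
    W_E, W_I : float
        Scaling of the external current onto the excitatory and
        inhibitory populations (dimensionless).
    w_plus : float
        Local excitatory recurrence (dimensionless).
    J_NMDA : float
        Excitatory synaptic coupling, nA.
    gE, gI : float
        Gain of the excitatory/inhibitory F-I curves, 1/nC.
    IthrE, IthrI : float
        Current thresholds of the F-I curves, nA.
    dE, dI : float
        Shape constants of the F-I curves around threshold, s.
    gamma_kin : float
        Excitatory kinetic parameter (dimensionless).
    sigma : float
        Amplitude of the uncorrelated Gaussian noise, nA.
    tau_NMDA, tau_GABA : float
        Synaptic gating time constants, s (100 ms and 10 ms).
    """

    I0: float = 0.382
    W_E: float = 1.0
    W_I: float = 0.7
    w_plus: float = 1.4
    J_NMDA: float = 0.15
    gE: float = 310.0
    gI: float = 615.0
    IthrE: float = 0.403
    IthrI: float = 0.288
    dE: float = 0.16
    dI: float = 0.087
    gamma_kin: float = 0.641
    sigma: float = 0.01
    tau_NMDA: float = 0.1
    tau_GABA: float = 0.01

    def __post_init__(self) -> None:
        positive = [f.name for f in fields(self)
                    if f.name not in ("W_E", "W_I", "w_plus")]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("W_E", "W_I", "w_plus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon-Windkessel constants mapping firing rates to BOLD.

    Defaults follow the standard hemodynamic parameter set of the
    Balloon-Windkessel literature; every field can be overridden.

    Attributes
    ----------
    kappa : float
        Vasodilatory signal decay rate, 1/s.
    gamma_BW : float
        Autoregulatory flow feedback rate, 1/s.
    tau_BW : float
        Hemodynamic transit time, s.
    alpha_BW : float
        Grubb vessel-resistance exponent (dimensionless).
    rho : float
        Resting oxygen extraction fraction (dimensionless).
    V0 : float
        Resting venous blood volume fraction.
    k1, k2, k3 : float
        BOLD signal coefficients (k3 may be negative).
    """

    kappa: float = 0.65
    gamma_BW: float = 0.41
    tau_BW: float = 0.98
    alpha_BW: float = 0.32
    rho: float = 0.34
    V0: float = 0.02
    k1: float = 2.77264
    k2: float = 0.572
    k3: float = -0.43

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma_BW", "tau_BW", "alpha_BW", "rho", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
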
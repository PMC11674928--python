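"""Turbulence-like dynamics measures.

Instantaneous phases of the band-limited BOLD signal, an exponential
spatial kernel over region distances, the local Kuramoto order parameter
R_n(t) (kernel-weighted average of unit phasors) and the turbulence level
D, the pooled standard deviation of R across regions and time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .connectome import Connectome
from .fic import calibrate_fic_linear
from .integrate import DivergenceError, IntegrationConfig, run_simulation
from .model import CouplingConfig
from .observables import ObservablesConfig, bandpass
from .params import DMFParameters, HemodynamicParameters


@dataclass(frozen=True)
class TurbulenceConfig:
    """Spatial scale and preprocessing of the turbulence pipeline.

    lambda_scale : exponential decay rate of the spatial kernel, 1/mm
        (0.18, the value used with empirical cortical coordinates).
    band : filter band for the phase extraction, Hz.
    include_self : keep the kernel diagonal (K_nn = 1).
    edge_drop : phase samples dropped at each end before computing R
        (Hilbert transform edge artifacts).
    """

    lambda_scale: float = 0.18
    band: tuple[float, float] = (0.01, 0.1)
    include_self: bool = True
    edge_drop: int = 5

    def __post_init__(self) -> None:
        if self.lambda_scale <= 0:
            raise ValueError("lambda_scale must be positive")


@dataclass
class LocalOrder:
    """Local Kuramoto order parameter: modulus R and phase nu, per
    region and time point. 0 <= R <= 1 elementwise."""

    R: np.ndarray
    nu: np.ndarray


def instantaneous_phases(filtered: np.ndarray) -> np.ndarray:
    """Phases of the analytic (Hilbert) signal, per region, in (-pi, pi]."""
    x = np.atleast_2d(np.asarray(filtered, dtype=float))
    if np.any(np.all(x == 0, axis=1)):
        raise ValueError("all-zero region: phase undefined")
    return np.angle(hilbert(x, axis=1))


def spatial_kernel(coordinates: np.ndarray, lambda_scale: float = 0.18,
                   include_self: bool = True) -> np.ndarray:
    """Exponential distance kernel K_nq = exp(-lambda * ||x_n - x_q||)."""
    c = np.asarray(coordinates, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3 or not np.all(np.isfinite(c)):
        raise ValueError("coordinates must be a finite N x 3 array")
    diff = c[:, None, :] - c[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    K = np.exp(-lambda_scale * dist)
    if not include_self:
        np.fill_diagonal(K, 0.0)
    return K


def local_kuramoto(phases: np.ndarray, kernel: np.ndarray) -> LocalOrder:
    """Kernel-weighted local synchronization.

    R_n(t) e^{i nu_n(t)} = sum_q K_nq e^{i phi_q(t)} / sum_q K_nq.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape != (phases.shape[0],) * 2:
        raise ValueError("kernel must be N x N matching the phase matrix")
    norm = kernel.sum(axis=1)
    if np.any(norm == 0):
        raise ValueError("zero kernel row: local order undefined")
    z = (kernel @ np.exp(1j * phases)) / norm[:, None]
    return LocalOrder(R=np.abs(z), nu=np.angle(z))


def turbulence_level(R: np.ndarray) -> float:
    """Turbulence level D: std of R pooled over all regions and times."""
    R = np.asarray(R, dtype=float)
    if R.size == 0:
        raise ValueError("R is empty")
    var = np.mean(R * R) - np.mean(R) ** 2
    return float(np.sqrt(max(var, 0.0)))  # guard roundoff for constant R


def turbulence_from_bold(bold: np.ndarray, coordinates: np.ndarray,
                         config: TurbulenceConfig = TurbulenceConfig(),
                         TR: float = 2.0) -> float:
    """D for a BOLD matrix: filter, phases, local order, pooled std."""
    obs = ObservablesConfig(band=config.band, sampling_interval=TR)
    phases = instantaneous_phases(bandpass(bold, obs))
    if config.edge_drop > 0:
        if phases.shape[1] <= 2 * config.edge_drop:
            raise ValueError("too few samples after edge trimming")
        phases = phases[:, config.edge_drop:-config.edge_drop]
    K = spatial_kernel(coordinates, config.lambda_scale, config.include_self)
    return turbulence_level(local_kuramoto(phases, K).R)


@dataclass
class TurbulenceGridResult:
    """Mean |D_sim - D_ref| surface over the (G, alpha) grid."""

    G_values: np.ndarray
    alpha_values: np.ndarray
    surface: np.ndarray          # (len(G), len(alpha)); NaN = divergent cell
    best: tuple[float, float]    # argmin (G, alpha)
    D_values: np.ndarray         # (len(G), len(alpha), n_seeds)


def turbulence_grid(params: DMFParameters, hemo: HemodynamicParameters,
                    connectome: Connectome, G_values, alpha_values,
                    reference_D: float, duration: float = 300.0,
                    n_seeds: int = 2, seed: int = 0,
                    config: TurbulenceConfig = TurbulenceConfig(),
                    TR: float = 2.0) -> TurbulenceGridResult:
    """Scan (G, alpha), comparing simulated D to a reference level.

    Each cell runs ``n_seeds`` simulations with the linear FIC rule and
    reports the mean absolute difference to ``reference_D``; divergent
    cells are recorded as NaN rather than aborting the scan. The same
    seeds are reused across cells (common random numbers), so cell-to-cell
    comparisons cancel the shared seed effect instead of adding it.
    """
    if connectome.coordinates is None:
        raise ValueError("connectome coordinates are required for turbulence")
    G_values = np.asarray(G_values, dtype=float)
    alpha_values = np.asarray(alpha_values, dtype=float)
    surface = np.full((G_values.size, alpha_values.size), np.nan)
    D_all = np.full((G_values.size, alpha_values.size, n_seeds), np.nan)
    for i, G in enumerate(G_values):
        for j, alpha in enumerate(alpha_values):
            J = calibrate_fic_linear(params, connectome, G, alpha)
            diffs = []
            for k in range(n_seeds):
                cfg = IntegrationConfig(duration=duration, TR=TR,
                                        seed=seed + k)
                try:
                    res = run_simulation(params, hemo, connectome,
                                         CouplingConfig(G=G, J=J, alpha=alpha), cfg)
                except DivergenceError:
                    continue
                D = turbulence_from_bold(res.bold, connectome.coordinates,
                                         config, TR)
                D_all[i, j, k] = D
                diffs.append(abs(D - reference_D))
            if diffs:
                surface[i, j] = float(np.mean(diffs))
    if np.all(np.isnan(surface)):
        raise DivergenceError("every grid cell diverged")
    flat = np.nanargmin(surface)
    bi, bj = np.unravel_index(flat, surface.shape)
    return TurbulenceGridResult(G_values=G_values, alpha_values=alpha_values,
                                surface=surface,
                                best=(float(G_values[bi]), float(alpha_values[bj])),
                                D_values=D_all)
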
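"""Synthetic connectomes, coordinates and surrogate BOLD cohorts.

These generators stand in for tractography-derived connectivity and
empirical fMRI: distance-dependent or random weight matrices with the
invariants the model requires (symmetric, nonnegative, zero diagonal,
connected), region coordinates on simple geometries, and model-generated
"empirical" cohorts with a known ground-truth working point so fitting
has a well-defined answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, node_strength
from .integrate import IntegrationConfig, run_simulation
from .model import CouplingConfig
from .params import DMFParameters, HemodynamicParameters

_DISTANCE_SCALE_MM = 40.0  # decay length of the distance-exponential model


@dataclass(frozen=True)
class ConnectomeSpec:
    """Recipe for a synthetic structural connectome.

    model : 'distance-exponential' (weights exp(-d/40 mm), the empirical
        distance dependence of tract strength), 'uniform-random', or
        'modular' (two blocks, dense within, sparse between).
    density : fraction of potential edges kept.
    target_mean_strength : rescale so the mean node strength matches.
    """

    n_regions: int
    model: str = "distance-exponential"
    density: float = 0.4
    weight_scale: float = 1.0
    target_mean_strength: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if self.model not in ("distance-exponential", "uniform-random", "modular"):
            raise ValueError(f"unknown connectome model {self.model!r}")


def make_coordinates(n: int, geometry: str = "sphere", scale: float = 70.0,
                     seed: int = 0) -> np.ndarray:
    """Random region coordinates in mm on a sphere surface or in a box."""
    if n < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    if geometry == "sphere":
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return v * scale
    if geometry == "box":
        return rng.uniform(-scale / 2, scale / 2, size=(n, 3))
    raise ValueError(f"unknown geometry {geometry!r}")


def _connected(w: np.ndarray) -> bool:
    n = w.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(w[i] > 0):
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return bool(seen.all())


def make_connectome(spec: ConnectomeSpec,
                    coordinates: np.ndarray | None = None) -> Connectome:
    """Draw a synthetic connectome satisfying the model's invariants.

    Redraws (up to 100 times) until the graph is connected; rescales to
    ``target_mean_strength`` when requested.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    if spec.model == "distance-exponential" and coordinates is None:
        coordinates = make_coordinates(n, seed=spec.seed)
    for _ in range(100):
        if spec.model == "distance-exponential":
            diff = coordinates[:, None, :] - coordinates[None, :, :]
            dist = np.sqrt((diff * diff).sum(axis=2))
            w = spec.weight_scale * np.exp(-dist / _DISTANCE_SCALE_MM)
        elif spec.model == "uniform-random":
            w = spec.weight_scale * rng.uniform(0, 1, size=(n, n))
            w = (w + w.T) / 2
        else:  # modular
            half = n // 2
            w = spec.weight_scale * rng.uniform(0, 0.2, size=(n, n))
            w[:half, :half] += spec.weight_scale * rng.uniform(0.5, 1.0, (half, half))
            w[half:, half:] += spec.weight_scale * rng.uniform(0.5, 1.0, (n - half, n - half))
            w = (w + w.T) / 2
        mask = rng.uniform(size=(n, n)) < spec.density
        mask = np.triu(mask, k=1)
        mask = mask | mask.T
        w = np.where(mask, w, 0.0)
        np.fill_diagonal(w, 0.0)
        if _connected(w):
            break
    else:
        raise RuntimeError("could not draw a connected graph at this density")
    conn = Connectome(w, coordinates=coordinates)
    if spec.target_mean_strength is not None:
        mean_beta = node_strength(conn).mean()
        if mean_beta == 0:
            raise RuntimeError("empty graph cannot be rescaled")
        conn = Connectome(w * (spec.target_mean_strength / mean_beta),
                          coordinates=coordinates)
    return conn


def make_surrogate_cohort(connectome: Connectome, G_star: float,
                          alpha_star: float, n_subjects: int = 13,
                          duration: float = 500.0, TR: float = 2.0,
                          seed: int = 0,
                          params: DMFParameters = DMFParameters(),
                          hemo: HemodynamicParameters = HemodynamicParameters(),
                          ) -> list[np.ndarray]:
    """Model-generated "empirical" BOLD cohort at a known working point.

    ``n_subjects`` independent simulations (distinct seeds) at
    (G*, alpha*) with the linear FIC rule; the default 500 s at TR = 2 s
    leaves 245 post-transient volumes per subject, comfortably above the
    200-volume floor of usable resting-state runs.
    """
    from .fic import calibrate_fic_linear  # local import to avoid cycle

    J = calibrate_fic_linear(params, connectome, G_star, alpha_star)
    coupling = CouplingConfig(G=G_star, J=J, alpha=alpha_star)
    cohort = []
    for s in range(n_subjects):
        cfg = IntegrationConfig(duration=duration, TR=TR, seed=seed + 7919 * s)
        try:
            res = run_simulation(params, hemo, connectome, coupling, cfg)
        except Exception as exc:  # noqa: BLE001 - re-raise with advice
            raise RuntimeError(
                f"surrogate generation diverged at (G={G_star}, "
                f"alpha={alpha_star}); choose a tamer working point") from exc
        cohort.append(res.bold)
    return cohort
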
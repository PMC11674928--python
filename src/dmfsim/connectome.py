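"""Structural connectome container and strength computation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SYMMETRY_TOL = 1e-8


@dataclass
class Connectome:
    """A structural connectivity matrix with labels and optional coordinates.

    Parameters
    ----------
    weights : (N, N) ndarray
        Symmetric, nonnegative, zero-diagonal coupling weights.
    labels : list of str, optional
        Region names; defaults to ``R000 .. R{N-1}``.
    coordinates : (N, 3) ndarray, optional
        Region centroids in mm, required only for turbulence measures.
    """

    weights: np.ndarray
    labels: list[str] | None = None
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if w.shape[0] < 1:
            raise ValueError("connectome needs at least one region")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if np.max(np.abs(w - w.T)) > SYMMETRY_TOL:
            raise ValueError("weights must be symmetric within 1e-8")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        self.weights = w
        if self.labels is None:
            self.labels = [f"R{i:03d}" for i in range(w.shape[0])]
        elif len(self.labels) != w.shape[0]:
            raise ValueError("labels length must match matrix size")
        if self.coordinates is not None:
            c = np.asarray(self.coordinates, dtype=float)
            if c.shape != (w.shape[0], 3):
                raise ValueError("coordinates must be N x 3")
            self.coordinates = c

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def node_strength(connectome: Connectome, halve: bool = False) -> np.ndarray:
    """Row-sum strength beta_n of each region.

    With ``halve=True`` the strengths are divided by 2 to compensate the
    double counting of symmetric edges; the default is the literal row sum.
    """
    beta = connectome.weights.sum(axis=1)
    return beta / 2.0 if halve else beta
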
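"""Delimited-text and HDF5 readers/writers plus run configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .connectome import Connectome
from .fitting import FitConfig
from .integrate import IntegrationConfig
from .observables import ObservablesConfig
from .params import DMFParameters, HemodynamicParameters
from .turbulence import TurbulenceConfig

log = logging.getLogger("dmfsim")

_ASYMMETRY_TOL = 1e-6


def _sniff_delimiter(path: Path) -> str | None:
    head = path.read_text().splitlines()[0]
    for d in (",", "\t", ";"):
        if d in head:
            return d
    return None  # whitespace


def read_connectome(path: str | Path, delimiter: str | None = "auto") -> Connectome:
    """Load a square weight matrix from delimited text.

    Mild asymmetry (<= 1e-6, e.g. from probabilistic tracking in both
    directions) is symmetrized by averaging with a log line; larger
    asymmetry is an error, as are negative weights and NaNs.
    """
    path = Path(path)
    if delimiter == "auto":
        delimiter = _sniff_delimiter(path)
    w = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"connectome must be square, got {w.shape}")
    if np.any(~np.isfinite(w)):
        raise ValueError("connectome contains NaN/inf")
    if np.any(w < 0):
        raise ValueError("connectome contains negative weights")
    asym = float(np.max(np.abs(w - w.T))) if w.size else 0.0
    if asym > _ASYMMETRY_TOL:
        raise ValueError(f"asymmetry {asym:.2e} exceeds tolerance {_ASYMMETRY_TOL}")
    if asym > 0:
        log.info("symmetrizing connectome (max asymmetry %.2e)", asym)
        w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return Connectome(w)


def read_coordinates(path: str | Path, delimiter: str | None = "auto") -> np.ndarray:
    """Load an N x 3 coordinate table (mm)."""
    path = Path(path)
    if delimiter == "auto":
        delimiter = _sniff_delimiter(path)
    c = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    if c.shape[1] != 3:
        raise ValueError(f"coordinates must have 3 columns, got {c.shape[1]}")
    return c


def write_bold(path: str | Path, bold: np.ndarray,
               labels: list[str] | None = None, delimiter: str = "\t") -> None:
    """Write a regions x time matrix with a header row of labels.

    Values are printed at 17 significant digits so a round trip is
    bit-stable.
    """
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    if labels is None:
        labels = [f"R{i:03d}" for i in range(bold.shape[0])]
    header = delimiter.join(labels)
    np.savetxt(path, bold, delimiter=delimiter, header=header,
               comments="", fmt="%.17g")


def read_bold(path: str | Path, delimiter: str | None = "auto"
              ) -> tuple[np.ndarray, list[str]]:
    """Read a regions x time matrix written by :func:`write_bold`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError("empty BOLD file")
    if delimiter == "auto":
        delimiter = _sniff_delimiter(path)
    labels = lines[0].split(delimiter)
    data = np.loadtxt(lines[1:], delimiter=delimiter, ndmin=2)
    widths = {len(l.split(delimiter)) for l in lines[1:] if l.strip()}
    if len(widths) > 1:
        raise ValueError("ragged rows in BOLD file")
    if data.shape[0] > 50 * data.shape[1]:
        log.warning("matrix has far more rows than columns; expected "
                    "regions x time orientation")
    return data, labels


def write_result_h5(path: str | Path, result) -> None:
    """Hierarchical container with /bold, /rate_mean, /rate_std, /config."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("bold", data=result.bold)
        f.create_dataset("rate_mean", data=result.rate_mean)
        f.create_dataset("rate_std", data=result.rate_std)
        f.attrs["config"] = json.dumps(dataclasses.asdict(result.config))
        f.attrs["seed"] = result.seed


def write_fcd_h5(path: str | Path, summary) -> None:
    """Hierarchical container for an FCD summary: /fcd and /pooled."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("fcd", data=summary.fcd)
        f.create_dataset("pooled", data=summary.pooled_values)
        f.attrs["window_count"] = summary.window_count


@dataclass
class RunConfig:
    """Nested configuration document for CLI runs.

    Every section is optional and falls back to the documented defaults;
    unknown keys anywhere are rejected.
    """

    dmf: DMFParameters = field(default_factory=DMFParameters)
    hemodynamics: HemodynamicParameters = field(default_factory=HemodynamicParameters)
    integration: dict = field(default_factory=dict)   # merged into IntegrationConfig
    observables: ObservablesConfig = field(default_factory=ObservablesConfig)
    turbulence: TurbulenceConfig = field(default_factory=TurbulenceConfig)
    fit: FitConfig = field(default_factory=FitConfig)


_SECTIONS = {
    "dmf": DMFParameters,
    "hemodynamics": HemodynamicParameters,
    "observables": ObservablesConfig,
    "turbulence": TurbulenceConfig,
    "fit": FitConfig,
}


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML/JSON configuration document into a RunConfig."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_SECTIONS) - {"integration"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - valid
        if bad:
            raise ValueError(f"unknown key(s) in [{name}]: {sorted(bad)}")
        if "band" in section:
            section["band"] = tuple(section["band"])
        for key in ("bounds_G", "bounds_alpha"):
            if key in section:
                section[key] = tuple(section[key])
        kwargs[name] = cls(**section)
    integ = raw.get("integration", {}) or {}
    valid = {f.name for f in dataclasses.fields(IntegrationConfig)}
    bad = set(integ) - valid
    if bad:
        raise ValueError(f"unknown key(s) in [integration]: {sorted(bad)}")
    return RunConfig(integration=integ, **kwargs)
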
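"""BOLD signal processing and summary statistics.

Band-pass filtering, static functional connectivity (FC), sliding-window
functional connectivity dynamics (FCD) and the pooled-FCD two-sample
Kolmogorov-Smirnov distance that serves as the model-fitting objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats


@dataclass(frozen=True)
class ObservablesConfig:
    """Filter band and FCD windowing.

    band : low/high cutoffs in Hz (default 0.01-0.1, the resting-state
        band); must lie below the Nyquist frequency 1/(2*TR).
    filter_order : Butterworth order (2).
    window_length / window_overlap : FCD sliding windows in TR samples
        (30 points, 28 overlap, i.e. stride 2).
    sampling_interval : TR in seconds.
    """

    band: tuple[float, float] = (0.01, 0.1)
    filter_order: int = 2
    window_length: int = 30
    window_overlap: int = 28
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        low, high = self.band
        nyq = 0.5 / self.sampling_interval
        if not (0 < low < high < nyq):
            raise ValueError(f"band must satisfy 0 < low < high < {nyq} Hz")
        if not (0 <= self.window_overlap < self.window_length):
            raise ValueError("overlap must be smaller than window length")

    @property
    def stride(self) -> int:
        return self.window_length - self.window_overlap


@dataclass
class FCDSummary:
    """FCD matrix with its pooled upper-triangle sample."""

    fcd: np.ndarray
    pooled_values: np.ndarray
    window_count: int


def bandpass(signals: np.ndarray,
             config: ObservablesConfig = ObservablesConfig()) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied per region.

    Forward-backward filtering with edge padding of 3*(order+1) samples.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals contain non-finite values")
    T = signals.shape[1]
    padlen = 3 * (config.filter_order + 1)
    if T <= max(6 * config.filter_order, padlen):
        raise ValueError(f"time series too short to filter (T={T})")
    fs = 1.0 / config.sampling_interval
    b, a = signal.butter(config.filter_order, config.band,
                         btype="bandpass", fs=fs)
    return signal.filtfilt(b, a, signals, axis=1, padlen=padlen)


def fc_matrix(signals: np.ndarray) -> np.ndarray:
    """Static FC: Pearson correlations between all region pairs.

    Zero-variance regions are reported explicitly rather than silently
    mapped to zero correlation.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    sd = signals.std(axis=1)
    if np.any(sd == 0):
        flat = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance region(s) {flat.tolist()}: "
                         "correlation undefined")
    fc = np.corrcoef(signals)
    return np.atleast_2d(fc)


def _upper_triangle(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(m, k=1)
    return m[iu]


def fcd_matrix(signals: np.ndarray,
               config: ObservablesConfig = ObservablesConfig()) -> FCDSummary:
    """Sliding-window FCD.

    FC is computed on consecutive windows (length ``window_length``,
    advancing by the stride, trailing partial window dropped), each FC is
    vectorized by its strict upper triangle, and the FCD matrix collects
    the Pearson correlations among those vectors.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    T = signals.shape[1]
    L, s = config.window_length, config.stride
    if T < L:
        raise ValueError(f"need at least {L} samples, got {T}")
    W = (T - L) // s + 1
    vecs = np.empty((W, signals.shape[0] * (signals.shape[0] - 1) // 2))
    for w in range(W):
        win = signals[:, w * s:w * s + L]
        vecs[w] = _upper_triangle(fc_matrix(win))
    fcd = np.corrcoef(vecs)
    fcd = np.atleast_2d(fcd)
    return FCDSummary(fcd=fcd, pooled_values=_upper_triangle(fcd),
                      window_count=W)


def ks_distance(sample_a: np.ndarray, sample_b: np.ndarray,
                binned: bool = False, bins: int = 100) -> float:
    """Two-sample Kolmogorov-Smirnov statistic, sup |ECDF_a - ECDF_b|.

    ``binned=True`` computes the statistic on histogram-based CDFs over a
    common grid instead of the raw samples.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    if binned:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        edges = np.linspace(lo, hi, bins + 1)
        ca = np.cumsum(np.histogram(a, edges)[0]) / a.size
        cb = np.cumsum(np.histogram(b, edges)[0]) / b.size
        return float(np.max(np.abs(ca - cb)))
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def pool_fcd(summaries: list[FCDSummary]) -> np.ndarray:
    """Concatenate upper-triangle FCD values across subjects/runs."""
    if not summaries:
        raise ValueError("need at least one FCD summary")
    return np.concatenate([s.pooled_values for s in summaries])


@dataclass
class RateCheck:
    """Per-region verdicts of the physiological firing-rate check."""

    passed: bool
    flags: np.ndarray          # True where the region is in range
    failing_regions: list[int]


def rate_in_range(rate_mean: np.ndarray, low: float = 3.0,
                  high: float = 4.0) -> RateCheck:
    """Check mean excitatory rates against the plausible 3-4 Hz band.

    The interval is closed: boundary values pass.
    """
    r = np.atleast_1d(np.asarray(rate_mean, dtype=float))
    flags = (r >= low) & (r <= high)
    return RateCheck(passed=bool(np.all(flags)), flags=flags,
                     failing_regions=np.flatnonzero(~flags).tolist())
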
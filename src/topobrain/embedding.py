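"""Takens delay embedding of ROI time series, with automatic parameter selection.

A scalar series x(t) is reconstructed as the point cloud whose i-th point is
(x_i, x_{i+tau}, ..., x_{i+(m-1) tau}).  The delay ``tau`` is chosen at the
first local minimum of the lagged mutual information and the dimension ``m``
by the false-nearest-neighbor criterion of Kennel et al.  One global (tau, m)
pair is used for a whole dataset so that embedded geometry is comparable
across subjects.

An optional zero-phase Butterworth bandpass (default band 0.01-0.08 Hz,
the conventional resting-state fMRI band) can be applied first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddingParams",
    "PointCloud",
    "DegenerateSeriesError",
    "bandpass",
    "select_delay_mi",
    "select_dimension_fnn",
    "delay_embed",
    "select_global_params",
]


class DegenerateSeriesError(ValueError):
    """Raised when a series carries no usable variation (e.g. constant)."""


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters: delay in samples, dimension as a count."""

    delay: int
    dimension: int

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError("delay must be >= 1")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")

    def n_points(self, n_samples: int) -> int:
        return n_samples - (self.dimension - 1) * self.delay


@dataclass
class PointCloud:
    """An n x m matrix of embedded state-space points with its provenance."""

    points: np.ndarray
    source: tuple = ()

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if np.isnan(self.points).any():
            raise ValueError("point cloud contains NaN")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


def bandpass(series, fs: float, low: float = 0.01, high: float = 0.08,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (applied forward and backward)."""
    x = np.asarray(series, dtype=float)
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    min_len = 3 * (2 * order + 1)
    if x.shape[-1] <= min_len:
        raise ValueError(f"series length {x.shape[-1]} too short; need > {min_len}")
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x, axis=-1)


def _mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Histogram MI in nats with equal-width bins over each variable's range."""
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def mi_profile(series, max_lag: int, n_bins: int = 16) -> np.ndarray:
    """MI between x(t) and x(t+lag) for lag = 0..max_lag."""
    x = np.asarray(series, dtype=float)
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = x[: len(x) - lag] if lag else x
        b = x[lag:]
        out[lag] = _mutual_information(a, b, n_bins)
    return out


def select_delay_mi(series, max_lag: int, n_bins: int = 16,
                    smooth: int = 7) -> int:
    """Delay at the first local minimum of the lagged mutual information.

    The MI profile is smoothed with a centered moving average of width
    ``smooth`` before scanning (the histogram estimator's lag-to-lag jitter
    otherwise produces spurious shallow minima); the first lag l with
    MI(l) < MI(l-1) and MI(l) <= MI(l+1) on the smoothed profile is
    returned.  If no local minimum exists in [1, max_lag], the raw profile's
    global-minimum lag is returned and a warning is issued.
    """
    x = np.asarray(series, dtype=float)
    if max_lag >= len(x) / 2:
        raise ValueError("max_lag must be below half the series length")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series has no MI structure")
    mi = mi_profile(x, max_lag, n_bins)
    sm = mi
    if smooth > 1:
        sm = np.convolve(mi, np.ones(smooth) / smooth, mode="same")
    for lag in range(1, max_lag):
        if sm[lag] < sm[lag - 1] and sm[lag] <= sm[lag + 1]:
            return lag
    warnings.warn("no local MI minimum found; falling back to global minimum",
                  stacklevel=2)
    return int(np.argmin(mi[1:]) + 1)


def fnn_fractions(series, delay: int, max_dim: int, r_tol: float = 15.0,
                  a_tol: float = 2.0) -> np.ndarray:
    """False-nearest-neighbor fraction for dimensions 1..max_dim.

    A neighbor pair at dimension m is false when the extra (m+1)-th delay
    coordinate either stretches the pair by more than ``r_tol`` relative to
    its distance, or pushes the pair apart relative to the attractor size by
    more than ``a_tol`` (Kennel et al.'s two criteria).
    """
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        raise DegenerateSeriesError("constant series cannot be embedded")
    fracs = np.empty(max_dim)
    for m in range(1, max_dim + 1):
        n_pts = len(x) - m * delay  # one extra coordinate must exist
        if n_pts < 2:
            raise ValueError(f"series too short for FNN at dimension {m}")
        emb = np.column_stack([x[k * delay : k * delay + n_pts] for k in range(m)])
        nxt = x[m * delay : m * delay + n_pts]
        tree = cKDTree(emb)
        dist, idx = tree.query(emb, k=2)
        r = dist[:, 1]
        nn = idx[:, 1]
        extra = np.abs(nxt - nxt[nn])
        with np.errstate(divide="ignore", invalid="ignore"):
            crit1 = np.where(r > 0, extra / r, np.inf) > r_tol
        crit2 = np.sqrt(r**2 + extra**2) / sd > a_tol
        false = crit1 | crit2
        # neighbors whose extra-coordinate gap is at numerical-noise level
        # (exact revisits of a periodic orbit) are true neighbors even when
        # the ratio test misfires on two denormal-scale numbers
        false[extra <= 1e-8 * sd] = False
        fracs[m - 1] = false.mean()
    return fracs


def select_dimension_fnn(series, delay: int, max_dim: int = 8,
                         r_tol: float = 15.0, a_tol: float = 2.0,
                         fnn_threshold: float = 0.02) -> int:
    """Smallest dimension whose FNN fraction drops below ``fnn_threshold``.

    Returns ``max_dim`` with a warning when the fraction never drops below
    the threshold (typical for noise-dominated series).
    """
    fracs = fnn_fractions(series, delay, max_dim, r_tol, a_tol)
    below = np.nonzero(fracs < fnn_threshold)[0]
    if len(below):
        return int(below[0] + 1)
    warnings.warn("FNN fraction never fell below threshold; using max_dim",
                  stacklevel=2)
    return max_dim


def delay_embed(series, params: EmbeddingParams, source: tuple = ()) -> PointCloud:
    """Embed a scalar series: row i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = np.asarray(series, dtype=float)
    tau, m = params.delay, params.dimension
    n = len(x) - (m - 1) * tau
    if n < m:
        raise ValueError(
            f"series of length {len(x)} too short for (delay={tau}, dim={m}); "
            f"need at least {(m - 1) * tau + m} samples"
        )
    pts = np.column_stack([x[k * tau : k * tau + n] for k in range(m)])
    return PointCloud(points=pts, source=source)


def select_global_params(series_list, max_lag: int = 50, max_dim: int = 8,
                         n_bins: int = 16, subsample: int | None = None,
                         seed: int = 0, **fnn_kwargs) -> EmbeddingParams:
    """One global (delay, dimension) pair for a whole dataset.

    Per-series delays and dimensions are estimated on a random subsample of
    the series and aggregated by the median, rounded up to an integer.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("need at least one series")
    if subsample is not None and subsample < len(series_list):
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(series_list), size=subsample, replace=False)
        series_list = [series_list[i] for i in sorted(pick)]
    delays, dims = [], []
    for s in series_list:
        tau = select_delay_mi(s, max_lag=max_lag, n_bins=n_bins)
        delays.append(tau)
        dims.append(select_dimension_fnn(s, delay=tau, max_dim=max_dim, **fnn_kwargs))
    delay = math.ceil(np.median(delays))
    dim = math.ceil(np.median(dims))
    return EmbeddingParams(delay=delay, dimension=dim)
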
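"""Conventional per-ROI time-series features: the 24-dimensional baseline.

Each ROI series is summarized by 22 classical time-series statistics spanning
autocorrelation structure, distribution shape, frequency content, nonlinearity
and stationarity, plus the raw mean and standard deviation appended in the
last two positions.  The 22 statistics are computed on an internally z-scored
copy of the series (so they describe shape, not scale); mean and std are taken
from the raw series and carry the scale information.

The feature order is fixed (``TEMPORAL_FEATURE_NAMES``) and the map is fully
deterministic.  Statistics that are undefined for a given series propagate as
NaN and are median-imputed per feature at the cohort level before modeling.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal, stats
from scipy.spatial import distance

__all__ = ["TEMPORAL_FEATURE_NAMES", "temporal_features", "impute_feature_matrix"]

TEMPORAL_FEATURE_NAMES = (
    "acf_lag1",
    "acf_lag2",
    "acf_lag5",
    "acf_first_zero_lag",
    "acf_first_1e_lag",
    "pacf_lag2",
    "spectral_centroid",
    "spectral_entropy",
    "low_freq_power_fraction",
    "hist_mode_10bin",
    "hist_mode_5bin",
    "prop_abs_above_2sd",
    "skewness",
    "excess_kurtosis",
    "time_reversal_asymmetry",
    "mean_abs_diff",
    "longest_stretch_above_mean",
    "longest_monotonic_decrease",
    "mean_crossing_rate",
    "sample_entropy_m2",
    "dfa_exponent",
    "segment_mean_dispersion",
    "mean",
    "std",
)


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return np.full(max_lag + 1, np.nan)
    full = np.correlate(xc, xc, mode="full")[n - 1 :]
    return full[: max_lag + 1] / denom


def _pacf_lag2(acf: np.ndarray) -> float:
    # Durbin-Levinson second-order partial autocorrelation
    r1, r2 = acf[1], acf[2]
    denom = 1 - r1**2
    return float((r2 - r1**2) / denom) if denom != 0 else np.nan


def _first_crossing(acf: np.ndarray, level: float) -> float:
    below = np.nonzero(acf[1:] <= level)[0]
    return float(below[0] + 1) if len(below) else float(len(acf))


def _hist_mode(z: np.ndarray, bins: int) -> float:
    counts, edges = np.histogram(z, bins=bins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def _sample_entropy(z: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    n = len(z)
    if n < m + 2:
        return np.nan

    def count(mm: int) -> int:
        emb = np.column_stack([z[k : n - mm + 1 + k] for k in range(mm)])
        d = distance.pdist(emb, "chebyshev")
        return int(np.sum(d <= r))

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def _dfa_exponent(z: np.ndarray) -> float:
    n = len(z)
    y = np.cumsum(z - z.mean())
    sizes = np.unique(np.floor(np.logspace(np.log10(4), np.log10(n // 4), 10)).astype(int))
    sizes = sizes[sizes >= 4]
    if len(sizes) < 3:
        return np.nan
    flucts = []
    for s in sizes:
        nseg = n // s
        segs = y[: nseg * s].reshape(nseg, s)
        t = np.arange(s)
        tc = t - t.mean()
        beta = segs @ tc / (tc @ tc)
        resid = segs - segs.mean(axis=1, keepdims=True) - beta[:, None] * tc
        flucts.append(np.sqrt(np.mean(resid**2)))
    flucts = np.asarray(flucts)
    if np.any(flucts <= 0):
        return np.nan
    slope = np.polyfit(np.log(sizes), np.log(flucts), 1)[0]
    return float(slope)


def temporal_features(series) -> np.ndarray:
    """24-vector of temporal features; mean and std occupy the last two slots.

    Requires at least 30 samples.  A constant series is flagged with a
    warning; its 22 shape features are set to 0 and std is 0.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 30:
        raise ValueError(f"series length {len(x)} below the minimum of 30")
    mu = float(x.mean())
    sd = float(x.std())  # population convention
    if sd == 0:
        warnings.warn("constant series: shape features undefined, set to 0",
                      stacklevel=2)
        out = np.zeros(24)
        out[22], out[23] = mu, 0.0
        return out
    z = (x - mu) / sd
    n = len(z)

    acf = _acf(z, max_lag=min(20, n - 2))
    dz = np.diff(z)
    sq = float(np.mean(dz**2))
    trev = float(np.mean(dz**3) / sq**1.5) if sq > 0 else np.nan

    freqs, psd = signal.welch(z, nperseg=min(128, n))
    power = psd / psd.sum() if psd.sum() > 0 else np.full_like(psd, np.nan)
    centroid = float(np.sum(freqs * power))
    nz = power[power > 0]
    spec_ent = float(-(nz * np.log(nz)).sum() / np.log(len(power)))
    low = float(power[freqs <= freqs.max() / 4].sum())

    above = z > 0
    crossings = float(np.mean(above[1:] != above[:-1]))
    feats = np.array([
        acf[1],
        acf[2],
        acf[5] if len(acf) > 5 else np.nan,
        _first_crossing(acf, 0.0),
        _first_crossing(acf, 1 / np.e),
        _pacf_lag2(acf),
        centroid,
        spec_ent,
        low,
        _hist_mode(z, 10),
        _hist_mode(z, 5),
        float(np.mean(np.abs(z) > 2)),
        float(stats.skew(z)),
        float(stats.kurtosis(z)),
        trev,
        float(np.mean(np.abs(dz))),
        _longest_run(above) / n,
        _longest_run(dz < 0) / n,
        crossings,
        _sample_entropy(z),
        _dfa_exponent(z),
        float(np.std([seg.mean() for seg in np.array_split(z, 5)])),
        mu,
        sd,
    ])
    return feats


def impute_feature_matrix(X: np.ndarray) -> np.ndarray:
    """Replace non-finite entries by the per-column median of finite values."""
    X = np.array(X, dtype=float)
    bad = ~np.isfinite(X)
    if bad.any():
        for j in np.nonzero(bad.any(axis=0))[0]:
            col = X[:, j]
            finite = col[np.isfinite(col)]
            fill = np.median(finite) if len(finite) else 0.0
            col[~np.isfinite(col)] = fill
    return X
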
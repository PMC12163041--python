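"""Brain-behavior canonical correlation analysis with permutation inference.

Pipeline: behavioral item filtering -> confound regression -> z-scoring and
PCA of both the feature matrix and the behavior matrix -> first-mode CCA ->
permutation test shuffling subject rows of the behavioral PC matrix ->
interpretation via per-ROI first-PC contributions and behavioral structure
loadings.

The first canonical correlation is computed by the SVD formulation: with
Qx, Qy orthonormal bases of the column-centered PC score matrices, the
canonical correlations are the singular values of Qx' Qy.  The permutation
p-value is (1 + #{r_perm >= r_obs}) / (1 + n_perm), whose floor at n_perm
permutations is 1/(n_perm + 1) — e.g. 0.0001 at 10,000 iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CcaModeResult",
    "RoiContribution",
    "filter_behaviors",
    "deconfound",
    "cca_first_mode",
    "roi_contributions",
    "top_behavior_loadings",
]


@dataclass
class CcaModeResult:
    """First canonical mode: correlation, weights, variates, permutation null."""

    r1: float
    p_perm: float
    perm_null: np.ndarray
    x_variate: np.ndarray  # (n,) canonical feature scores
    y_variate: np.ndarray  # (n,) canonical behavior scores
    feature_weights: np.ndarray  # weights in original (z-scored) feature space
    behavior_weights: np.ndarray  # weights in original (z-scored) behavior space
    n_pc: int = 0
    n_perm: int = 0


@dataclass
class RoiContribution:
    """Per-ROI/per-network contribution of each homology dimension."""

    roi_table: pd.DataFrame  # columns: roi, dim, contribution, network
    network_table: pd.DataFrame  # per (network, dim): mean, sd, n_rois
    network_tests: pd.DataFrame  # per network: t statistic and p, |H0| vs |H1|


def filter_behaviors(Y: pd.DataFrame, missing_max: float = 0.10,
                     var_floor: float = 1e-12,
                     max_category_freq: float = 0.95):
    """Drop behavioral items with too much missingness, no variance, or a
    dominant single value.

    Returns ``(filtered frame, kept item names)``.  Raises if nothing
    survives.
    """
    if Y.columns.duplicated().any():
        raise ValueError("behavior item names must be unique")
    kept = []
    for col in Y.columns:
        v = Y[col]
        if v.isna().mean() > missing_max:
            continue
        obs = v.dropna()
        if len(obs) == 0 or obs.var(ddof=0) < var_floor:
            continue
        if obs.value_counts(normalize=True).iloc[0] > max_category_freq:
            continue
        kept.append(col)
    if not kept:
        raise ValueError("behavioral filtering dropped every item")
    return Y[kept], kept


def deconfound(X: np.ndarray, C: np.ndarray | None = None) -> np.ndarray:
    """Residualize X on confounds C (an intercept is always included).

    Returns X - C (C'C)^{-1} C' X; residual columns are orthogonal to every
    confound column.  Rank-deficient designs are rejected with the offending
    columns named.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    design = np.ones((n, 1))
    if C is not None and np.size(C):
        C = np.asarray(C, dtype=float).reshape(n, -1)
        design = np.hstack([design, C])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name collinear columns (0 = intercept)
        bad = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(design[:, :j]):
                bad.append(j - 1)
        raise ValueError(f"confound matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ beta


def _zscore(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=0)) / sd_safe


def _pca_scores(X: np.ndarray, n_pc: int):
    """Top-n_pc principal component scores of a centered matrix (via SVD)."""
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_pc = min(n_pc, (s > 1e-12).sum())
    return U[:, :n_pc] * s[:n_pc], Vt[:n_pc]


def _first_canonical(Qx: np.ndarray, Qy: np.ndarray):
    M = Qx.T @ Qy
    U, s, Vt = np.linalg.svd(M)
    return float(min(s[0], 1.0)), U[:, 0], Vt[0]


def cca_first_mode(Xf: np.ndarray, Yb: np.ndarray, n_pc: int = 100,
                   n_perm: int = 10_000, seed: int = 0) -> CcaModeResult:
    """First-mode CCA between features and behaviors with a permutation test.

    Both matrices are z-scored column-wise and reduced by PCA to at most
    ``n_pc`` components.  Significance comes from shuffling the subject rows
    of the behavioral PC matrix ``n_perm`` times and recomputing the first
    canonical correlation.
    """
    Xf = np.asarray(Xf, dtype=float)
    Yb = np.asarray(Yb, dtype=float)
    n = Xf.shape[0]
    if Yb.shape[0] != n:
        raise ValueError("feature and behavior rows must align")
    if n <= n_pc:
        raise ValueError(
            f"n_subjects={n} must exceed n_pc={n_pc}; lower n_pc"
        )
    Xpc, Vx = _pca_scores(_zscore(Xf), n_pc)
    Ypc, Vy = _pca_scores(_zscore(Yb), n_pc)

    Qx, Rx = np.linalg.qr(Xpc - Xpc.mean(axis=0))
    Qy, Ry = np.linalg.qr(Ypc - Ypc.mean(axis=0))
    r1, ax, ay = _first_canonical(Qx, Qy)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        M = Qx.T @ Qy[perm]
        null[b] = np.linalg.svd(M, compute_uv=False)[0]
    p = (1.0 + np.sum(null >= r1)) / (1.0 + n_perm)

    x_variate = Qx @ ax
    y_variate = Qy @ ay
    # map orthonormal-basis weights back: PC space, then original columns
    wx_pc = np.linalg.solve(Rx, ax)
    wy_pc = np.linalg.solve(Ry, ay)
    feature_weights = Vx.T @ wx_pc
    behavior_weights = Vy.T @ wy_pc
    return CcaModeResult(
        r1=r1, p_perm=float(p), perm_null=null,
        x_variate=x_variate, y_variate=y_variate,
        feature_weights=feature_weights, behavior_weights=behavior_weights,
        n_pc=n_pc, n_perm=n_perm,
    )


def _roi_first_pc(block: np.ndarray) -> np.ndarray:
    """Sign-aligned first principal component score of one ROI's features.

    The sign is fixed so the score correlates positively with the ROI's mean
    feature value across subjects (PCA signs are otherwise arbitrary).
    """
    Z = _zscore(block)
    scores, _ = _pca_scores(Z, 1)
    score = scores[:, 0]
    anchor = block.mean(axis=1)
    c = np.corrcoef(score, anchor)[0, 1]
    if np.isfinite(c) and c < 0:
        score = -score
    return score


def roi_contributions(features: np.ndarray, layout, result: CcaModeResult,
                      network_labels) -> RoiContribution:
    """Correlate each ROI's first-PC score with the canonical feature variate.

    For every (ROI, dim) block of landscape features, the block's
    sign-aligned first PC is the ROI's representative feature; its Pearson
    correlation with the canonical variate is the ROI's contribution.
    Contributions are aggregated per network, and |H0| vs |H1| contributions
    are compared per network by a two-sample t-test.
    """
    labels = list(network_labels)
    if len(labels) != len(layout.rois):
        raise ValueError("need one network label per ROI")
    rows = []
    for roi, net in zip(layout.rois, labels):
        for dim in layout.dims:
            cols = layout.columns_for(roi, dim)
            score = _roi_first_pc(features[:, cols])
            contrib = float(np.corrcoef(score, result.x_variate)[0, 1])
            rows.append({"roi": roi, "dim": dim, "contribution": contrib,
                         "network": net})
    roi_table = pd.DataFrame(rows)
    network_table = (
        roi_table.groupby(["network", "dim"])["contribution"]
        .agg(mean="mean", sd="std", n_rois="count")
        .reset_index()
    )
    tests = []
    for net, sub in roi_table.groupby("network"):
        h0 = sub.loc[sub["dim"] == 0, "contribution"].abs().to_numpy()
        h1 = sub.loc[sub["dim"] == 1, "contribution"].abs().to_numpy()
        if len(h0) >= 2 and len(h1) >= 2:
            t, p = stats.ttest_ind(h0, h1)
        else:
            t, p = np.nan, np.nan
        tests.append({"network": net, "t": float(t), "p": float(p)})
    return RoiContribution(roi_table=roi_table, network_table=network_table,
                           network_tests=pd.DataFrame(tests))


def top_behavior_loadings(Y_items: pd.DataFrame, result: CcaModeResult,
                          k: int = 10) -> pd.DataFrame:
    """Top-k behavioral items by |structure loading| on the behavior variate.

    Loadings are Pearson correlations of each (original) item with the
    canonical behavior variate — the standard interpretive quantity; raw
    weights remain available on the result object.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > Y_items.shape[1]:
        warnings.warn("k exceeds item count; returning all items", stacklevel=2)
        k = Y_items.shape[1]
    v = result.y_variate
    loadings = {
        col: float(np.corrcoef(Y_items[col].to_numpy(dtype=float), v)[0, 1])
        for col in Y_items.columns
    }
    table = (
        pd.DataFrame({"item": list(loadings), "loading": list(loadings.values())})
        .assign(abs_loading=lambda d: d["loading"].abs())
        .sort_values("abs_loading", ascending=False, kind="mergesort")
        .drop(columns="abs_loading")
        .head(k)
        .reset_index(drop=True)
    )
    return table
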
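"""Supervised harnesses comparing feature sets.

Binary (gender-analog) classification by L2 logistic regression with
stratified five-fold cross-validation and a single ROC/AUC from the pooled
out-of-fold probabilities; behavioral regression with five-fold CV repeated
with different splits, scoring one Pearson r (predicted vs observed) per
repeat; and a paired t-test across repeats to compare two feature sets on
identical fold splits.

Dimensionality reduction (z-score + PCA) is fit inside each training fold and
applied to the held-out fold, so no statistic of held-out subjects ever
enters training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "CvPrediction",
    "reduce_features",
    "classify_binary",
    "regress_behavior",
    "paired_compare",
    "domain_summary",
]


@dataclass
class CvPrediction:
    """Cross-validated out-of-fold predictions and per-repeat metrics."""

    fold_assignment: np.ndarray  # (n,) or (n_repeats, n)
    scores: np.ndarray  # out-of-fold probabilities or predictions
    metrics: np.ndarray  # AUC (scalar array) or Pearson r per repeat
    seeds: tuple


def reduce_features(F: np.ndarray, n_pc: int):
    """Global z-score + PCA reduction to ``n_pc`` scores.

    For cross-validated modeling use the in-fold pipelines below instead;
    this global variant serves unsupervised summaries.
    """
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    if n <= n_pc:
        raise ValueError(f"n_subjects={n} must exceed n_pc={n_pc}")
    sd = F.std(axis=0)
    Z = (F - F.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    return PCA(n_components=n_pc, svd_solver="full").fit_transform(Z)


def _pc_pipeline(model, n_pc: int | None, n_train: int, n_feat: int) -> Pipeline:
    steps = [("scale", StandardScaler())]
    if n_pc is not None:
        k = min(n_pc, n_train - 1, n_feat)
        steps.append(("pca", PCA(n_components=k, svd_solver="full")))
    steps.append(("model", model))
    return Pipeline(steps)


def classify_binary(F: np.ndarray, labels, n_folds: int = 5, seed: int = 0,
                    n_pc: int | None = None) -> CvPrediction:
    """Stratified k-fold logistic regression; one AUC from pooled
    out-of-fold class probabilities."""
    F = np.asarray(F, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    proba = np.empty(len(y))
    folds = np.empty(len(y), dtype=int)
    for k, (tr, te) in enumerate(cv.split(F, y)):
        pipe = _pc_pipeline(
            LogisticRegression(C=1.0, max_iter=2000),  # L2 penalty (default)
            n_pc, len(tr), F.shape[1],
        )
        pipe.fit(F[tr], y[tr])
        proba[te] = pipe.predict_proba(F[te])[:, 1]
        folds[te] = k
    auc = float(roc_auc_score(y, proba))
    return CvPrediction(fold_assignment=folds, scores=proba,
                        metrics=np.array([auc]), seeds=(seed,))


def regress_behavior(F: np.ndarray, y, n_folds: int = 5, n_repeats: int = 10,
                     seed: int = 0, n_pc: int | None = None) -> CvPrediction:
    """Repeated k-fold linear regression; one Pearson r per repeat.

    Repeat r uses KFold seeded with ``seed + r`` so that two feature sets
    evaluated with the same ``seed`` share identical splits (required for the
    paired comparison).
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise ValueError("behavioral target has zero variance")
    n = len(y)
    rs = np.empty(n_repeats)
    preds = np.empty((n_repeats, n))
    folds = np.empty((n_repeats, n), dtype=int)
    for rep in range(n_repeats):
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        for k, (tr, te) in enumerate(cv.split(F)):
            pipe = _pc_pipeline(LinearRegression(), n_pc, len(tr), F.shape[1])
            pipe.fit(F[tr], y[tr])
            preds[rep, te] = pipe.predict(F[te])
            folds[rep, te] = k
        rs[rep] = np.corrcoef(preds[rep], y)[0, 1]
    return CvPrediction(fold_assignment=folds, scores=preds, metrics=rs,
                        seeds=tuple(seed + r for r in range(n_repeats)))


def paired_compare(r_A, r_B):
    """Paired t-test across repeats (two-sided).

    Degenerate cases are pinned: identical vectors give (0, 1); a constant
    nonzero difference gives (+/-inf, 0) with a warning.
    """
    a = np.asarray(r_A, dtype=float)
    b = np.asarray(r_B, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metrics must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 paired repeats")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if d.std(ddof=1) <= 1e-12 * max(1.0, float(np.abs(d).max())):
        warnings.warn("zero-variance nonzero difference: t is infinite",
                      stacklevel=2)
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def domain_summary(Y: pd.DataFrame, domain_map: dict) -> pd.DataFrame:
    """One summary score per behavioral domain: the first PC of its items.

    Items are z-scored, PCA is run within the domain, and the first-PC score
    is sign-aligned to correlate positively with the mean of the domain's
    items.  One-item domains pass through z-scored.
    """
    unmapped = [c for c in Y.columns if c not in domain_map]
    if unmapped:
        raise ValueError(f"items without a domain assignment: {unmapped}")
    domains: dict = {}
    for col, dom in domain_map.items():
        if col in Y.columns:
            domains.setdefault(dom, []).append(col)
    out = {}
    for dom, items in domains.items():
        block = Y[items].to_numpy(dtype=float)
        sd = block.std(axis=0)
        Z = (block - block.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        if len(items) == 1:
            score = Z[:, 0]
        else:
            score = PCA(n_components=1, svd_solver="full").fit_transform(Z)[:, 0]
            anchor = Z.mean(axis=1)
            c = np.corrcoef(score, anchor)[0, 1]
            if np.isfinite(c) and c < 0:
                score = -score
        out[dom] = score
    return pd.DataFrame(out, index=Y.index)
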
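"""Cross-session individual identification ("fingerprinting").

Each session-2 feature vector (target) is matched against all session-1
vectors (database) by Pearson correlation; the database subject with the
highest correlation is the predicted identity.  Identification accuracy is
the fraction of subjects whose predicted identity is themselves.  Per-network
analysis repeats the matching on the feature columns of a single network's
ROIs only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FingerprintResult", "identify", "identify_by_network"]


@dataclass
class FingerprintResult:
    """Outcome of one identification run."""

    accuracy: float
    similarity: np.ndarray  # (N, N): rows targets, cols database
    predicted: np.ndarray  # (N,) database index per target
    correct: np.ndarray  # (N,) booleans
    ties: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    n_subjects: int = 0


def _row_corr(targets: np.ndarray, database: np.ndarray) -> np.ndarray:
    """Pearson correlation of every target row with every database row.

    Rows with zero variance get correlation -inf (they can never win a
    match) and trigger a warning.
    """
    t = targets - targets.mean(axis=1, keepdims=True)
    d = database - database.mean(axis=1, keepdims=True)
    tn = np.linalg.norm(t, axis=1)
    dn = np.linalg.norm(d, axis=1)
    bad_t = tn == 0
    bad_d = dn == 0
    if bad_t.any() or bad_d.any():
        warnings.warn("constant feature vector(s): correlations undefined, "
                      "treated as -inf similarity", stacklevel=3)
    tn[bad_t] = 1.0
    dn[bad_d] = 1.0
    r = (t / tn[:, None]) @ (d / dn[:, None]).T
    r[bad_t, :] = -np.inf
    r[:, bad_d] = -np.inf
    return r


def identify(database: np.ndarray, targets: np.ndarray) -> FingerprintResult:
    """Match each target (session 2) to its most correlated database row.

    Ties in the argmax are broken toward the smallest database index and
    flagged.  Accuracy is #{i : argmax_j r_ij = i} / N.
    """
    database = np.asarray(database, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if database.shape != targets.shape:
        raise ValueError("database and targets must share shape and layout")
    n = database.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    r = _row_corr(targets, database)
    predicted = np.argmax(r, axis=1)
    ties = (r == r[np.arange(n), predicted][:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(f"{int(ties.sum())} tied similarity maxima; "
                      "broken toward the smallest index", stacklevel=2)
    correct = predicted == np.arange(n)
    return FingerprintResult(
        accuracy=float(correct.mean()),
        similarity=r,
        predicted=predicted,
        correct=correct,
        ties=ties,
        n_subjects=n,
    )


def identify_by_network(database: np.ndarray, targets: np.ndarray,
                        network_labels, layout) -> dict:
    """Run identification separately on each network's feature columns.

    ``network_labels`` gives one network name per ROI in ``layout.rois``
    order; ``layout`` maps ROIs to feature columns.  Networks with no ROIs
    are skipped with a warning.
    """
    labels = list(network_labels)
    if len(labels) != len(layout.rois):
        raise ValueError("need exactly one network label per ROI")
    results: dict = {}
    for net in dict.fromkeys(labels):  # preserve first-appearance order
        rois = [roi for roi, lab in zip(layout.rois, labels) if lab == net]
        if not rois:
            warnings.warn(f"network {net!r} has no ROIs; skipped", stacklevel=2)
            continue
        cols = layout.columns_for_rois(rois)
        results[net] = identify(database[:, cols], targets[:, cols])
    return results
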
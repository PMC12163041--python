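"""Persistence landscapes and subject-level feature assembly.

A diagram point (b, d) contributes the tent function
Lambda(t) = max(0, min(t - b, d - t)); the k-th landscape layer lambda_k(t)
is the k-th largest tent value at t.  Landscapes are sampled on a fixed grid
shared by every diagram of the same homology dimension so that flattened
vectors are comparable across subjects, then concatenated ROI-major
(H0 block before H1 block per ROI) into one feature vector per
subject-session.  With 200 ROIs and 100 samples per landscape over both
dimensions this yields the canonical 200 x 100 x 2 = 40000-length vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PersistenceLandscape",
    "FeatureLayout",
    "tent",
    "landscape",
    "global_grid",
    "assemble_features",
]


def tent(b: float, d: float, t) -> np.ndarray | float:
    """Tent function of a diagram point: max(0, min(t - b, d - t))."""
    if np.any(np.asarray(b) > np.asarray(d)):
        raise ValueError("birth must not exceed death")
    return np.maximum(0.0, np.minimum(np.asarray(t) - b, d - np.asarray(t)))


@dataclass
class PersistenceLandscape:
    """k layers of a diagram's landscape sampled on a fixed grid."""

    dim: int
    grid: np.ndarray  # (n_bins,) strictly increasing
    values: np.ndarray  # (k, n_bins), rows pointwise nonincreasing

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def flatten(self) -> np.ndarray:
        """Layer-major vector of length k * n_bins."""
        return self.values.ravel()


def landscape(diagram, k: int, grid) -> PersistenceLandscape:
    """Sample the first k landscape layers of a diagram on a grid.

    Layers beyond the number of diagram points are zero; the empty diagram
    yields the all-zero landscape.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    pairs = np.asarray(diagram.pairs, dtype=float).reshape(-1, 2)
    if len(pairs) == 0:
        vals = np.zeros((k, len(grid)))
    else:
        b = pairs[:, 0][:, None]
        d = pairs[:, 1][:, None]
        tents = np.maximum(0.0, np.minimum(grid[None, :] - b, d - grid[None, :]))
        if len(pairs) < k:
            tents = np.vstack([tents, np.zeros((k - len(pairs), len(grid)))])
        # k-th largest value at each grid point
        vals = -np.sort(-tents, axis=0)[:k]
    return PersistenceLandscape(dim=diagram.dim, grid=grid, values=vals)


def global_grid(diagrams, n_bins: int) -> np.ndarray:
    """Uniform grid from 0 to the maximum death across a diagram collection.

    One grid is computed per homology dimension (callers group diagrams by
    dimension) and must be persisted and reused verbatim for held-out data so
    that features share a basis.
    """
    diagrams = list(diagrams)
    max_death = 0.0
    any_pairs = False
    for dgm in diagrams:
        pairs = np.asarray(dgm.pairs).reshape(-1, 2)
        if len(pairs):
            any_pairs = True
            max_death = max(max_death, float(pairs[:, 1].max()))
    if not diagrams or not any_pairs:
        raise ValueError("cannot build a grid from an all-empty diagram collection")
    return np.linspace(0.0, max_death, n_bins)


@dataclass(frozen=True)
class FeatureLayout:
    """Column layout of an assembled feature matrix.

    Columns are ROI-major, then homology dimension (H0 before H1), then
    landscape layer, then grid bin.  ``block_size = k * n_bins`` columns per
    (ROI, dim) cell.
    """

    rois: tuple
    dims: tuple
    k: int
    n_bins: int

    @property
    def block_size(self) -> int:
        return self.k * self.n_bins

    @property
    def n_features(self) -> int:
        return len(self.rois) * len(self.dims) * self.block_size

    def columns_for(self, roi, dim=None) -> np.ndarray:
        """Column indices of one ROI (optionally restricted to one dim)."""
        r = self.rois.index(roi)
        per_roi = len(self.dims) * self.block_size
        base = r * per_roi
        if dim is None:
            return np.arange(base, base + per_roi)
        d = self.dims.index(dim)
        start = base + d * self.block_size
        return np.arange(start, start + self.block_size)

    def columns_for_rois(self, rois) -> np.ndarray:
        return np.concatenate([self.columns_for(r) for r in rois])


def assemble_features(landscapes_by_key: dict, rois, dims=(0, 1)):
    """Concatenate per-(subject, session, roi, dim) landscapes into vectors.

    ``landscapes_by_key`` maps (subject, session, roi, dim) to a
    PersistenceLandscape.  Every (roi, dim) cell must be present for every
    subject-session that appears.  Returns ``(matrix, index, layout)`` where
    ``matrix`` has one row per (subject, session) in sorted ``index`` order.
    """
    rois = tuple(rois)
    dims = tuple(dims)
    keys = sorted({(s, sess) for (s, sess, _, _) in landscapes_by_key})
    if not keys:
        raise ValueError("no landscapes to assemble")
    probe = next(iter(landscapes_by_key.values()))
    layout = FeatureLayout(rois=rois, dims=dims, k=probe.k, n_bins=probe.n_bins)
    mat = np.empty((len(keys), layout.n_features))
    for row, (subj, sess) in enumerate(keys):
        parts = []
        for roi in rois:
            for dim in dims:
                cell = (subj, sess, roi, dim)
                if cell not in landscapes_by_key:
                    raise KeyError(
                        f"missing landscape for subject={subj} session={sess} "
                        f"roi={roi} dim={dim}"
                    )
                parts.append(landscapes_by_key[cell].flatten())
        mat[row] = np.concatenate(parts)
    return mat, keys, layout
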
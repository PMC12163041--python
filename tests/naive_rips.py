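"""Independent brute-force Vietoris-Rips persistence oracle for tests.

Textbook full boundary-matrix reduction over GF(2) with Python sets and no
optimizations: every simplex up to dimension 2 is enumerated, the global
filtration order interleaves dimensions (value, then dimension, then
lexicographic vertices), and columns are reduced left to right.  Entirely
separate code path from the package implementation (no union-find, no
numba, no per-dimension shortcuts), so agreement is meaningful evidence.
"""

from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform


def naive_rips_diagrams(points, max_eps=None):
    """H0 and H1 diagrams by full matrix reduction.

    Returns ``{0: [(b, d), ...], 1: [(b, d), ...]}`` with the essential
    component (and any surviving loops) capped at ``max_eps``; zero-
    persistence H1 pairs are dropped, zero-persistence H0 pairs kept.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    D = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))
    if max_eps is None:
        max_eps = float(D.max()) if n > 1 else 1.0

    simplices = [(0.0, 0, (i,)) for i in range(n)]
    for i, j in combinations(range(n), 2):
        if D[i, j] <= max_eps:
            simplices.append((float(D[i, j]), 1, (i, j)))
    for i, j, k in combinations(range(n), 3):
        val = max(D[i, j], D[i, k], D[j, k])
        if val <= max_eps:
            simplices.append((float(val), 2, (i, j, k)))
    simplices.sort()
    index = {s[2]: idx for idx, s in enumerate(simplices)}

    columns = {}
    low_inv = {}
    pairs = []
    for j, (val, dim, verts) in enumerate(simplices):
        col = set()
        if dim > 0:
            for facet in combinations(verts, dim):
                col ^= {index[facet]}
        while col:
            low = max(col)
            if low in low_inv:
                col ^= columns[low_inv[low]]
            else:
                break
        columns[j] = col
        if col:
            low = max(col)
            low_inv[low] = j
            pairs.append((low, j))

    paired = {i for i, _ in pairs} | {j for _, j in pairs}
    diagrams = {0: [], 1: []}
    for i, j in pairs:
        birth_val, birth_dim, _ = simplices[i]
        death_val = simplices[j][0]
        if birth_dim == 0:
            diagrams[0].append((birth_val, death_val))
        elif birth_dim == 1 and death_val > birth_val:
            diagrams[1].append((birth_val, death_val))
    for idx, (val, dim, _) in enumerate(simplices):
        if idx not in paired and not columns[idx] and dim < 2:
            if dim == 0:
                diagrams[0].append((val, max_eps))
            elif val < max_eps:
                diagrams[1].append((val, max_eps))
    diagrams[0].sort()
    diagrams[1].sort()
    return diagrams


def match_diagrams(a, b, tol=1e-6):
    """True if two (birth, death) multisets agree endpoint-wise within tol."""
    a = sorted(map(tuple, a))
    b = sorted(map(tuple, b))
    if len(a) != len(b):
        return False
    return all(abs(x - u) <= tol and abs(y - v) <= tol
               for (x, y), (u, v) in zip(a, b))
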
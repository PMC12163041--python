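"""Vietoris-Rips persistent homology in dimensions 0 and 1.

Computes persistence diagrams of a Euclidean point cloud under the
Vietoris-Rips filtration: a simplex enters the complex at the length of its
longest edge.  H0 (connected components) is computed by Kruskal-style
union-find over distance-sorted point pairs; H1 (loops) by reduction of the
edge/triangle boundary matrix over GF(2) in filtration order.

Conventions
-----------
* The filtration value of a simplex is its longest pairwise distance
  (closed threshold); ties are broken by lexicographic vertex order.
* Every H0 class is born at 0.  The essential component is capped at
  ``max_eps`` so that downstream landscape vectorization sees finite deaths;
  the cap is recorded on the diagram.
* H1 bars of zero persistence are discarded.  H1 classes still alive at
  ``max_eps`` (possible only when ``max_eps`` is below the cloud diameter)
  are capped at ``max_eps``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PersistenceDiagram",
    "rips_h0",
    "rips_h1",
    "landmark_subsample",
]


@dataclass
class PersistenceDiagram:
    """Multiset of (birth, death) pairs for one homology dimension.

    ``pairs`` is an (k, 2) float array with ``0 <= birth <= death <= max_eps``.
    """

    dim: int
    pairs: np.ndarray
    max_eps: float
    source: tuple = field(default=())

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)

    @property
    def persistence(self) -> np.ndarray:
        return self.pairs[:, 1] - self.pairs[:, 0]

    def __len__(self) -> int:
        return len(self.pairs)


def _as_points(cloud) -> np.ndarray:
    pts = getattr(cloud, "points", cloud)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    return pts


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _sorted_edges(dmat: np.ndarray):
    """Edges (i<j) sorted by (length, i, j)."""
    n = dmat.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = dmat[iu, ju]
    order = np.lexsort((ju, iu, d))
    return iu[order], ju[order], d[order]


def rips_h0(cloud, max_eps: float | None = None, source: tuple = ()) -> PersistenceDiagram:
    """H0 persistence diagram: one bar per point.

    Finite deaths are the minimum-spanning-tree edge weights; the essential
    component is capped at ``max_eps``.  Duplicate points yield bars of zero
    persistence (death 0), which are kept.
    """
    pts = _as_points(cloud)
    n = pts.shape[0]
    if n == 0:
        raise ValueError("empty point cloud")
    dmat = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))
    if max_eps is None:
        max_eps = float(dmat.max()) if n > 1 else 1.0
    if max_eps <= 0:
        raise ValueError("max_eps must be positive")
    uf = _UnionFind(n)
    deaths = []
    for i, j, d in zip(*_sorted_edges(dmat)):
        if uf.union(int(i), int(j)):
            deaths.append(min(float(d), max_eps))
            if len(deaths) == n - 1:
                break
    deaths.append(max_eps)  # essential component, capped
    pairs = np.column_stack([np.zeros(n), np.sort(deaths)])
    return PersistenceDiagram(dim=0, pairs=pairs, max_eps=float(max_eps), source=source)


@njit(cache=True)
def _count_triangles(dmat, max_eps):  # pragma: no cover - numba
    n = dmat.shape[0]
    cnt = 0
    for i in range(n):
        for j in range(i + 1, n):
            if dmat[i, j] > max_eps:
                continue
            for k in range(j + 1, n):
                if dmat[i, k] <= max_eps and dmat[j, k] <= max_eps:
                    cnt += 1
    return cnt


@njit(cache=True)
def _fill_triangles(dmat, max_eps, ti, tj, tk, tval):  # pragma: no cover - numba
    n = dmat.shape[0]
    c = 0
    for i in range(n):
        for j in range(i + 1, n):
            dij = dmat[i, j]
            if dij > max_eps:
                continue
            for k in range(j + 1, n):
                dik = dmat[i, k]
                djk = dmat[j, k]
                if dik <= max_eps and djk <= max_eps:
                    ti[c] = i
                    tj[c] = j
                    tk[c] = k
                    v = dij
                    if dik > v:
                        v = dik
                    if djk > v:
                        v = djk
                    tval[c] = v
                    c += 1


@njit(cache=True)
def _reduce_h1(tri_e1, tri_e2, tri_e3, n_edges):  # pragma: no cover - numba
    """Column reduction of the triangle boundary matrix over GF(2).

    Triangle columns arrive in filtration order; rows are edge ranks in
    filtration order.  Returns, per triangle, the pivot edge rank it pairs
    with (-1 if the column reduces to zero).  Standard left-to-right
    reduction with stored reduced columns; edge columns never need reducing
    because H0 is handled separately by union-find.
    """
    nt = tri_e1.shape[0]
    pivot_owner = np.full(n_edges, -1, dtype=np.int64)
    tri_pivot = np.full(nt, -1, dtype=np.int64)
    # reduced columns stored in a flat pool
    cap = max(16, nt * 4)
    pool = np.empty(cap, dtype=np.int64)
    col_start = np.empty(nt, dtype=np.int64)
    col_len = np.zeros(nt, dtype=np.int64)
    pool_used = 0
    work = np.empty(max(16, n_edges), dtype=np.int64)
    buf = np.empty(max(16, n_edges), dtype=np.int64)

    for t in range(nt):
        # initial column: the triangle's three edges, ascending rank
        a, b, c = tri_e1[t], tri_e2[t], tri_e3[t]
        if a > b:
            a, b = b, a
        if b > c:
            b, c = c, b
        if a > b:
            a, b = b, a
        work[0], work[1], work[2] = a, b, c
        wlen = 3
        while wlen > 0:
            piv = work[wlen - 1]
            owner = pivot_owner[piv]
            if owner == -1:
                pivot_owner[piv] = t
                tri_pivot[t] = piv
                if pool_used + wlen > cap:
                    newcap = cap * 2
                    while newcap < pool_used + wlen:
                        newcap *= 2
                    newpool = np.empty(newcap, dtype=np.int64)
                    newpool[:pool_used] = pool[:pool_used]
                    pool = newpool
                    cap = newcap
                col_start[t] = pool_used
                col_len[t] = wlen
                pool[pool_used : pool_used + wlen] = work[:wlen]
                pool_used += wlen
                break
            # symmetric difference with the owner's stored column
            os = col_start[owner]
            ol = col_len[owner]
            i1 = 0
            i2 = 0
            m = 0
            while i1 < wlen and i2 < ol:
                v1 = work[i1]
                v2 = pool[os + i2]
                if v1 < v2:
                    buf[m] = v1
                    m += 1
                    i1 += 1
                elif v2 < v1:
                    buf[m] = v2
                    m += 1
                    i2 += 1
                else:
                    i1 += 1
                    i2 += 1
            while i1 < wlen:
                buf[m] = work[i1]
                m += 1
                i1 += 1
            while i2 < ol:
                buf[m] = pool[os + i2]
                m += 1
                i2 += 1
            work[:m] = buf[:m]
            wlen = m
    return tri_pivot


def rips_h1(cloud, max_eps: float | None = None, source: tuple = ()) -> PersistenceDiagram:
    """H1 persistence diagram of the Vietoris-Rips filtration.

    Loops are born at the length of the cycle-creating edge and die at the
    filtration value of the triangle whose reduced boundary column pivots on
    that edge.  Clouds with fewer than 3 points have no loops and yield an
    empty diagram.
    """
    pts = _as_points(cloud)
    n = pts.shape[0]
    if n < 3:
        return PersistenceDiagram(dim=1, pairs=np.empty((0, 2)),
                                  max_eps=float(max_eps or 0.0), source=source)
    dmat = squareform(pdist(pts))
    if max_eps is None:
        max_eps = float(dmat.max())
    if max_eps <= 0:
        raise ValueError("max_eps must be positive")
    # Beyond the enclosing radius (min over points of its max distance) the
    # complex is a cone, hence has no 1-cycles: truncating there leaves the
    # H1 diagram unchanged while shrinking the filtration substantially.
    eff_eps = min(max_eps, float(dmat.max(axis=1).min()))

    ei, ej, ed = _sorted_edges(dmat)
    keep = ed <= eff_eps
    ei, ej, ed = ei[keep], ej[keep], ed[keep]
    n_edges = len(ed)
    # rank lookup: pair (i,j) -> filtration rank of that edge
    rank = np.full((n, n), -1, dtype=np.int64)
    rank[ei, ej] = np.arange(n_edges)
    rank[ej, ei] = np.arange(n_edges)
    nt = int(_count_triangles(dmat, eff_eps))
    bars: list[tuple[float, float]] = []
    pivot_edges: set[int] = set()
    if nt > 0:
        ti = np.empty(nt, dtype=np.int64)
        tj = np.empty(nt, dtype=np.int64)
        tk = np.empty(nt, dtype=np.int64)
        tval = np.empty(nt, dtype=float)
        _fill_triangles(dmat, eff_eps, ti, tj, tk, tval)
        order = np.lexsort((tk, tj, ti, tval))
        ti, tj, tk, tval = ti[order], tj[order], tk[order], tval[order]
        e1 = rank[ti, tj]
        e2 = rank[ti, tk]
        e3 = rank[tj, tk]
        tri_pivot = _reduce_h1(e1, e2, e3, n_edges)
        paired = tri_pivot >= 0
        births = ed[tri_pivot[paired]]
        deaths = tval[paired]
        pos = deaths > births
        bars.extend(zip(births[pos], deaths[pos]))
        pivot_edges = set(int(p) for p in tri_pivot[paired])

    # essential loops: cycle-creating edges never killed by a triangle
    # (possible only when the user capped max_eps below the enclosing radius)
    uf = _UnionFind(n)
    for r in range(n_edges):
        if not uf.union(int(ei[r]), int(ej[r])) and r not in pivot_edges:
            if ed[r] < max_eps:
                bars.append((float(ed[r]), float(max_eps)))

    pairs = np.array(sorted(bars)) if bars else np.empty((0, 2))
    return PersistenceDiagram(dim=1, pairs=pairs, max_eps=float(max_eps), source=source)


def landmark_subsample(cloud, n_max: int = 300, seed: int = 0):
    """Maxmin (farthest-point) landmark selection down to ``n_max`` points.

    Starts from a seeded random point and greedily adds the point farthest
    from the current landmark set.  Identity when the cloud already has at
    most ``n_max`` points.  Deterministic given ``seed``.
    """
    if n_max < 3:
        raise ValueError("n_max must be at least 3")
    pts = _as_points(cloud)
    n = pts.shape[0]
    if n <= n_max:
        return cloud
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    chosen = np.empty(n_max, dtype=np.int64)
    chosen[0] = start
    mind = np.linalg.norm(pts - pts[start], axis=1)
    for k in range(1, n_max):
        nxt = int(np.argmax(mind))
        chosen[k] = nxt
        np.minimum(mind, np.linalg.norm(pts - pts[nxt], axis=1), out=mind)
    sub = pts[np.sort(chosen)]
    src = getattr(cloud, "source", None)
    if src is not None and hasattr(cloud, "points"):
        return type(cloud)(points=sub, source=src)
    return sub


def warm_up() -> None:
    """Trigger numba compilation on a trivial cloud (call once per process)."""
    tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    rips_h1(tri)
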
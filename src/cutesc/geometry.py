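"""Proximity-graph substrate: Delaunay triangulation, Gabriel graph, edge statistics.

The clustering pipeline cuts edges of the Gabriel graph, a subgraph of the
Delaunay triangulation that keeps an edge (u, v) iff no third point lies
strictly inside the disk whose diameter is the segment uv.  All cut
thresholds are driven by edge-length statistics computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, cKDTree

from .exceptions import (
    DegenerateInputError,
    DuplicatePointsError,
    StatisticsUndefinedError,
)

__all__ = [
    "PointSet",
    "ProximityGraph",
    "EdgeStats",
    "delaunay_edges",
    "gabriel_filter",
    "edge_statistics",
]


@dataclass(frozen=True)
class PointSet:
    """An ordered set of d-dimensional points; row index = vertex id.

    Coordinates must be finite; the row order is stable and defines the
    vertex ids 0..n-1 used by every graph built on top.
    """

    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise ValueError(f"coords must be 2-D (n, d), got shape {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("point set must contain at least one point")
        if not np.all(np.isfinite(coords)):
            bad = np.argwhere(~np.isfinite(coords))[0]
            raise ValueError(
                f"non-finite coordinate at point {bad[0]}, axis {bad[1]}"
            )
        coords = coords.copy()
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def subset(self, indices: np.ndarray) -> "PointSet":
        return PointSet(self.coords[np.asarray(indices)])


@dataclass(frozen=True)
class ProximityGraph:
    """Undirected weighted graph on vertices 0..n-1.

    ``edges`` is an (m, 2) integer array with u < v in every row, rows in
    lexicographic order; ``weights[i]`` is the Euclidean length of edge i.
    The canonical ordering makes graphs comparable and output deterministic.
    """

    n: int
    edges: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if edges.shape[0] != weights.shape[0]:
            raise ValueError("edges and weights length mismatch")
        if edges.size:
            if edges.min() < 0 or edges.max() >= self.n:
                raise ValueError("edge endpoint out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loop in edge list")
        edges = np.sort(edges, axis=1)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges, weights = edges[order], weights[order]
        if edges.shape[0] > 1 and np.any(np.all(np.diff(edges, axis=0) == 0, axis=1)):
            raise ValueError("duplicate edge in edge list")
        edges.setflags(write=False)
        weights.setflags(write=False)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "weights", weights)

    @property
    def m(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        if self.m:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def incident_edges(self) -> list[np.ndarray]:
        """Per-vertex array of incident edge indices."""
        inc: list[list[int]] = [[] for _ in range(self.n)]
        for i, (u, v) in enumerate(self.edges):
            inc[u].append(i)
            inc[v].append(i)
        return [np.asarray(a, dtype=np.int64) for a in inc]

    def neighbors(self) -> list[np.ndarray]:
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return [np.asarray(a, dtype=np.int64) for a in adj]

    def component_labels(self) -> np.ndarray:
        if self.m == 0:
            return np.arange(self.n, dtype=np.int64)
        mat = sparse.coo_matrix(
            (np.ones(self.m), (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n, self.n),
        )
        _, labels = connected_components(mat, directed=False)
        return labels.astype(np.int64)

    def keep_edges(self, mask: np.ndarray) -> "ProximityGraph":
        """Subgraph on the same vertex set keeping edges where mask is True."""
        mask = np.asarray(mask, dtype=bool)
        return ProximityGraph(self.n, self.edges[mask], self.weights[mask])

    def to_edgelist(self) -> str:
        """Serialize as `u v weight` lines (0-based ids), for debugging."""
        lines = [
            f"{u} {v} {w:.17g}" for (u, v), w in zip(self.edges, self.weights)
        ]
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_coords(cls, coords: np.ndarray, edges: np.ndarray) -> "ProximityGraph":
        coords = np.asarray(coords, dtype=float)
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        w = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
        return cls(coords.shape[0], edges, w)


@dataclass(frozen=True)
class EdgeStats:
    """Edge-length summary statistics over a scope of a graph.

    ``local_mean``/``local_std`` are full-length arrays indexed by vertex id,
    NaN for vertices outside the scope or with no in-scope incident edge.
    Standard deviations are population (divide by N) so that a single
    observation has a well-defined spread of zero.
    """

    global_mean: float
    global_std: float
    local_mean: np.ndarray
    local_std: np.ndarray
    mean_local_std: float


def delaunay_edges(points: PointSet) -> ProximityGraph:
    """Edge set of the Delaunay triangulation of ``points``.

    Raises :class:`DegenerateInputError` for fewer than d+1 affinely
    independent points and :class:`DuplicatePointsError` for coincident
    points, which would otherwise create zero-length edges that poison the
    length statistics downstream.
    """
    coords = points.coords
    if points.d < 2:
        raise DegenerateInputError("triangulation requires dimensionality >= 2")
    if points.n < points.d + 1:
        raise DegenerateInputError(
            f"need at least {points.d + 1} points in dimension {points.d}, "
            f"got {points.n}"
        )
    _, inverse, counts = np.unique(
        coords, axis=0, return_inverse=True, return_counts=True
    )
    if np.any(counts > 1):
        dup_groups = np.flatnonzero(counts > 1)
        dup_idx = np.flatnonzero(np.isin(inverse, dup_groups))
        raise DuplicatePointsError(dup_idx.tolist())
    try:
        tri = Delaunay(coords)
    except QhullError as exc:
        raise DegenerateInputError(
            f"degenerate point configuration (affinely dependent input in "
            f"dimension {points.d}): {str(exc).splitlines()[0]}"
        ) from exc
    pairs = set()
    for simplex in tri.simplices:
        for u, v in combinations(sorted(int(i) for i in simplex), 2):
            pairs.add((u, v))
    edges = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    return ProximityGraph.from_coords(coords, edges)


def gabriel_filter(points: PointSet, g: ProximityGraph) -> ProximityGraph:
    """Keep edge (u, v) iff no third point lies strictly inside its diametral disk.

    Points exactly on the bounding circle do not block the edge, which keeps
    cocircular configurations stable and preserves Gabriel ⊆ Delaunay.
    """
    if g.m == 0:
        return g
    coords = points.coords
    mids = 0.5 * (coords[g.edges[:, 0]] + coords[g.edges[:, 1]])
    radii = 0.5 * g.weights
    tree = cKDTree(coords)
    # inflate the query radius slightly; strictness is enforced exactly below
    hits = tree.query_ball_point(mids, radii * (1 + 1e-12))
    keep = np.ones(g.m, dtype=bool)
    for i, cand in enumerate(hits):
        u, v = g.edges[i]
        r2 = radii[i] ** 2
        for p in cand:
            if p == u or p == v:
                continue
            if np.sum((coords[p] - mids[i]) ** 2) < r2:
                keep[i] = False
                break
    return g.keep_edges(keep)


def _in_scope_mask(g: ProximityGraph, scope) -> np.ndarray:
    if isinstance(scope, str):
        if scope != "all":
            raise ValueError(f"unknown scope {scope!r}")
        return np.ones(g.n, dtype=bool)
    scope = np.asarray(scope)
    if scope.dtype == bool:
        if scope.shape != (g.n,):
            raise ValueError("boolean scope mask must have length n")
        return scope
    mask = np.zeros(g.n, dtype=bool)
    mask[scope.astype(np.int64)] = True
    return mask


def edge_statistics(g: ProximityGraph, scope="all") -> EdgeStats:
    """Edge-length statistics over the subgraph induced by ``scope``.

    Global statistics cover edges with both endpoints in scope; local
    statistics cover each in-scope vertex's in-scope incident edges.
    Raises :class:`StatisticsUndefinedError` when the scope induces no edge.
    """
    vmask = _in_scope_mask(g, scope)
    if not vmask.any():
        raise StatisticsUndefinedError("empty scope")
    emask = vmask[g.edges[:, 0]] & vmask[g.edges[:, 1]] if g.m else np.zeros(0, bool)
    if not emask.any():
        raise StatisticsUndefinedError("scope induces no edges")
    w = g.weights[emask]
    eu, ev = g.edges[emask, 0], g.edges[emask, 1]

    deg = np.zeros(g.n, dtype=np.int64)
    np.add.at(deg, eu, 1)
    np.add.at(deg, ev, 1)
    s1 = np.zeros(g.n)
    np.add.at(s1, eu, w)
    np.add.at(s1, ev, w)
    s2 = np.zeros(g.n)
    np.add.at(s2, eu, w**2)
    np.add.at(s2, ev, w**2)

    local_mean = np.full(g.n, np.nan)
    local_std = np.full(g.n, np.nan)
    has = deg > 0
    local_mean[has] = s1[has] / deg[has]
    var = np.clip(s2[has] / deg[has] - local_mean[has] ** 2, 0.0, None)
    local_std[has] = np.sqrt(var)

    return EdgeStats(
        global_mean=float(np.mean(w)),
        global_std=float(np.std(w)),
        local_mean=local_mean,
        local_std=local_std,
        mean_local_std=float(np.mean(local_std[has])),
    )
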
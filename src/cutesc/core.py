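"""The edge-cutting hierarchy and cluster extraction.

Clustering proceeds top-down on the Gabriel graph through three cutting
criteria applied in a strict order:

1. **global cut** — edges long with respect to the whole graph's length
   distribution (large-scale effect);
2. **component-local cut** — within each connected component left by stage 1,
   edges long with respect to that component's statistics (small-scale
   effect);
3. **second-order-neighborhood cut** — a pruning step scoped to each vertex's
   2-hop neighborhood that resolves "touching" problems (thin chains and
   necks joining genuinely distinct clusters) the coarser scopes cannot see.

Connected components of the final graph that reach a minimum size become
clusters; smaller components are labeled outliers (sentinel -1).  The
parametric variant (CutESC-P) exposes weights alpha (global cut) and beta
(local cut); the parameter-free algorithm (CutESC) is the alpha = beta = 1
fixed point.

Every stage computes all of its removals from a frozen snapshot of the graph
and applies them afterwards, so the output never depends on edge iteration
order.  Thresholds are compared strictly, so a zero-spread scope removes
nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, StatisticsUndefinedError, UndefinedScoreError
from .geometry import EdgeStats, PointSet, ProximityGraph, delaunay_edges, edge_statistics, gabriel_filter

__all__ = [
    "CutParams",
    "ClusterLabeling",
    "LevelTrace",
    "OUTLIER",
    "cut_global_edges",
    "cut_local_edges",
    "cut_local_inner_edges",
    "label_components",
    "cutesc_p",
    "cutesc",
    "iterative_cutesc",
]

OUTLIER = -1

DEFAULT_MIN_CLUSTER_SIZE = 3


@dataclass(frozen=True)
class CutParams:
    """Parameters of the parametric variant (CutESC-P).

    alpha
        Weight on the global cut threshold; larger keeps more long edges.
    beta
        Weight on the component-local cut threshold.
    min_cluster_size
        Components smaller than this become outliers.
    iterate, max_levels
        Enable the Calinski-Harabasz-guided iterative driver and bound its
        depth.
    """

    alpha: float = 1.0
    beta: float = 1.0
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
    iterate: bool = False
    max_levels: int = 5

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")


@dataclass(frozen=True)
class ClusterLabeling:
    """Per-point cluster assignment; ids 0..k-1 plus the outlier sentinel -1.

    Cluster ids are ordered by decreasing size (ties broken by the smallest
    contained vertex id), so the labeling is deterministic and stable under
    permutations of internal processing order.  ``per_stage_groups`` records
    the number of groups (components of at least ``min_cluster_size`` points)
    after each of the three cutting criteria.
    """

    labels: np.ndarray
    k: int
    per_stage_groups: tuple[int, int, int] | None = None

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        labels.setflags(write=False)
        object.__setattr__(self, "labels", labels)

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.labels == OUTLIER))


@dataclass(frozen=True)
class LevelTrace:
    """Trace of the iterative driver: one entry per explored level.

    ``cluster_counts[i]`` and ``scores[i]`` describe level i+1;
    ``scores`` entries are NaN where the Calinski-Harabasz score is
    undefined (fewer than 2 clusters).  ``accepted_level`` is 1-based.
    """

    labelings: tuple[ClusterLabeling, ...]
    cluster_counts: tuple[int, ...]
    scores: tuple[float, ...]
    accepted_level: int

    @property
    def accepted(self) -> ClusterLabeling:
        return self.labelings[self.accepted_level - 1]


# ---------------------------------------------------------------------------
# threshold policies (the seam: swap these to change the cut statistics)
#
# Every stage compares edge lengths against a scoped statistical threshold,
# but each stage judges from a different vantage point:
#
# * stage 1 judges against whole-graph statistics, with per-vertex local
#   means left "polluted" by the edge under test — a globally long edge
#   inflates its own endpoints' means, lowering their tolerance, which is
#   precisely what flags it;
# * stage 2 judges against component statistics using each endpoint's
#   nearest-neighbour distance as its scale, which is immune to that
#   pollution (a long edge is never its endpoint's shortest);
# * stage 3 judges each vertex's edges against the mean edge length of its
#   2-hop neighbourhood inflated by that neighbourhood's length spread, so
#   a uniform neighbourhood tolerates almost no excess while a noisy one
#   tolerates a lot.
#
# Stages 1 and 2 cut an edge only when it is long from BOTH endpoints'
# perspectives: a point whose every edge is long (an isolated straggler)
# never votes to disconnect itself, which keeps outlier handling in the
# component-size rule where it belongs.  Stage 3 cuts from either side —
# that one-sidedness is what lets it sever chains and necks whose far
# endpoint considers the edge normal.
# ---------------------------------------------------------------------------

GLOBAL_MARGIN = 2.0
"""Widening factor on the global-cut margin (stage 1)."""

LOCAL_SCALE_MARGIN = 1.5
"""Weight of the nearest-neighbour scale in the component-cut threshold
(stage 2)."""

NEIGHBORHOOD_MARGIN = 8.0
"""Spread multiplier of the 2-hop pruning threshold (stage 3)."""


def _nearest_neighbor_dist(g: ProximityGraph, emask: np.ndarray) -> np.ndarray:
    """Per-vertex minimum in-scope incident edge length (inf if none)."""
    nn = np.full(g.n, np.inf)
    for col in (0, 1):
        np.minimum.at(nn, g.edges[emask, col], g.weights[emask])
    return nn


# ---------------------------------------------------------------------------
# cutting stages
# ---------------------------------------------------------------------------

def cut_global_edges(g: ProximityGraph, stats: EdgeStats, alpha: float) -> ProximityGraph:
    """Stage 1: remove edges long at the scale of the whole graph.

    The per-vertex threshold is ``g_mean + alpha * GLOBAL_MARGIN *
    (g_mean / local_mean(v)) * g_std``: a vertex whose local mean is
    inflated (because a long edge hangs off it) tolerates less, and an edge
    is removed only when it exceeds both endpoints' thresholds.
    """
    if g.m == 0:
        warnings.warn("global cut on an edgeless graph is a no-op")
        return g
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.global_mean + alpha * GLOBAL_MARGIN * (
            stats.global_mean / stats.local_mean
        ) * stats.global_std
    te = np.maximum(t[g.edges[:, 0]], t[g.edges[:, 1]])
    return g.keep_edges(~(g.weights > te))


def cut_local_edges(g: ProximityGraph, beta: float) -> ProximityGraph:
    """Stage 2: within each connected component, remove edges long relative
    to both endpoints' nearest-neighbour scale.

    The threshold for endpoint v in component C is
    ``(1 + LOCAL_SCALE_MARGIN * beta) * nn(v) + beta * edge_std(C)``
    where nn(v) is v's shortest in-component edge; the
    edge must exceed the threshold of BOTH endpoints.  Judging by the
    shortest incident edge makes the test immune to the self-inflation that
    long edges exert on plain local means, which matters when a component's
    length distribution is bimodal (parallel dense structures bridged by
    many comparable long edges).  Components are processed from a frozen
    snapshot; a single-edge component can never cut (threshold >= weight).
    """
    if g.m == 0:
        return g
    comp = g.component_labels()
    cut = np.zeros(g.m, dtype=bool)
    for c in np.unique(comp[g.edges[:, 0]]):
        scope = comp == c
        emask = scope[g.edges[:, 0]] & scope[g.edges[:, 1]]
        if not emask.any():
            continue
        stats = edge_statistics(g, scope)
        nn = _nearest_neighbor_dist(g, emask)
        t = (1.0 + LOCAL_SCALE_MARGIN * beta) * nn + beta * stats.global_std
        te = np.maximum(t[g.edges[:, 0]], t[g.edges[:, 1]])
        cut |= emask & (g.weights > te)
    return g.keep_edges(~cut)


def cut_local_inner_edges(g: ProximityGraph) -> ProximityGraph:
    """Stage 3: prune edges long relative to their 2-hop neighbourhood.

    For each vertex v with degree >= 2, edge statistics are recomputed on
    the subgraph induced by the vertices within graph distance 2 of v; an
    incident edge is removed when it exceeds the neighbourhood's mean edge
    length plus ``NEIGHBORHOOD_MARGIN`` times its mean local spread.  A
    homogeneous neighbourhood therefore tolerates almost no excess — which
    is what severs the thin chains and necks joining touching clusters —
    while a heterogeneous one is left alone.  The sweep is evaluated from a
    frozen snapshot and all removals are applied at the end.
    """
    if g.m == 0:
        return g
    adj = g.neighbors()
    inc = g.incident_edges()
    cut = np.zeros(g.m, dtype=bool)
    for v in range(g.n):
        if adj[v].size < 2:
            continue
        members = set(adj[v].tolist())
        members.add(v)
        for u in adj[v]:
            members.update(adj[u].tolist())
        scope = np.fromiter(members, dtype=np.int64)
        try:
            stats = edge_statistics(g, scope)
        except StatisticsUndefinedError:
            continue
        threshold = stats.global_mean + NEIGHBORHOOD_MARGIN * stats.mean_local_std
        for ei in inc[v]:
            if g.weights[ei] > threshold:
                cut[ei] = True
    return g.keep_edges(~cut)


def _component_sizes(g: ProximityGraph) -> tuple[np.ndarray, np.ndarray]:
    comp = g.component_labels()
    sizes = np.bincount(comp)
    return comp, sizes


def count_groups(g: ProximityGraph, min_cluster_size: int) -> int:
    """Number of connected components with at least ``min_cluster_size`` points."""
    _, sizes = _component_sizes(g)
    return int(np.sum(sizes >= min_cluster_size))


def label_components(g: ProximityGraph, min_cluster_size: int) -> ClusterLabeling:
    """Turn connected components into clusters; small components become outliers.

    Clusters are numbered 0..k-1 by decreasing size, ties broken by the
    smallest contained vertex id.
    """
    comp, sizes = _component_sizes(g)
    first_vertex = np.full(sizes.shape, g.n, dtype=np.int64)
    for v in range(g.n - 1, -1, -1):
        first_vertex[comp[v]] = v
    big = np.flatnonzero(sizes >= min_cluster_size)
    order = sorted(big, key=lambda c: (-int(sizes[c]), int(first_vertex[c])))
    remap = np.full(sizes.shape, OUTLIER, dtype=np.int64)
    for new_id, c in enumerate(order):
        remap[c] = new_id
    return ClusterLabeling(labels=remap[comp], k=len(order))


def cutesc_p(points: PointSet, params: CutParams | None = None) -> ClusterLabeling:
    """Run the full parametric pipeline on a point set.

    Delaunay triangulation → Gabriel filter → global cut (alpha) →
    component-local cut (beta) → 2-hop-neighborhood cut → component
    labeling.  ``per_stage_groups`` on the result records the group count
    after each cutting stage.
    """
    params = params or CutParams()
    g = gabriel_filter(points, delaunay_edges(points))
    stats = edge_statistics(g)
    g1 = cut_global_edges(g, stats, params.alpha)
    g2 = cut_local_edges(g1, params.beta)
    g3 = cut_local_inner_edges(g2)
    labeling = label_components(g3, params.min_cluster_size)
    groups = tuple(
        count_groups(stage, params.min_cluster_size) for stage in (g1, g2, g3)
    )
    return ClusterLabeling(
        labels=labeling.labels, k=labeling.k, per_stage_groups=groups
    )


def cutesc(points: PointSet, min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE) -> ClusterLabeling:
    """Parameter-free clustering: the alpha = beta = 1 fixed point of cutesc_p."""
    return cutesc_p(
        points, CutParams(alpha=1.0, beta=1.0, min_cluster_size=min_cluster_size)
    )


def _calinski_harabasz_or_nan(points: PointSet, labels: np.ndarray) -> float:
    from .metrics import calinski_harabasz

    try:
        return calinski_harabasz(points, labels)
    except UndefinedScoreError:
        return float("nan")


def iterative_cutesc(points: PointSet, params: CutParams | None = None) -> LevelTrace:
    """Calinski-Harabasz-guided nested clustering.

    Level 1 clusters the full point set; level l+1 re-runs the pipeline
    independently inside each level-l cluster and concatenates the results
    (outliers stay outliers).  Each level's labeling is scored on the full
    point set with outliers excluded; descent continues while the score
    strictly increases, so a plateau or an undefined score stops it.  The
    trace keeps the first rejected level so the caller can see why descent
    stopped.
    """
    params = params or CutParams(iterate=True)
    labelings: list[ClusterLabeling] = []
    counts: list[int] = []
    scores: list[float] = []

    current = cutesc_p(points, params)
    labelings.append(current)
    counts.append(current.k)
    scores.append(_calinski_harabasz_or_nan(points, current.labels))
    accepted = 1

    while len(labelings) < params.max_levels:
        prev = labelings[-1]
        new_labels = np.full(points.n, OUTLIER, dtype=np.int64)
        next_id = 0
        split_any = False
        for c in range(prev.k):
            idx = np.flatnonzero(prev.labels == c)
            sub_labels = None
            if idx.size >= max(points.d + 1, params.min_cluster_size):
                try:
                    sub = cutesc_p(points.subset(idx), params)
                    # a single-cluster sub-result means no nested structure;
                    # keep the cluster whole rather than promoting its
                    # stragglers to outliers, which would shrink the scored
                    # point set and bias the level comparison
                    if sub.k >= 2:
                        sub_labels = sub.labels
                except DegenerateInputError:
                    sub_labels = None
            if sub_labels is None:
                new_labels[idx] = next_id
                next_id += 1
                continue
            split_any = True
            for s in np.unique(sub_labels[sub_labels >= 0]):
                new_labels[idx[sub_labels == s]] = next_id
                next_id += 1
        labeling = ClusterLabeling(labels=new_labels, k=next_id)
        labelings.append(labeling)
        counts.append(labeling.k)
        score = _calinski_harabasz_or_nan(points, new_labels)
        scores.append(score)
        prev_score = scores[len(labelings) - 2]
        improved = (
            np.isfinite(score)
            and np.isfinite(prev_score)
            and score > prev_score
        )
        if not improved:
            break
        accepted = len(labelings)
        if not split_any:
            break

    return LevelTrace(
        labelings=tuple(labelings),
        cluster_counts=tuple(counts),
        scores=tuple(scores),
        accepted_level=accepted,
    )
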
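# Methods

## The model

`cutesc` clusters a finite set of points in R^d by carving a proximity
graph.  The substrate is the Gabriel graph: the subgraph of the Delaunay
triangulation that keeps an edge (u, v) iff no third point lies strictly
inside the disk whose diameter is the segment uv.  The Gabriel graph
connects exactly the pairs of points that are "neighbours with nothing
between them", so clusters appear as densely connected regions joined to
other clusters by statistically long edges.  Clustering then reduces to
deciding which edges are long, removing them, and reading off connected
components.  Components smaller than `min_cluster_size` (default 3, the
smallest component with non-trivial internal structure) are labelled
outliers with the sentinel −1.

Long edges are removed in three passes of strictly decreasing scope, and
the order is part of the model:

1. **Global cut** (weight α) — edges long at the scale of the whole
   dataset (bridges between well-separated clusters).
2. **Component cut** (weight β) — within each connected component left by
   pass 1, edges long at the component's scale (sub-group boundaries that
   a heterogeneous dataset hides from the global statistics).
3. **Neighbourhood cut** — within each vertex's 2-hop neighbourhood, a
   parameter-free pruning pass that resolves "touching" configurations:
   thin chains and necks whose edges are only anomalous at the most local
   scale.

The parameter-free algorithm (`cutesc`) is the α = β = 1 case of the
parametric one (`cutesc_p`); α and β only scale the margins of passes 1
and 2.

## Threshold statistics

All passes consume the same scoped summary statistics of edge length: the
scope's mean and population standard deviation over edges (`g_mean`,
`g_std`), each vertex's mean and population standard deviation over its
incident in-scope edges (`local_mean`, `local_std`), and the scope mean of
the per-vertex standard deviations (`mean_local_std`).  Population (÷N)
normalisation keeps single-observation scopes well defined (spread 0).
All statistics are computed on the Gabriel graph, the graph actually cut.
Every comparison is strict, so a zero-spread scope never cuts, and each
pass computes all removals from a frozen snapshot before applying any, so
results are independent of iteration order.

The per-pass thresholds are:

* **Pass 1** — vertex v tolerates
  `g_mean + 2·α·(g_mean / local_mean(v))·g_std`.
  The ratio term lowers the tolerance of vertices whose local mean is
  inflated — and a globally long edge inflates its own endpoints' means,
  which is precisely what flags it.  An edge is removed only when it
  exceeds **both** endpoints' tolerances: a point whose every edge is long
  (an isolated straggler) never votes to disconnect itself, leaving
  outlier handling to the component-size rule rather than to the cut.
* **Pass 2** — within component C, vertex v tolerates
  `(1 + 1.5·β)·nn(v) + β·edge_std(C)`, where nn(v) is v's shortest
  in-component edge, again with the both-endpoints rule.  The
  nearest-neighbour scale is immune to the self-inflation that plain
  local means suffer when a component's length distribution is bimodal —
  the regime of parallel dense structures (spiral arms) bridged by many
  comparable rungs, where a majority of edges can be "long" and mean-based
  vertex statistics are useless.
* **Pass 3** — for each vertex v of degree ≥ 2, any incident edge longer
  than `mean + 8·mean_local_std` of v's 2-hop-induced subgraph is removed.
  This pass cuts from **either** side: the far endpoint of a chain edge
  considers it normal (it is that vertex's own scale), so necks are
  severable only by a one-sided rule.  A homogeneous neighbourhood
  tolerates almost no excess; a heterogeneous one is left alone — which is
  why the pass must run *after* the component cut has removed
  component-scale anomalies near the neck, and why swapping passes 2 and 3
  fails to separate touching clusters.

The three margin constants (2, 1.5, 8) were fixed once, jointly, as the
smallest values at which the three passes neither fragment internally
heterogeneous clusters (Gaussian blobs sampled at their own scale) nor
lose their separating power on the regimes each pass exists for (bridged
blobs, interleaved spiral arms, chain-joined discs); they are module
constants, deliberately not exposed as user parameters.  The threshold
functions live behind one seam in `core.py` and can be swapped without
touching the pipeline.

Properties that follow from the construction: every threshold is
homogeneous of degree 1 in edge length, so labelings are invariant under
rigid motions and equivariant under uniform scaling; removals are
monotone in α and β; the pipeline is fully deterministic.

## The iterative driver

`iterative_cutesc` re-runs the pipeline inside each cluster and keeps
descending while the Calinski–Harabasz score
`CH = [SSB/(k−1)] / [SSW/(n−k)]` of the full labeling strictly increases
(outlier points excluded from the score; k < 2 counts as undefined and
stops descent; a plateau stops it too).  A within-cluster re-run that
returns a single cluster is treated as "no nested structure" and the
cluster is kept whole — promoting its stragglers to outliers would shrink
the scored point set and could raise the score spuriously, biasing the
level comparison.  The trace retains the first rejected level so callers
can inspect why descent stopped.

## Validation criteria

External criteria are computed from the true-class × predicted-cluster
contingency table and its induced counts over the n(n−1)/2 point pairs:
pair Jaccard, precision, recall, Fowlkes–Mallows (√(P·R)), Dice
(identically the pairwise F1), the adjusted Rand index, and adjusted
mutual information with the exact hypergeometric expected-MI correction,
normalised by max(H(U), H(V)) (the normalisation is a keyword).  Predicted
outliers are promoted to singleton clusters by default so no point is
dropped and over-noising is penalised symmetrically; `outliers="exclude"`
drops them instead.  Conventions: both-trivial identical partitions score
1; a 0/0 ratio otherwise scores 0.

## Synthetic regimes

Each generator emulates one regime the method must handle, with defaults
frozen so derived expectations are stable; all draw from
`numpy.random.default_rng(seed)` and are bitwise reproducible.

* `make_uniform_blobs` — k isotropic Gaussian blobs on a grid
  (defaults k=3, 50 points each, σ=0.05, separation 1.0 = 20σ): the
  exact-recovery regime.  With 150 Gaussian points a seed occasionally
  contains a ≥4σ straggler that the cuts correctly isolate as an outlier;
  exact-recovery assertions therefore pin the documented default seed.
* `make_spirals` — k Archimedean arms sampled uniformly in arc length
  (the classic spiral benchmarks have near-constant spacing), with the
  inner radius placed where adjacent arm starts are exactly one asymptotic
  inter-arm gap (2π·growth/k) apart, so separation is uniform down to the
  hub.
* `make_touching_pair` — the touching problem: two lattice discs joined
  by a sparse chain at 2.9× the disc spacing.  A far-away grid cluster
  keeps the global length spread wide (so pass 1 spares the chain); the
  chain's own spacing shields it from pass 2 (nearest-neighbour scale);
  a short satellite chainlet tethered to each neck anchor supplies the
  component-scale anomaly whose removal by pass 2 quiets the anchor's
  2-hop neighbourhood enough for pass 3 to fire — and whose presence,
  under the flipped order, prevents it.  The geometry is deliberately
  tight: the tether sits just above the component-cut threshold and just
  below the longest edge the Gabriel graph admits at a disc pole.
* `make_nonuniform` — four clusters whose spacing spans an order of
  magnitude; the level-2 score drops, exercising the driver's stop rule.
* `make_density_gradient` — one cluster with exponentially decaying
  density along x (robustness smoke).
* `make_nuclei_like` — a Neyman–Scott clustered point process with greedy
  hard-core thinning (minimum spacing 0.008 of the field), mimicking cell
  nucleus centroids in histology: parents uniform, offspring Gaussian with
  Poisson counts.

What the generators do **not** emulate: measurement noise structure of
real images (anisotropy, staining artefacts, boundary truncation),
overlapping clusters, and background clutter mixed through clusters.
Passing tests on these fixtures show the algorithm implements its
contracts, not that it wins on any particular real dataset.

## Numerical choices and degenerate inputs

Delaunay triangulation and point location are delegated to Qhull via
`scipy.spatial.Delaunay`; cocircular ties are resolved by accepting the
triangulation Qhull returns and canonicalising edges as sorted vertex
pairs.  The Gabriel test uses the strict interior of the diametral disk
(points exactly on the circle do not block), which keeps cocircular
configurations stable and preserves Gabriel ⊆ Delaunay under the same
tie-break.  Duplicate points are an error naming the offending indices —
zero-length edges would poison every length statistic.  Fewer than d+1
affinely independent points is an error.  d > 2 is supported throughout
(the construction and statistics are dimension-agnostic).  Cluster ids are
assigned by decreasing component size with ties broken by smallest
contained vertex id, so output is stable under any internal reordering.

## Problem sizes

The shipped fixtures run the full pipeline on 150–650 points; the test
suite and the acceptance script each complete in seconds.  The pipeline
is exact (no sampling or approximation), and its cost is dominated by the
2-hop pass, roughly O(Σ_v deg(v)²) statistic evaluations on a planar-ish
graph.

## Known limitations

* The global pass shatters an isolated cluster whose internal spacing
  exceeds a few multiples of the dataset's mean edge length (its ratio
  term punishes sparse vertices); the usable density dynamic range within
  one dataset is roughly an order of magnitude.
* Chains at or below ~2× the local spacing are indistinguishable from
  in-cluster variation and are not severed.
* Touching clusters connected by *dense* bridges (necks whose edges are
  not longer than cluster edges) are out of reach of any length-based
  rule, including this one.
* The α/β grid search (`scan`) optimises an external criterion and
  therefore needs ground truth; there is no automatic parameter selection.
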
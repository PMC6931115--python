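"""Deterministic synthetic point-set generators.

Each generator emulates one regime the clustering pipeline must handle:
well-separated isotropic blobs, interleaved spiral arms, touching clusters
joined by a thin chain (the "neck" problem only the 2-hop cutting stage
resolves), mixed-density configurations, a single cluster with a smooth
density gradient, and a nuclei-like clustered point process with hard-core
spacing, mimicking cell-nucleus centroids in histology images.

All generators are driven by :func:`numpy.random.default_rng` with an
explicit seed, so identical (parameters, seed) yield bitwise-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PointSet

__all__ = [
    "SyntheticDataset",
    "make_uniform_blobs",
    "make_touching_pair",
    "make_spirals",
    "make_nonuniform",
    "make_density_gradient",
    "make_nuclei_like",
    "REGIMES",
]


@dataclass(frozen=True)
class SyntheticDataset:
    points: PointSet
    true_labels: np.ndarray
    seed: int
    regime: str

    def __post_init__(self):
        labels = np.asarray(self.true_labels, dtype=np.int64)
        if labels.shape[0] != self.points.n:
            raise ValueError("labels length must match point count")
        if np.any(labels < 0):
            raise ValueError("generated labels never use the outlier sentinel")
        labels.setflags(write=False)
        object.__setattr__(self, "true_labels", labels)

    @property
    def k(self) -> int:
        return int(np.unique(self.true_labels).size)


def make_uniform_blobs(
    k: int = 3,
    n_per: int = 50,
    spread: float = 0.05,
    separation: float = 1.0,
    seed: int = 0,
) -> SyntheticDataset:
    """k isotropic Gaussian blobs on a square grid of centers.

    With ``separation > 4 * spread`` the blobs are well separated: the gaps
    between them dwarf the internal spacing, so the pipeline recovers them
    exactly.
    """
    if k < 1 or n_per < 1:
        raise ValueError("k and n_per must be positive")
    if spread <= 0 or separation <= 0:
        raise ValueError("spread and separation must be positive")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(k)))
    centers = np.array(
        [(separation * (i % side), separation * (i // side)) for i in range(k)],
        dtype=float,
    )
    coords = np.vstack(
        [rng.normal(loc=c, scale=spread, size=(n_per, 2)) for c in centers]
    )
    labels = np.repeat(np.arange(k), n_per)
    return SyntheticDataset(PointSet(coords), labels, seed, "uniform_blobs")


def _lattice_disc(center, radius, spacing, jitter, rng):
    """Jittered triangular-lattice fill of a disc: near-uniform spacing."""
    cx, cy = center
    pts = []
    ny = int(np.ceil(radius / (spacing * np.sqrt(3) / 2))) + 1
    for row in range(-ny, ny + 1):
        y = row * spacing * np.sqrt(3) / 2
        x0 = 0.0 if row % 2 == 0 else spacing / 2
        nx = int(np.ceil(radius / spacing)) + 1
        for col in range(-nx, nx + 1):
            x = x0 + col * spacing
            if x * x + y * y <= radius * radius:
                pts.append((cx + x, cy + y))
    pts = np.asarray(pts, dtype=float)
    return pts + rng.normal(scale=jitter, size=pts.shape)


def make_touching_pair(
    n_per: int = 60,
    neck_len: int = 4,
    seed: int = 0,
    *,
    spacing: float = 1.0,
    chain_factor: float = 2.9,
    jitter: float = 0.05,
) -> SyntheticDataset:
    """Two dense discs joined by a sparse chain — the touching problem.

    The fixture reproduces the one configuration that only the
    second-order-neighbourhood stage can resolve: the chain spacing
    (``chain_factor`` times the disc spacing) is too short for the global
    cut (a heterogeneous far-away context cluster keeps the global length
    spread wide) and invisible to the component cut (each chain point's
    nearest neighbour is another chain point, so the chain never looks long
    from its own side).  A small satellite clump tethered to each disc next
    to the neck anchor supplies component-scale long edges that the
    component cut removes; while those tethers are present, the 2-hop
    neighbourhood of the anchors is too heterogeneous for the
    neighbourhood cut to fire, which is why running the neighbourhood
    stage before the component stage fails to separate the discs.

    Points: two lattice discs of about ``n_per`` points (labels 0 and 1),
    ``neck_len`` chain points labelled by the nearer disc, a context
    cluster (label 2) and two satellites (labels 3 and 4).
    ``neck_len=0`` widens the gap to two chain hops of empty space, so the
    discs separate at the global stage already.
    """
    if n_per < 10 or neck_len < 0:
        raise ValueError("n_per must be >= 10 and neck_len non-negative")
    rng = np.random.default_rng(seed)
    s = spacing
    c = chain_factor * s
    radius = np.sqrt(n_per / (np.pi * 2.0 / (np.sqrt(3.0)))) * s
    gap = c * (neck_len + 1) if neck_len >= 1 else 2.0 * c
    xb = radius + gap + radius  # centre-to-centre distance

    disc_a = _lattice_disc((0.0, 0.0), radius, s, jitter * s, rng)
    disc_b = _lattice_disc((xb, 0.0), radius, s, jitter * s, rng)
    coords = [disc_a, disc_b]
    labels = [np.zeros(len(disc_a), np.int64), np.ones(len(disc_b), np.int64)]

    if neck_len >= 1:
        xs = radius + c * np.arange(1, neck_len + 1)
        chain = np.column_stack(
            [xs, rng.normal(scale=jitter * s, size=neck_len)]
        )
        coords.append(chain)
        labels.append((xs > xb / 2).astype(np.int64))

    # satellites: 4-point clumps tethered radially to a boundary vertex of
    # each disc adjacent to the neck anchor; the tether is a component-scale
    # long edge removed by the component cut
    # satellite chainlets tethered to each neck anchor: the tether length
    # sits just above the component-cut threshold (and just below the
    # longest edge the proximity graph will admit at a disc pole), so the
    # component cut removes it; while it is present, the anchor's 2-hop
    # neighbourhood is too heterogeneous for the neighbourhood cut to fire
    tether = 3.2 * s
    ang = 0.67  # tether elevation off the neck axis (radians)
    anchored = ((disc_a, 0.0, 1.0, 3), (disc_b, xb, -1.0, 4)) if neck_len >= 1 else ()
    for disc, centre_x, axis, lab in anchored:
        pole = np.array([centre_x + axis * radius, 0.0])
        anchor = disc[np.argmin(np.sum((disc - pole) ** 2, axis=1))]
        direction = np.array([axis * np.cos(ang), np.sin(ang)])
        head = anchor + tether * direction
        sat = head + s * direction * np.arange(4)[:, None]
        sat = sat + rng.normal(scale=jitter * s, size=sat.shape)
        coords.append(sat)
        labels.append(np.full(4, lab, np.int64))

    # context cluster: jittered grid, spacing 3 s, far above the complex;
    # its many medium-length edges keep the global length spread wide
    nx_c, ny_c = 18, 16
    gx, gy = np.meshgrid(np.arange(nx_c) * 3.0 * s, np.arange(ny_c) * 3.0 * s)
    ctx = np.column_stack([gx.ravel(), gy.ravel()])
    ctx = ctx - ctx.mean(axis=0) + np.array([xb / 2, radius + 30.0 * s])
    ctx = ctx + rng.normal(scale=jitter * s, size=ctx.shape)
    coords.append(ctx)
    labels.append(np.full(len(ctx), 2, np.int64))

    coords = np.vstack(coords)
    labels = np.concatenate(labels)
    return SyntheticDataset(PointSet(coords), labels, seed, "touching")


def make_spirals(
    k: int = 3,
    n_per: int = 150,
    noise: float = 0.0,
    seed: int = 0,
    *,
    turns: float = 1.5,
    inner_radius: float | None = None,
    growth: float = 1.0,
) -> SyntheticDataset:
    """k interleaved Archimedean spiral arms with optional Gaussian jitter.

    Arm j is the curve r = inner_radius + growth * t rotated by 2*pi*j/k,
    sampled at n_per points equally spaced in arc length (the classic
    spiral benchmarks have near-constant point spacing along each arm), so
    the intra-arm gap is everywhere smaller than the inter-arm distance and
    each arm is recoverable as one cluster.  The default inner radius
    places the arm starts where adjacent starts are as far apart as the
    asymptotic inter-arm gap 2*pi*growth/k, so arm separation is uniform
    all the way to the centre.
    """
    if k < 1 or n_per < 2:
        raise ValueError("k must be >= 1 and n_per >= 2")
    if inner_radius is None:
        inner_radius = np.pi * growth / (k * np.sin(np.pi / k)) if k > 1 else 1.0
    rng = np.random.default_rng(seed)
    # equal arc-length parameter values via inversion of the cumulative
    # arc length s(t) = integral sqrt(r^2 + growth^2) dt on a fine grid
    t_fine = np.linspace(0.0, turns * 2 * np.pi, 4096)
    r_fine = inner_radius + growth * t_fine
    ds = np.sqrt(r_fine**2 + growth**2)
    s_fine = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(t_fine))])
    s_targets = np.linspace(0.0, s_fine[-1], n_per)
    t = np.interp(s_targets, s_fine, t_fine)
    coords = []
    for j in range(k):
        phase = 2 * np.pi * j / k
        r = inner_radius + growth * t
        arm = np.column_stack([r * np.cos(t + phase), r * np.sin(t + phase)])
        if noise > 0:
            arm = arm + rng.normal(scale=noise, size=arm.shape)
        coords.append(arm)
    labels = np.repeat(np.arange(k), n_per)
    return SyntheticDataset(PointSet(np.vstack(coords)), labels, seed, "spirals")


def make_nonuniform(seed: int = 0) -> SyntheticDataset:
    """Mixed-density multi-scale configuration.

    A tight pair of small blobs near a large loose blob plus a moderately
    dense elongated cluster: cluster spacing varies by an order of
    magnitude, which is the regime where a single global threshold is least
    informative and deeper iterative levels can matter.
    """
    rng = np.random.default_rng(seed)
    parts = [
        rng.normal(loc=(0.0, 0.0), scale=0.03, size=(40, 2)),
        rng.normal(loc=(0.35, 0.0), scale=0.03, size=(40, 2)),
        rng.normal(loc=(3.0, 0.5), scale=0.45, size=(120, 2)),
        np.column_stack(
            [
                rng.uniform(-0.5, 1.5, size=80),
                rng.normal(scale=0.08, size=80) + 2.5,
            ]
        ),
    ]
    labels = np.repeat(np.arange(4), [40, 40, 120, 80])
    return SyntheticDataset(
        PointSet(np.vstack(parts)), labels, seed, "nonuniform"
    )


def make_density_gradient(seed: int = 0, n: int = 250) -> SyntheticDataset:
    """One cluster whose density decays smoothly along the x axis."""
    rng = np.random.default_rng(seed)
    x = rng.exponential(scale=1.0, size=n)
    y = rng.uniform(0.0, 1.0, size=n)
    coords = np.column_stack([x, y])
    return SyntheticDataset(
        PointSet(coords), np.zeros(n, np.int64), seed, "density_gradient"
    )


def make_nuclei_like(
    n_regions: int = 5,
    seed: int = 0,
    *,
    mean_per_region: int = 40,
    region_scale: float = 0.12,
    field_size: float = 1.0,
    hardcore_radius: float = 0.008,
) -> SyntheticDataset:
    """Neyman-Scott-style clustered point process with hard-core spacing.

    Parent centers are uniform in the unit field; offspring are Gaussian
    around their parent with Poisson-distributed counts.  A greedy thinning
    pass enforces a minimum pairwise distance (``hardcore_radius``),
    mimicking the physical footprint of cell nuclei whose centroids cannot
    coincide.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be positive")
    rng = np.random.default_rng(seed)
    parents = rng.uniform(0.1 * field_size, 0.9 * field_size, size=(n_regions, 2))
    coords, labels = [], []
    for i, p in enumerate(parents):
        cnt = max(3, rng.poisson(mean_per_region))
        coords.append(rng.normal(loc=p, scale=region_scale, size=(cnt, 2)))
        labels.append(np.full(cnt, i, np.int64))
    coords = np.vstack(coords)
    labels = np.concatenate(labels)

    # greedy hard-core thinning in generation order
    kept_idx: list[int] = []
    for i in range(coords.shape[0]):
        ok = True
        for j in kept_idx:
            if np.sum((coords[i] - coords[j]) ** 2) < hardcore_radius**2:
                ok = False
                break
        if ok:
            kept_idx.append(i)
    keep = np.asarray(kept_idx, dtype=np.int64)
    coords, labels = coords[keep], labels[keep]
    # relabel contiguously in case a region was thinned away entirely
    _, labels = np.unique(labels, return_inverse=True)
    return SyntheticDataset(
        PointSet(coords), labels.astype(np.int64), seed, "nuclei_like"
    )


REGIMES = {
    "uniform_blobs": make_uniform_blobs,
    "touching": make_touching_pair,
    "spirals": make_spirals,
    "nonuniform": make_nonuniform,
    "density_gradient": make_density_gradient,
    "nuclei_like": make_nuclei_like,
}
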
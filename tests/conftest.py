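import numpy as np
import pytest

from cutesc import (
    PointSet,
    make_nonuniform,
    make_spirals,
    make_touching_pair,
    make_uniform_blobs,
)


@pytest.fixture(scope="session")
def blobs():
    """Three well-separated Gaussian blobs (the exact-recovery regime)."""
    return make_uniform_blobs(k=3, n_per=50, spread=0.05, separation=1.0, seed=0)


@pytest.fixture(scope="session")
def spirals():
    return make_spirals(k=3, noise=0.0, seed=0)


@pytest.fixture(scope="session")
def touching():
    return make_touching_pair(seed=0)


@pytest.fixture(scope="session")
def nonuniform():
    return make_nonuniform(seed=0)


@pytest.fixture(scope="session")
def hierarchical():
    """Two super-clusters each made of two sub-blobs: the nested-structure
    regime where the iterative driver should descend exactly one level."""
    rng = np.random.default_rng(0)

    def pair(cx):
        return np.vstack([
            rng.normal((cx - 0.15, 0.0), 0.05, (60, 2)),
            rng.normal((cx + 0.15, 0.0), 0.05, (60, 2)),
        ])

    return PointSet(np.vstack([pair(0.0), pair(5.0)]))


def touching_disc_masks(ds):
    """Boolean masks selecting the actual disc points (not chain points,
    which inherit disc labels) of the touching fixture."""
    coords = ds.points.coords
    lab = ds.true_labels
    radius = np.sqrt(60 / (np.pi * 2 / np.sqrt(3)))
    xmax = coords[lab == 1][:, 0].max()
    in_a = (lab == 0) & (coords[:, 0] < radius + 0.5)
    in_b = (lab == 1) & (coords[:, 0] > xmax - 2 * radius - 0.5)
    return in_a, in_b


def discs_separated(ds, graph):
    comp = graph.component_labels()
    in_a, in_b = touching_disc_masks(ds)
    return len(set(comp[in_a]) & set(comp[in_b])) == 0
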
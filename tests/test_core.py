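"""The cutting hierarchy: stage behaviors, invariances, and the iterative
driver's level-selection rule."""

import numpy as np
import pytest

from cutesc import (
    ClusterLabeling,
    CutParams,
    PointSet,
    ProximityGraph,
    cut_global_edges,
    cut_local_edges,
    cut_local_inner_edges,
    cutesc,
    cutesc_p,
    delaunay_edges,
    edge_statistics,
    external_report,
    gabriel_filter,
    iterative_cutesc,
    label_components,
)
from .conftest import discs_separated


def build_gabriel(points: PointSet) -> ProximityGraph:
    return gabriel_filter(points, delaunay_edges(points))


def two_squares_bridge_graph():
    """Two unit squares (4 edges each) joined by one length-20 bridge."""
    edges = [(0, 1), (1, 2), (2, 3), (3, 0),
             (4, 5), (5, 6), (6, 7), (7, 4), (0, 4)]
    weights = [1.0] * 8 + [20.0]
    return ProximityGraph(8, np.array(edges), np.array(weights))


class TestGlobalCut:
    def test_bridge_between_tight_squares_is_the_only_removal(self):
        g = two_squares_bridge_graph()
        out = cut_global_edges(g, edge_statistics(g), alpha=1.0)
        assert out.m == 8
        assert (0, 4) not in set(map(tuple, out.edges))
        assert len(np.unique(out.component_labels())) == 2

    def test_large_alpha_removes_nothing(self):
        g = two_squares_bridge_graph()
        out = cut_global_edges(g, edge_statistics(g), alpha=1e9)
        assert out.m == g.m

    def test_uniform_lengths_never_cut(self):
        # zero spread -> threshold equals the common length; strict test
        g = ProximityGraph(4, np.array([[0, 1], [1, 2], [2, 3], [3, 0]]),
                           np.full(4, 2.0))
        out = cut_global_edges(g, edge_statistics(g), alpha=0.5)
        assert out.m == 4

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(5)
        pts = PointSet(rng.uniform(0, 1, (60, 2)))
        g = build_gabriel(pts)
        st = edge_statistics(g)
        removed = [
            g.m - cut_global_edges(g, st, a).m for a in (0.2, 0.5, 1.0, 2.0)
        ]
        assert removed == sorted(removed, reverse=True)


class TestLocalCut:
    def test_chord_on_unit_path_removed_path_intact(self):
        edges = [(i, i + 1) for i in range(9)] + [(0, 6)]
        weights = [1.0] * 9 + [6.0]
        g = ProximityGraph(10, np.array(edges), np.array(weights))
        out = cut_local_edges(g, beta=1.0)
        kept = set(map(tuple, out.edges))
        assert (0, 6) not in kept
        assert len(kept) == 9

    def test_large_beta_is_identity(self):
        edges = [(i, i + 1) for i in range(9)] + [(0, 6)]
        g = ProximityGraph(10, np.array(edges), np.array([1.0] * 9 + [6.0]))
        assert cut_local_edges(g, beta=1e9).m == g.m

    def test_equal_lengths_in_component_never_cut(self):
        g = ProximityGraph(5, np.array([[0, 1], [1, 2], [2, 3], [3, 4]]),
                           np.full(4, 3.0))
        assert cut_local_edges(g, beta=1.0).m == 4

    def test_single_edge_component_skipped(self):
        g = ProximityGraph(4, np.array([[0, 1], [2, 3]]),
                           np.array([1.0, 50.0]))
        assert cut_local_edges(g, beta=1.0).m == 2

    def test_beta_monotonicity(self):
        rng = np.random.default_rng(9)
        pts = PointSet(rng.uniform(0, 1, (60, 2)))
        g = build_gabriel(pts)
        removed = [g.m - cut_local_edges(g, b).m for b in (0.2, 0.5, 1.0, 2.0)]
        assert removed == sorted(removed, reverse=True)


class TestLocalInnerCut:
    def test_equal_lengths_everywhere_is_identity(self):
        # 3x3 grid graph with unit weights: every 2-hop scope has zero spread
        edges, n = [], 9
        for r in range(3):
            for c in range(3):
                i = 3 * r + c
                if c < 2:
                    edges.append((i, i + 1))
                if r < 2:
                    edges.append((i, i + 3))
        g = ProximityGraph(n, np.array(edges), np.full(len(edges), 1.0))
        assert cut_local_inner_edges(g).m == g.m

    def test_touching_fixture_neck_cut_after_stages_1_2(self, touching):
        g = build_gabriel(touching.points)
        g = cut_global_edges(g, edge_statistics(g), 1.0)
        g = cut_local_edges(g, 1.0)
        assert not discs_separated(touching, g)
        g3 = cut_local_inner_edges(g)
        assert discs_separated(touching, g3)

    def test_rerunning_stage2_in_place_of_stage3_does_not_separate(self, touching):
        g = build_gabriel(touching.points)
        g = cut_global_edges(g, edge_statistics(g), 1.0)
        g = cut_local_edges(g, 1.0)
        g = cut_local_edges(g, 1.0)
        assert not discs_separated(touching, g)

    def test_flipped_stage_order_does_not_separate(self, touching):
        g = build_gabriel(touching.points)
        g = cut_global_edges(g, edge_statistics(g), 1.0)
        g = cut_local_inner_edges(g)
        g = cut_local_edges(g, 1.0)
        assert not discs_separated(touching, g)


class TestLabelComponents:
    def test_small_components_become_outliers(self):
        # components of sizes 5, 3, 1 with min size 2
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (5, 6), (6, 7)]
        g = ProximityGraph(9, np.array(edges), np.ones(len(edges)))
        lab = label_components(g, min_cluster_size=2)
        assert lab.k == 2
        assert lab.n_outliers == 1
        assert lab.labels[8] == -1
        # ids ordered by decreasing size
        assert np.sum(lab.labels == 0) == 5
        assert np.sum(lab.labels == 1) == 3

    def test_fully_connected_single_cluster(self):
        g = ProximityGraph(4, np.array([[0, 1], [1, 2], [2, 3]]), np.ones(3))
        lab = label_components(g, 1)
        assert lab.k == 1 and lab.n_outliers == 0

    def test_empty_edge_set_singletons(self):
        g = ProximityGraph(4, np.empty((0, 2), dtype=np.int64), np.empty(0))
        lab = label_components(g, 1)
        assert lab.k == 4
        assert sorted(lab.labels) == [0, 1, 2, 3]

    def test_size_ties_broken_by_smallest_vertex(self):
        edges = [(2, 3), (0, 1)]
        g = ProximityGraph(4, np.array(edges), np.ones(2))
        lab = label_components(g, 1)
        assert lab.labels[0] == 0 and lab.labels[2] == 1


class TestPipeline:
    def test_three_blob_exact_recovery(self, blobs):
        lab = cutesc_p(blobs.points, CutParams(alpha=1.0, beta=1.0))
        assert lab.k == 3
        assert external_report(blobs.true_labels, lab.labels)["ari"] == 1.0

    def test_triangle_single_cluster(self):
        lab = cutesc_p(PointSet([[0, 0], [1, 0], [0, 1]]),
                       CutParams(min_cluster_size=1))
        assert lab.k == 1 and lab.n_outliers == 0

    def test_per_stage_groups_recorded_and_nondecreasing(self, touching):
        lab = cutesc(touching.points)
        assert len(lab.per_stage_groups) == 3
        assert list(lab.per_stage_groups) == sorted(lab.per_stage_groups)

    def test_parameter_free_equals_unit_parameters(self, blobs, spirals, touching):
        for ds in (blobs, spirals, touching):
            a = cutesc(ds.points)
            b = cutesc_p(ds.points, CutParams(alpha=1.0, beta=1.0))
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_determinism(self, blobs):
        a = cutesc(blobs.points)
        b = cutesc(blobs.points)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_rigid_motion_invariance(self, blobs):
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = PointSet(blobs.points.coords @ rot.T + [10.0, -4.0])
        np.testing.assert_array_equal(
            cutesc(blobs.points).labels, cutesc(moved).labels
        )

    def test_scale_equivariance(self, blobs):
        scaled = PointSet(blobs.points.coords * 37.5)
        np.testing.assert_array_equal(
            cutesc(blobs.points).labels, cutesc(scaled).labels
        )

    def test_stagewise_edge_monotonicity(self, nonuniform):
        g0 = build_gabriel(nonuniform.points)
        g1 = cut_global_edges(g0, edge_statistics(g0), 1.0)
        g2 = cut_local_edges(g1, 1.0)
        g3 = cut_local_inner_edges(g2)
        e0, e1, e2, e3 = (set(map(tuple, g.edges)) for g in (g0, g1, g2, g3))
        assert e3 <= e2 <= e1 <= e0
        comps = [len(np.unique(g.component_labels())) for g in (g0, g1, g2, g3)]
        assert comps == sorted(comps)


class TestIterativeDriver:
    def test_max_levels_one_is_plain_clustering(self, blobs):
        trace = iterative_cutesc(blobs.points,
                                 CutParams(iterate=True, max_levels=1))
        assert len(trace.labelings) == 1
        assert trace.accepted_level == 1
        np.testing.assert_array_equal(
            trace.accepted.labels, cutesc(blobs.points).labels
        )

    def test_plateau_stops_at_level_one(self, blobs):
        trace = iterative_cutesc(blobs.points,
                                 CutParams(iterate=True, max_levels=3))
        assert trace.accepted_level == 1
        assert trace.scores[1] <= trace.scores[0]
        assert trace.cluster_counts[1] >= trace.cluster_counts[0]

    def test_decreasing_score_stops_at_level_one(self, nonuniform):
        trace = iterative_cutesc(nonuniform.points,
                                 CutParams(iterate=True, max_levels=3))
        assert trace.accepted_level == 1
        assert trace.scores[1] < trace.scores[0]

    def test_nested_structure_accepts_level_two(self, hierarchical):
        trace = iterative_cutesc(hierarchical,
                                 CutParams(iterate=True, max_levels=4))
        assert trace.cluster_counts[0] == 2
        assert trace.cluster_counts[1] == 4
        assert trace.scores[1] > trace.scores[0]
        assert trace.accepted_level == 2

    def test_accepted_level_score_dominates_shallower_levels(self, hierarchical):
        trace = iterative_cutesc(hierarchical,
                                 CutParams(iterate=True, max_levels=4))
        accepted = trace.scores[trace.accepted_level - 1]
        for s in trace.scores[: trace.accepted_level - 1]:
            assert accepted >= s


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": 0.0}, {"beta": -1.0}, {"min_cluster_size": 0},
        {"max_levels": 0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CutParams(**kwargs)
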
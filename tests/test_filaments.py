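"""Skeletonization, graph building, radius estimation and filament gates."""

import numpy as np
import pytest

from lymphmorph.filaments import (
    FilamentParams,
    build_graph,
    estimate_radii,
    prune,
    seed_filter,
    skeletonize,
)
from lymphmorph.graphs import VesselGraph
from lymphmorph.stacks import BinaryMask, ImageStack

from conftest import make_ball_mask, make_tube_mask, y_graph


class TestSkeletonize:
    def test_empty_mask_gives_empty_skeleton(self):
        mask = BinaryMask(np.zeros((5, 5, 5), bool), (1, 1, 1))
        assert not skeletonize(mask).any()

    def test_skeleton_is_subset_and_thin(self):
        mask = make_tube_mask(3.0, 60)
        sk = skeletonize(mask)
        assert not (sk & ~mask.voxels).any()
        # no 2x2x2 all-true block
        blocks = (
            sk[:-1, :-1, :-1]
            & sk[1:, :-1, :-1]
            & sk[:-1, 1:, :-1]
            & sk[:-1, :-1, 1:]
            & sk[1:, 1:, :-1]
            & sk[1:, :-1, 1:]
            & sk[:-1, 1:, 1:]
            & sk[1:, 1:, 1:]
        )
        assert not blocks.any()

    def test_straight_tube_skeleton_hugs_the_axis(self):
        mask = make_tube_mask(3.0, 60)
        sk = skeletonize(mask)
        coords = np.argwhere(sk)
        center = (np.asarray(mask.shape) - 1) / 2.0
        # all skeleton voxels within 1 voxel of the tube axis (z, y = center)
        off_axis = np.abs(coords[:, :2] - center[:2]).max()
        assert off_axis <= 1.0
        graph = build_graph(sk, (1, 1, 1))
        assert graph.n_edges == 1
        assert len(graph.endpoints()) == 2

    def test_ball_collapses_to_near_centroid(self):
        sk = skeletonize(make_ball_mask(6.0))
        assert 0 < sk.sum() <= 9

    def test_torus_skeleton_keeps_exactly_one_cycle(self):
        # hollow torus around the z axis
        n = 49
        zz, yy, xx = np.mgrid[:9, :n, :n]
        cy = cx = (n - 1) / 2
        rho = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        torus = (rho - 15.0) ** 2 + (zz - 4.0) ** 2 <= 3.0**2
        sk = skeletonize(BinaryMask(torus, (1, 1, 1)))
        graph = build_graph(sk, (1, 1, 1))
        nxg = graph.to_networkx()
        import networkx as nx

        cycles = nxg.number_of_edges() - nxg.number_of_nodes() + nx.number_connected_components(nxg)
        assert cycles == 1


class TestBuildGraph:
    def test_straight_path(self):
        sk = np.zeros((3, 3, 20), bool)
        sk[1, 1, 2:18] = True
        g = build_graph(sk, (1, 1, 1))
        assert len(g.endpoints()) == 2
        assert len(g.branch_points()) == 0
        assert g.n_edges == 1
        assert g.total_length == pytest.approx(15.0)

    def test_y_shape_single_branch_node(self):
        sk = np.zeros((3, 21, 21), bool)
        sk[1, 10, 2:11] = True  # stem along x
        for i in range(1, 9):  # two diverging limbs
            sk[1, 10 - i, 10 + i] = True
            sk[1, 10 + i, 10 + i] = True
        g = build_graph(sk, (1, 1, 1))
        assert len(g.branch_points()) == 1
        assert len(g.endpoints()) == 3
        assert g.n_edges == 3

    def test_binary_tree_edge_count_identity(self):
        # full binary tree with 2 branch nodes: E = n_roots + 2B = 5
        sk = np.zeros((3, 40, 40), bool)
        sk[1, 20, 2:12] = True
        for i in range(1, 10):
            sk[1, 20 - i, 11 + i] = True
            sk[1, 20 + i, 11 + i] = True
        for i in range(1, 8):
            sk[1, 11 - i, 20 + i] = True
            sk[1, 11, 20 + i] = True
        g = build_graph(sk, (1, 1, 1))
        assert len(g.branch_points()) == 2
        assert g.n_edges == 5

    def test_total_length_invariant_under_axis_permutation_and_flip(self):
        rng = np.random.default_rng(2)
        sk = skeletonize(make_tube_mask(3.0, 40))
        base = build_graph(sk, (1, 1, 1)).total_length
        for perm in ((1, 2, 0), (2, 0, 1)):
            assert build_graph(np.transpose(sk, perm), (1, 1, 1)).total_length == pytest.approx(base)
        assert build_graph(sk[::-1], (1, 1, 1)).total_length == pytest.approx(base)


class TestRadii:
    def test_isotropic_tube_diameter(self):
        mask = make_tube_mask(3.0, 60, spacing=(1, 1, 1))
        g = estimate_radii(build_graph(skeletonize(mask), mask.spacing), mask)
        interior = np.concatenate(
            [e.radii[5:-5] for e in g.edges if len(e.radii) > 10]
        )
        assert 2 * interior.mean() == pytest.approx(6.0, abs=1.0)

    def test_anisotropic_tube_along_z(self):
        mask = make_tube_mask(3.0, 40, spacing=(2.0, 1.0, 1.0), axis=0)
        g = estimate_radii(build_graph(skeletonize(mask), mask.spacing), mask)
        interior = np.concatenate(
            [e.radii[3:-3] for e in g.edges if len(e.radii) > 6]
        )
        # recovery within one z-step
        assert 2 * interior.mean() == pytest.approx(6.0, abs=2.0)

    def test_single_voxel_line_hits_the_edt_floor(self):
        vox = np.zeros((3, 3, 30), bool)
        vox[1, 1, 2:28] = True
        mask = BinaryMask(vox, (2.0, 1.0, 1.0))
        g = estimate_radii(build_graph(skeletonize(mask), mask.spacing), mask)
        interior = np.concatenate([e.radii[3:-3] for e in g.edges])
        # the distance floor is one lateral voxel spacing
        assert interior.mean() == pytest.approx(1.0, abs=0.3)

    def test_point_outside_mask_gets_zero_radius(self):
        mask = BinaryMask(np.zeros((5, 5, 5), bool), (1, 1, 1))
        mask.voxels[2, 2, 2] = True
        g = VesselGraph()
        a = g.add_node([2.0, 2.0, 0.0])
        b = g.add_node([2.0, 2.0, 4.0])
        g.add_edge(a, b, np.array([[2.0, 2.0, 0.0], [2.0, 2.0, 4.0]]))
        out = estimate_radii(g, mask)
        assert out.edges[0].radii[0] == 0.0
        assert out.n_points_outside_mask >= 1


class TestSeedFilter:
    def _graph_over(self, stack_shape, pos_a, pos_b):
        g = VesselGraph()
        a = g.add_node(pos_a)
        b = g.add_node(pos_b)
        g.add_edge(a, b, np.linspace(pos_a, pos_b, 8), np.ones(8))
        return g

    def test_dim_component_dropped_at_lyve1_threshold(self):
        vox = np.full((5, 5, 20), 250.0)
        stack = ImageStack(vox, (1, 1, 1))
        g = self._graph_over(stack.shape, [2, 2, 1], [2, 2, 18])
        out = seed_filter(g, stack, 273.0)
        assert out.n_edges == 0

    def test_zero_threshold_is_identity(self):
        stack = ImageStack(np.zeros((5, 5, 20)), (1, 1, 1))
        g = self._graph_over(stack.shape, [2, 2, 1], [2, 2, 18])
        out = seed_filter(g, stack, 0.0)
        assert out.n_edges == 1

    def test_components_kept_atomically_at_vegfr3_threshold(self):
        vox = np.zeros((5, 10, 20))
        vox[:, :4, :] = 119.0
        vox[:, 6:, :] = 500.0
        stack = ImageStack(vox, (1, 1, 1))
        g = VesselGraph()
        a, b = g.add_node([2, 1, 1]), g.add_node([2, 1, 18])
        c, d = g.add_node([2, 8, 1]), g.add_node([2, 8, 18])
        g.add_edge(a, b, np.linspace([2, 1, 1], [2, 1, 18], 8), np.ones(8))
        g.add_edge(c, d, np.linspace([2, 8, 1], [2, 8, 18], 8), np.ones(8))
        out = seed_filter(g, stack, 120.0)
        assert out.n_edges == 1
        assert {out.edges[0].u, out.edges[0].v} == {c, d}


class TestPrune:
    def _one_edge(self, diameter):
        g = VesselGraph()
        a = g.add_node([0, 0, 0])
        b = g.add_node([0, 0, 100.0])
        poly = np.linspace([0, 0, 0], [0, 0, 100.0], 11)
        g.add_edge(a, b, poly, np.full(11, diameter / 2))
        return g

    @pytest.mark.parametrize(
        "diameter,kept",
        [(0.5, False), (31.0, False), (29.0, True), (1.5, True)],
    )
    def test_caliber_gate(self, diameter, kept):
        out = prune(self._one_edge(diameter), FilamentParams())
        assert (out.n_edges == 1) is kept

    def test_spur_on_trunk_removed_and_trunk_merged(self):
        g = VesselGraph()
        left = g.add_node([0, 0, 0.0])
        mid = g.add_node([0, 0, 60.0], kind="branch")
        right = g.add_node([0, 0, 120.0])
        tip = g.add_node([0, 2.0, 60.0])
        trunk_r = 3.0  # 6 um diameter trunk
        g.add_edge(left, mid, np.linspace([0, 0, 0], [0, 0, 60.0], 7), np.full(7, trunk_r))
        g.add_edge(mid, right, np.linspace([0, 0, 60.0], [0, 0, 120.0], 7), np.full(7, trunk_r))
        g.add_edge(mid, tip, np.linspace([0, 0, 60.0], [0, 2.0, 60.0], 3), np.full(3, 1.0))
        out = prune(g, FilamentParams(min_twig_length_factor=2.0))
        assert len(out.branch_points()) == 0
        assert out.n_edges == 1
        assert out.edges[0].length == pytest.approx(120.0)

    def test_prune_and_seed_filter_only_shrink(self, stack_from_mask):
        mask = make_tube_mask(3.0, 50)
        stack = stack_from_mask(mask, fg=300.0)
        g = estimate_radii(build_graph(skeletonize(mask), mask.spacing), mask)
        for out in (
            prune(g, FilamentParams()),
            seed_filter(g, stack, 100.0),
        ):
            assert out.n_nodes <= g.n_nodes
            assert out.n_edges <= g.n_edges
            assert out.total_length <= g.total_length + 1e-9
            assert len(out.branch_points()) <= len(g.branch_points())
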
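"""Phantom generator: determinism, ground truth, rasterization, presets."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from lymphmorph.segmentation import label_components
from lymphmorph.stacks import BinaryMask
from lymphmorph.synth import (
    PRESET_PAIR_NAMES,
    SynthParams,
    _draw_lengths,
    corrupt,
    generate_network,
    generate_phantom,
    preset_pair,
    rasterize,
)
from lymphmorph.graphs import VesselGraph

SMALL = dict(
    grid_shape=(48, 96, 96),
    n_roots=2,
    target_branch_count=4,
    target_total_length_um=800.0,
    n_distractor_spheres=0,
)


class TestGenerateNetwork:
    def test_fixed_seed_is_bit_reproducible(self):
        p = SynthParams(**SMALL, seed=9)
        g1, t1 = generate_network(p)
        g2, t2 = generate_network(p)
        assert g1.n_edges == g2.n_edges
        for e1, e2 in zip(g1.edges, g2.edges):
            np.testing.assert_array_equal(e1.polyline, e2.polyline)
            np.testing.assert_array_equal(e1.radii, e2.radii)
        assert t1.total_length_um == t2.total_length_um

    def test_no_branching_gives_unbranched_paths(self):
        p = SynthParams(
            grid_shape=(48, 96, 96),
            n_roots=3,
            branching_probability=0.0,
            target_branch_count=None,
            target_total_length_um=None,
            n_distractor_spheres=0,
            seed=2,
        )
        graph, truth = generate_network(p)
        assert truth.branch_point_count == 0
        assert graph.n_edges == 3

    def test_branch_budget_met_exactly(self):
        p = SynthParams(**SMALL, seed=4)
        _, truth = generate_network(p)
        assert truth.branch_point_count == 4

    def test_segment_lengths_follow_the_stated_lognormal(self):
        p = SynthParams(
            segment_length_mean_um=40.0,
            segment_length_sigma=0.3,
            segment_length_clip_um=None,
            target_total_length_um=None,
        )
        rng = np.random.default_rng(0)
        draws = _draw_lengths(p, 1000, rng)
        mu = np.log(40.0) - 0.3**2 / 2
        _, pvalue = stats.kstest(draws, stats.lognorm(s=0.3, scale=np.exp(mu)).cdf)
        assert pvalue > 0.01

    def test_ground_truth_scalars_match_recomputation_from_graph(self):
        _, truth = generate_network(SynthParams(**SMALL, seed=7))
        rec = truth.recompute_from_graph()
        assert rec["branch_point_count"] == truth.branch_point_count
        assert rec["total_length_um"] == pytest.approx(truth.total_length_um, rel=1e-6)
        assert rec["mean_diameter_um"] == pytest.approx(truth.mean_diameter_um, rel=1e-6)
        assert rec["total_volume_um3"] == pytest.approx(truth.total_volume_um3, rel=1e-6)

    def test_grid_too_small_for_one_segment_rejected(self):
        with pytest.raises(ValueError):
            SynthParams(grid_shape=(4, 8, 8), spacing=(1.0, 1.0, 1.0))


class TestRasterize:
    def test_capsule_volume_close_to_closed_form(self):
        g = VesselGraph()
        a = g.add_node([20.0, 20.0, 10.0])
        b = g.add_node([20.0, 20.0, 50.0])
        g.add_edge(a, b, np.linspace([20, 20, 10], [20, 20, 50.0], 9), np.full(9, 3.0))
        _, mask = rasterize(g, (40, 40, 64), (1.0, 1.0, 1.0))
        expected = np.pi * 9 * 40 + (4 / 3) * np.pi * 27  # cylinder + two caps
        assert mask.foreground_count == pytest.approx(expected, rel=0.05)

    def test_empty_graph_gives_uniform_background(self):
        stack, mask = rasterize(VesselGraph(), (8, 8, 8), (1, 1, 1), 300.0, 20.0)
        assert mask.foreground_count == 0
        assert np.all(stack.voxels == 20.0)

    def test_mask_volume_consistent_across_anisotropic_resampling(self):
        g, _ = generate_network(SynthParams(**SMALL, seed=3))
        _, iso = rasterize(g, (96, 96, 96), (1.24, 1.24, 1.24))
        _, aniso = rasterize(g, (60, 96, 96), (2.0, 1.24, 1.24))
        assert aniso.foreground_volume_um3 == pytest.approx(
            iso.foreground_volume_um3, rel=0.07
        )

    def test_mask_covers_every_polyline_point(self):
        g, truth = generate_network(SynthParams(**SMALL, seed=6))
        _, mask = rasterize(g, (48, 96, 96), (2.0, 1.24, 1.24))
        sp = np.array((2.0, 1.24, 1.24))
        for e in g.edges:
            idx = np.clip(
                np.rint(e.polyline / sp).astype(int), 0, np.array(mask.shape) - 1
            )
            assert mask.voxels[tuple(idx.T)].all()


class TestCorrupt:
    def test_noiseless_corrupt_is_identity(self):
        p = SynthParams(**SMALL, seed=1, noise_sd=0.0, blur_sigma_um=0.0)
        g, _ = generate_network(p)
        stack, _ = rasterize(g, p.grid_shape, p.spacing)
        out = corrupt(stack, p)
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_fixed_seed_reproducible(self):
        p = SynthParams(**SMALL, seed=5)
        g, _ = generate_network(p)
        stack, mask = rasterize(g, p.grid_shape, p.spacing)
        a = corrupt(stack, p, clean_mask=mask)
        b = corrupt(stack, p, clean_mask=mask)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_distractors_are_near_spherical_and_outside_the_vessel_band(self):
        p = SynthParams(
            grid_shape=(48, 96, 96),
            n_roots=1,
            target_branch_count=0,
            target_total_length_um=150.0,
            n_distractor_spheres=3,
            seed=8,
        )
        stack, truth = generate_phantom(p)
        assert truth.distractor_mask.foreground_count > 0
        comps = label_components(
            BinaryMask(truth.distractor_mask.voxels, p.spacing)
        )
        assert comps.n_components >= 1
        assert (comps.table["sphericity"] > 0.8).all()
        assert (comps.table["sphericity"] > 0.563).all()  # outside the keep-band


class TestPresets:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset_pair("nope")

    def test_all_pairs_share_grid_and_spacing(self):
        for name in PRESET_PAIR_NAMES:
            ref, trt = preset_pair(name)
            assert ref.grid_shape == trt.grid_shape
            assert ref.spacing == trt.spacing

    def test_caliber_pair_diameter_ratio_exact(self):
        ref, trt = preset_pair("lyve1_caliber")
        _, t_ref = generate_network(replace(ref, seed=21))
        _, t_trt = generate_network(replace(trt, seed=21))
        assert t_trt.mean_diameter_um / t_ref.mean_diameter_um == pytest.approx(
            0.92, abs=1e-6
        )
        assert t_trt.branch_point_count == t_ref.branch_point_count

    def test_segments_pair_length_scaling_exact(self):
        ref, trt = preset_pair("lyve1_segments")
        _, t_ref = generate_network(replace(ref, seed=22))
        _, t_trt = generate_network(replace(trt, seed=22))
        n_ref = len(t_ref.segment_lengths_um)
        assert len(t_trt.segment_lengths_um) == n_ref
        ratio = (t_trt.total_length_um / n_ref) / (t_ref.total_length_um / n_ref)
        assert ratio == pytest.approx(0.78, abs=1e-9)

    def test_geometry_pair_branch_density_ratio(self):
        ref, trt = preset_pair("lyve1_geometry")
        _, t_ref = generate_network(replace(ref, seed=23))
        _, t_trt = generate_network(replace(trt, seed=24))
        assert t_trt.branch_point_count / t_ref.branch_point_count == pytest.approx(
            2.01, rel=0.02
        )
        assert t_trt.total_length_um / t_ref.total_length_um == pytest.approx(
            1.75, rel=1e-9
        )

    def test_vegfr3_pair_volume_ratio(self):
        ref, trt = preset_pair("vegfr3_geometry")
        _, t_ref = generate_network(replace(ref, seed=25))
        _, t_trt = generate_network(replace(trt, seed=25))
        assert t_trt.total_volume_um3 / t_ref.total_volume_um3 == pytest.approx(
            1.68 * 1.047**2, rel=1e-6
        )
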
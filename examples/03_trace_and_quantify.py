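"""Trace a segmented mask into a vessel graph and extract the five metrics.

The mask is thinned to a centerline, converted to a spatial graph, radii
are read off the distance transform, and the network is summarized by
branch points, total length, average segment length, length-weighted mean
diameter and frustum-based filament volume — each also normalized by the
imaging volume.
"""

from lymphmorph import SynthParams, analyze_stack, generate_phantom

params = SynthParams(
    grid_shape=(64, 128, 128),
    n_roots=2,
    target_branch_count=6,
    target_total_length_um=1500.0,
    seed=5,
)
stack, truth = generate_phantom(params)

mask, graph, report = analyze_stack(
    stack, channel="lyve1", intensity_threshold=params.suggested_intensity_threshold
)

print(f"{'metric':35s} {'measured':>12s} {'ground truth':>12s}")
print(f"{'branch points':35s} {report.branch_point_count:12d} {truth.branch_point_count:12d}")
print(f"{'total filament length (um)':35s} {report.total_filament_length_um:12.1f} {truth.total_length_um:12.1f}")
print(f"{'mean vessel diameter (um)':35s} {report.mean_diameter_um:12.2f} {truth.mean_diameter_um:12.2f}")
print(f"{'total filament volume (um^3)':35s} {report.total_filament_volume_um3:12.0f} {truth.total_volume_um3:12.0f}")
print(f"{'average segment length (um)':35s} {report.avg_segment_length_um:12.1f}")
print(f"\nbranch-point density: {report.normalized['branch_point_count']:.3e} per um^3")
print(f"length density:       {report.normalized['total_filament_length_um']:.3e} um/um^3")
# On this small noisy phantom the recovery is close but not exact (an extra
# junction or a few percent of length can be lost to noise); on clean,
# well-separated phantoms branch points recover exactly and length/diameter
# land within a few percent of truth.
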
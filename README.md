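# lymphmorph

3D morphometry of lymphatic vessel networks in cleared whole-mount tissue
image stacks.

## The problem

Lymphangiogenesis — expansion and remodelling of the lymphatic vasculature —
is a hallmark of kidney injury. With tissue clearing (iDISCO) and whole-mount
immunolabelling against lymphatic endothelial markers (LYVE-1, VEGFR-3),
confocal stacks capture entire renal lymphatic networks in 3D, but turning
those stacks into numbers usually runs through interactive commercial
software: manual surface editing, trained filament tracing, per-session
parameter choices. `lymphmorph` reimplements that quantification as an open,
deterministic pipeline, so the same stack and the same parameters always
yield the same numbers:

1. **Segmentation** — absolute-intensity thresholding, connected-component
   analysis, and object filtering by voxel count and *sphericity*
   Ψ = π^(1/3) (6V)^(2/3) / A (Ψ = 1 for a sphere, low for elongated tubes).
   The sphericity band excludes near-spherical non-vessel objects such as
   free-floating labelled cells; an optional exclusion-ROI mask replaces
   interactive deletion. Published channel presets are built in
   (LYVE-1: voxel count > 173, Ψ ∈ [0.0566, 0.563]; VEGFR-3: > 75,
   Ψ ∈ [0.0519, 0.665]).
2. **Filament tracing** — topology-preserving 3D thinning of the vessel
   mask, conversion to a spatial graph (branch nodes, endpoints, polyline
   segments), local radii from the Euclidean distance transform, a
   seed-intensity gate (LYVE-1: 273, VEGFR-3: 120) and a 1–30 µm caliber
   gate with rule-based spur suppression.
3. **Morphometry** — the five network metrics: branch points, total
   filament length, average segment length, length-weighted mean vessel
   diameter, and total filament volume (conical-frustum sum over traced
   radii), each normalized by the physical imaging volume.
4. **Comparison** — average percent change of normalized metrics between a
   reference group (sham) and a treated group (e.g. bilateral
   ischemia–reperfusion injury), as 100 × (mean_t − mean_r) / mean_r.

Because no raw microscope data are deposited alongside the protocol this
package follows, validation is built on a **synthetic phantom generator**:
seeded branching tubular networks with exact known topology, lengths and
radii, rasterized into noisy anisotropic stacks with near-spherical
distractor objects. Packaged preset pairs encode the reported injury effect
sizes as exact ground truth, so the whole pipeline can be scored on how well
it recovers a known change.

## Worked example

```python
from lymphmorph import SynthParams, analyze_stack, generate_phantom

params = SynthParams(grid_shape=(64, 128, 128), n_roots=2,
                     target_branch_count=6, target_total_length_um=1500.0,
                     seed=5)
stack, truth = generate_phantom(params)
mask, graph, report = analyze_stack(stack, channel="lyve1",
                                    intensity_threshold=params.suggested_intensity_threshold)
print(report.branch_point_count, truth.branch_point_count)
print(round(report.total_filament_length_um, 1), truth.total_length_um)
print(round(report.mean_diameter_um, 2), round(truth.mean_diameter_um, 2))
```

prints (seed 5):

```
7 6
1374.2 1500.0
6.92 7.28
```

— the pipeline measured 7 branch points against 6 ground truth, 1374 µm of
filament against 1500 µm, and a 6.92 µm mean diameter against 7.28 µm on
this small, noisy, deliberately crowded phantom. On clean well-separated
phantoms the branch count recovers exactly and length lands within 5%
(see `tests/test_acceptance.py`). The `examples/` directory holds one short
script per capability: phantom generation, segmentation and distractor
filtering, tracing and quantification, group comparison, deconvolution.

A thin CLI wraps the same stages for shell use:

```bash
lymphmorph simulate --preset lyve1_geometry --arm treated --seed 4 --out s.tif --truth t.json
lymphmorph segment  --stack s.tif --preset lyve1 --threshold 160 --out mask.tif
lymphmorph trace    --mask mask.tif --stack s.tif --preset lyve1 --out graph.swc
lymphmorph quantify --graph graph.swc --dims 128x256x256 --spacing 2.0,1.24,1.24 --out report.csv
lymphmorph compare  --reference sham1.csv --reference sham2.csv --treated biri1.csv --out cmp.csv
```

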
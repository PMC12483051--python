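# Methods

This note documents the models, conventions and numerical choices behind
`lymphmorph`, and what validation on synthetic phantoms does and does not
demonstrate about real cleared-kidney stacks.

## Conventions

Axis order is (z, y, x) everywhere; TIFF pages are z-planes. Voxel indices
are 0-based; the physical position of a voxel center is `index × spacing`
in µm. Spacing is never defaulted: a stack without OME `PhysicalSize*`
metadata must be read with an explicit override, and every physical
quantity downstream traces to that spacing. Lateral spacing in the packaged
presets is 1.24 µm/px (the acquisition convention of the protocol this
pipeline reimplements); the axial step is a package convention of 2.0 µm,
since protocols typically leave the z-step to the acquisition session —
users must supply their own.

## Segmentation

A voxel is foreground iff intensity ≥ threshold (closed comparison; the
convention must be fixed for exactness and is documented here). The
threshold is deliberately the only sample-specific parameter: absolute
thresholds absorb per-animal background variation, while the object filters
are standardized per channel and shared across all samples of a run —
enforced structurally by a single preset object per pipeline run.

Connected components use 26-connectivity by default; thin anisotropically
sampled vessels fragment under 6-connectivity. Components touching the
stack border are kept (vessels legitimately exit the imaged volume); a flag
can exclude them.

Sphericity is Ψ = π^(1/3)(6V)^(2/3)/A with V from the voxel count and A
from a mesh: the 0.5-level marching-cubes surface of the component
indicator, spacing-aware, with 10 Taubin smoothing passes. Voxel-face
counting would overestimate A by up to ~1.5× and bias Ψ low relative to
bands derived from mesh-rendering software; the raw digital mesh still
overestimates curved areas by ~6% from voxelization scalloping, which the
volume-preserving Taubin passes remove (rasterized balls of radius ≥ 8
voxels then measure Ψ = 1 within 5%, digital cubes (π/6)^(1/3) ≈ 0.806
within 5%). Below ~30 voxels the mesh is not a reliable physical surface
and Ψ may even exceed 1; such objects are expected to be removed by the
voxel-count gate first, which the packaged presets (minimum counts 173/75)
guarantee by a wide margin. The voxel filter is strict (`count > N`,
reading "above N" literally).

Interactive deletion of non-vessel objects is re-specified as subtraction
of a user-supplied binary exclusion ROI, applied before component analysis.

## Filament tracing

Skeletonization is topology-preserving 3D thinning on the native voxel
grid; resampling to isotropic grids changes topology near thin structures,
so anisotropy is instead handled by spacing-weighted path lengths in the
graph stage. This rule-based tracing (thinning + deterministic gates) is
the package's replacement for interactively trained commercial tracing —
the largest intentional deviation from the workflow it mirrors, and the
price of exact reproducibility.

Skeleton voxels with ≥ 3 neighbours are junction voxels; 26-adjacent
junction voxels merge into one branch node at their centroid so a single
anatomical junction is not double-counted. Digital voxel chains zigzag
around the true centerline and inflate Euclidean length by up to ~10%; two
passes of a 5-point moving average over interior polyline points remove the
staircase (a straight oblique tube then measures length within 0.2%).

Radii come from the spacing-aware Euclidean distance transform. Because
skeleton voxels sit up to half a voxel off the true axis — where the EDT
has already fallen below its centerline peak — the radius at a polyline
point is the trilinear sample of the 3×3×3 *max-pooled* EDT, restoring the
peak value (a 3 µm-radius tube at 1 µm isotropic sampling then reads
diameter 5.97 µm). Consequence: a 1-voxel-wide line reads a radius of about
one lateral spacing (the center-to-center EDT floor), not half a spacing.

Three deterministic gates replace trained curation:

- **Seed gate** — a connected filament survives iff some polyline point
  lies on a voxel at least as bright as the channel's seed threshold
  (273 / 120); components are kept or dropped atomically.
- **Caliber gate** — edges whose *median* point diameter falls outside
  1–30 µm are removed. Median, not mean: the EDT bulges at junctions and
  would otherwise drag thin edges over the bound.
- **Junction consolidation and spur suppression** — thick junctions can
  split during thinning into two branch nodes joined by a vessel-scale
  stub; branch–branch edges shorter than 1.8× the network-median diameter
  are merged (the threshold is scaled by the network-wide typical caliber
  because stub-local diameters are junction-inflated). Terminal edges
  shorter than 2× their median diameter are dropped as spurs, and orphaned
  degree-2 nodes are dissolved. Both factors are exposed in
  `FilamentParams`.

Finally, thinning retracts every terminal branch by roughly one tube radius
(the skeleton ends where the end-cap ball stops fitting); terminal edges
are therefore extended by the local radius after pruning, tapering the
radius to zero.

**Resolution limit.** Junction consolidation cannot distinguish a genuine
segment of length ≲ 2 vessel diameters from a split-junction stub. Networks
whose inter-branch segments approach that scale lose a few percent of their
junctions; in the `lyve1_segments` phantom pair this shifts the measured
average-segment-length change from the encoded −22% to about −17%.

## Morphometry and comparison

Five metrics per traced network: branch-point count; total filament length
(Σ edge polyline lengths); average segment length (total / number of
edges); mean vessel diameter, length-weighted over polyline intervals so
dense sampling cannot bias it; and total filament volume as the
conical-frustum sum (π/3)·Δl·(r₁² + r₁r₂ + r₂²) over consecutive polyline
points (exact for uniform cylinders). A `--volume-from-mask` style
cross-check (voxel-count volume of the mask) is available via
`morphometry.mask_volume_um3`.

Extensive metrics are divided by the imaging volume (grid extents × voxel
volume). Intensive metrics (diameter, segment length) pass through
unchanged by default — dividing a diameter by a volume has no physical
meaning — with an `all_metrics` switch for strict parity with protocols
that normalize every raw value; percent changes are identical between the
modes whenever both groups share one imaging volume.

Group comparison reports the percent change of group means (ratio of
means). Samples are not paired across arms, so per-pair ratios are
undefined; a mean-of-ratios mode exists for sensitivity analysis. With
n = 3 per arm no inferential statistics are attached — point estimates
only.

## Preprocessing

Richardson–Lucy deconvolution maximizes the Poisson likelihood of the
observed stack under a supplied PSF; every internal convolution
reflect-pads by the PSF half-extent so no flux leaks at boundaries
(iterates are nonnegative, flux is conserved to < 0.1% for
interior-supported signals, and the Poisson divergence to the reblurred
estimate never increases). Deconvolution is off by default — segmentation
must also work on raw stacks — and defaults to 20 iterations when enabled;
the upstream protocol does not state its deconvolution settings, so these
are package conventions. A median filter (reflective boundaries) is the
denoising substitute for tool-specific denoisers.

## The phantom generator

`synth` grows seeded branching trees: binary-tree topologies (a branch
budget or a per-step branching probability), lognormal segment lengths
(mean 38 µm, log-sd 0.25, clipped to 24–70 µm in the packaged presets),
per-tree root calibers from a fixed spread around 4 µm with small lognormal
per-segment jitter, and persistent-direction random-walk embedding with
margin reflection and an occupancy-grid clearance constraint (default
10 µm) that steers growth away from earlier tubes, hairpins and parent
curl-backs. Segment polylines are chains of equal steps, so drawn lengths
are exact; drawn lengths are rescaled to exact total-length targets, and
branch budgets are exact integers — ground truth is therefore analytic, and
`SyntheticGroundTruth.recompute_from_graph` verifies the stored scalars
against the stored graph.

Rasterization is a capsule test (voxel center within the interpolated local
radius of any polyline interval; hemispherical caps at ends). Corruption
adds bright spheres (6–10 µm radius, near-unit sphericity — stand-ins for
nonspecific labelled cells), Gaussian blur (1.2 µm), and additive Gaussian
noise (sd 10 on a 20/300 background/vessel intensity scale), all
seed-deterministic. Distractors are placed clear of the vessel mask so they
remain separate objects after blurring. The suggested segmentation
threshold for phantoms is the vessel/background midpoint (160), where the
blurred tube profile crosses half-maximum and thresholding preserves
radius.

Default phantom geometry is 128×256×256 voxels at (2.0, 1.24, 1.24) µm.
The four preset pairs encode effect-size ratios exactly:
`lyve1_geometry` (branch density ×2.01 via budgets 100→201, length density
×1.75 via totals 8000→14000 µm, radius ×0.997), `lyve1_caliber` (identical
topology, radius ×0.92), `lyve1_segments` (identical structure, lengths
×0.78), `vegfr3_geometry` (length ×1.68, radius ×1.047, hence volume
×1.84). Pairs that are pure scalings reuse the reference seed in the
treated arm, so the effect applies to identical topology; both arms always
share grid and spacing, making normalization cancel in the comparison.

**What the phantoms do not emulate:** real stacks have depth-dependent
attenuation and scattering, inhomogeneous background, antibody-penetration
gradients, anastomotic loops (the presets grow trees; a loop option exists
for skeleton tests), vessel-wall intensity profiles, and genuinely
ambiguous non-vessel structures. Passing the phantom suite demonstrates
that the measurement chain is unbiased and deterministic under known
geometry and moderate noise — not that the printed filter bands are optimal
for any particular real acquisition.

## Validation summary

The test suite checks, among others: analytic shape oracles (sphere, cube,
cylinder sphericity; capsule volumes; frustum closed forms at 1e-9),
topology recovery on clean well-separated phantoms (branch counts exact,
length within 5%, diameter within 10% — conditions: radius ≥ 3 lateral
voxels, clearance parameter 14 µm, segments 35–90 µm, verified over a
12-seed sweep before freezing test seeds), 100% distractor rejection with
≥ 95% tube-foreground survival across 10 seeded scenes, Richardson–Lucy
identities, bit-reproducibility of seeded runs, and full-pipeline recovery
of every encoded effect size within 10 percentage points on 3+3 phantom
arms at full acquisition geometry (`scripts/acceptance.py` reruns this
from scratch).
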
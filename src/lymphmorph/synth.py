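"""Synthetic 3D vessel-network phantoms with exact ground truth.

The generator grows sparse branching tubular trees inside an anisotropic
voxel grid, rasterizes them into a clean stack plus clean mask, and then
corrupts the stack with blur, Gaussian noise and bright near-spherical
distractor objects (stand-ins for nonspecific labelled cells).  Every
phantom carries analytic ground truth — topology, per-segment lengths,
radii, and the clean mask — so each pipeline stage can be validated against
exact values rather than against another image-analysis tool.

Named preset pairs encode treated/reference effect-size ratios on the
normalized network metrics (branch-point density, length density, caliber,
segment length); within each pair the ratio is exact by construction:
branch budgets are integers in the stated ratio, drawn segment lengths are
rescaled to exact total-length targets, and radii carry a global scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .graphs import BRANCH, ENDPOINT, VesselGraph
from .stacks import BinaryMask, ImageStack, voxel_volume

__all__ = [
    "SynthParams",
    "SyntheticGroundTruth",
    "generate_network",
    "rasterize",
    "corrupt",
    "generate_phantom",
    "preset_pair",
    "PRESET_PAIR_NAMES",
]

# deterministic per-tree caliber spread: controlled variation in root radius
# without inflating between-arm variance of the mean squared radius
_ROOT_RADIUS_SPREAD = (0.85, 1.0, 1.15, 0.9, 1.1, 0.95, 1.05, 1.0)


@dataclass
class SynthParams:
    """Generator parameters; the seed fully determines the phantom.

    Lateral spacing defaults to 1.24 µm/px (the acquisition convention for
    the cleared-kidney stacks this emulates); the axial step is a package
    convention of 2.0 µm.  Segment lengths are lognormal in µm; radii are a
    deterministic per-tree caliber spread around ``radius_mean_um`` with a
    small lognormal per-segment jitter and a per-generation taper.
    """

    grid_shape: tuple[int, int, int] = (128, 256, 256)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = (2.0, 1.24, 1.24)  # µm
    n_roots: int = 8
    branching_probability: float = 0.35
    target_branch_count: int | None = None
    segment_length_mean_um: float = 38.0
    segment_length_sigma: float = 0.25  # log-sd of the lognormal
    segment_length_clip_um: tuple[float, float] | None = (24.0, 70.0)
    target_total_length_um: float | None = None
    length_scale: float = 1.0
    radius_mean_um: float = 4.0
    radius_jitter_sigma: float = 0.03
    radius_taper: float = 1.0  # multiplicative per generation
    radius_scale: float = 1.0
    direction_persistence: float = 8.0
    step_um: float = 4.0
    clearance_um: float = 10.0
    margin_um: float = 14.0
    vessel_intensity: float = 300.0
    background_intensity: float = 20.0
    noise_sd: float = 10.0
    blur_sigma_um: float = 1.2
    n_distractor_spheres: int = 3
    distractor_radius_um: tuple[float, float] = (6.0, 10.0)
    max_segments: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 1:
            raise ValueError("n_roots must be >= 1")
        if not (0.0 <= self.branching_probability < 1.0):
            raise ValueError("branching_probability must be in [0, 1)")
        if self.radius_mean_um * self.radius_scale < max(self.spacing) / 2:
            raise ValueError("mean radius must cover at least one voxel after rasterization")
        if min(self.vessel_intensity, self.background_intensity) < 0:
            raise ValueError("intensities must be nonnegative")
        extents = np.asarray(self.grid_shape) * np.asarray(self.spacing)
        if np.any(extents <= 2 * self.margin_um + self.step_um):
            raise ValueError(
                f"grid extents {tuple(extents)} µm cannot fit one segment inside the "
                f"{self.margin_um} µm margins"
            )

    @property
    def imaging_volume_um3(self) -> float:
        return float(np.prod(self.grid_shape)) * voxel_volume(self.spacing)

    @property
    def suggested_intensity_threshold(self) -> float:
        """Midpoint of vessel and background intensity: where the blurred tube
        profile crosses its half-maximum, so thresholding preserves radius."""
        return 0.5 * (self.vessel_intensity + self.background_intensity)


@dataclass
class SyntheticGroundTruth:
    """Exact generator-side truth for one phantom."""

    graph: VesselGraph
    branch_point_count: int
    segment_lengths_um: np.ndarray
    total_length_um: float
    mean_diameter_um: float  # length-weighted
    total_volume_um3: float  # Σ π r² l over segments
    imaging_volume_um3: float
    clean_mask: BinaryMask | None = None
    clean_mask_volume_um3: float = 0.0
    distractor_mask: BinaryMask | None = None

    def recompute_from_graph(self) -> dict:
        """Re-derive the stored scalars from the stored graph (consistency check)."""
        lengths = np.array([e.length for e in self.graph.edges])
        total = float(lengths.sum())
        diam = 0.0
        vol = 0.0
        for e in self.graph.edges:
            dl = np.linalg.norm(np.diff(e.polyline, axis=0), axis=1)
            rmid = 0.5 * (e.radii[:-1] + e.radii[1:])
            diam += float(np.sum(dl * 2 * rmid))
            vol += float(np.pi * np.sum(dl * rmid**2))
        return {
            "branch_point_count": len(self.graph.branch_points()),
            "total_length_um": total,
            "mean_diameter_um": diam / total if total else 0.0,
            "total_volume_um3": vol,
        }


# ---------------------------------------------------------------------------
# network growth
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / max(np.linalg.norm(v), 1e-12)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * np.dot(axis, v) * (1 - math.cos(angle))
    )


def _build_topology(params: SynthParams, rng: np.random.Generator):
    """Random binary-tree topologies: (parent, tree, generation) per segment.

    With a branch budget, random open tips are split until the budget is
    used; otherwise every segment end branches independently with
    ``branching_probability``.
    """
    parents: list[int] = []
    trees: list[int] = []
    generations: list[int] = []

    def new_segment(parent: int, tree: int, gen: int) -> int:
        parents.append(parent)
        trees.append(tree)
        generations.append(gen)
        return len(parents) - 1

    roots = [new_segment(-1, t, 0) for t in range(params.n_roots)]
    if params.target_branch_count is not None:
        budget = [
            params.target_branch_count // params.n_roots
            + (1 if t < params.target_branch_count % params.n_roots else 0)
            for t in range(params.n_roots)
        ]
        for t, root in enumerate(roots):
            tips = [root]
            for _ in range(budget[t]):
                tip = tips.pop(rng.integers(len(tips)))
                tips.append(new_segment(tip, t, generations[tip] + 1))
                tips.append(new_segment(tip, t, generations[tip] + 1))
    else:
        queue = list(roots)
        while queue and len(parents) < params.max_segments:
            seg = queue.pop(0)
            if rng.random() < params.branching_probability:
                queue.append(new_segment(seg, trees[seg], generations[seg] + 1))
                queue.append(new_segment(seg, trees[seg], generations[seg] + 1))
    return np.array(parents), np.array(trees), np.array(generations)


def _draw_lengths(params: SynthParams, n: int, rng: np.random.Generator) -> np.ndarray:
    mu = math.log(params.segment_length_mean_um) - params.segment_length_sigma**2 / 2
    lengths = rng.lognormal(mu, params.segment_length_sigma, size=n)
    if params.segment_length_clip_um is not None:
        lengths = np.clip(lengths, *params.segment_length_clip_um)
    if params.target_total_length_um is not None:
        lengths = lengths * (params.target_total_length_um / lengths.sum())
    return lengths * params.length_scale


def _draw_radii(
    params: SynthParams, trees: np.ndarray, generations: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    jitter = rng.lognormal(
        -params.radius_jitter_sigma**2 / 2, params.radius_jitter_sigma, size=len(trees)
    )
    spread = np.array([_ROOT_RADIUS_SPREAD[t % len(_ROOT_RADIUS_SPREAD)] for t in trees])
    return (
        params.radius_mean_um
        * spread
        * params.radius_taper**generations
        * jitter
        * params.radius_scale
    )


def generate_network(params: SynthParams) -> tuple[VesselGraph, SyntheticGroundTruth]:
    """Grow a seeded branching network and its exact ground truth.

    Segment polylines are chains of equal-length steps with persistent
    direction, reflected at the grid margins so the network stays inside the
    imaged volume; a coarse occupancy grid steers growth away from earlier
    segments to maintain inter-branch clearance.  All polyline lengths equal
    the drawn segment lengths exactly.
    """
    rng = np.random.default_rng([params.seed, 0])
    parents, trees, generations = _build_topology(params, rng)
    n_seg = len(parents)
    lengths = _draw_lengths(params, n_seg, rng)
    radii = _draw_radii(params, trees, generations, rng)

    extents = np.asarray(params.grid_shape) * np.asarray(params.spacing)
    lo = np.full(3, params.margin_um)
    hi = extents - params.margin_um

    # spread the roots: rejection-sample positions pairwise >= 4 x clearance
    root_pos: list[np.ndarray] = []
    for _ in range(params.n_roots):
        for _attempt in range(200):
            cand = lo + rng.random(3) * (hi - lo)
            if all(np.linalg.norm(cand - p) >= 4 * params.clearance_um for p in root_pos):
                break
        root_pos.append(cand)

    # occupancy grid at half-clearance resolution; a candidate step is blocked
    # when its 3x3x3 cell neighbourhood holds a mark from a foreign segment,
    # from its own path more than a few steps back (hairpin self-fusion), or
    # from the parent far from the shared junction (curl-back onto the parent)
    occupancy: dict[tuple[int, int, int], list[tuple[int, int, np.ndarray]]] = {}
    cell = params.clearance_um / 2.0
    _neigh = [np.array(o) for o in np.ndindex(3, 3, 3)]

    def occupy(pos: np.ndarray, seg: int, step: int) -> None:
        occupancy.setdefault(tuple((pos // cell).astype(int)), []).append((seg, step, pos))

    def hazard_distance(
        pos: np.ndarray, seg: int, parent: int, parent_len: int, sibling_ok: int, k: int
    ) -> float:
        """Distance to the nearest disallowed mark near ``pos`` (inf if none)."""
        base = (pos // cell).astype(int) - 1
        nearest = np.inf
        for off in _neigh:
            for owner, step, mark in occupancy.get(tuple(base + off), ()):
                if owner == seg and k - step <= 8:
                    continue  # own recent path
                if owner == parent and parent_len - step <= 4:
                    continue  # shared junction region
                if owner == sibling_ok:
                    continue
                nearest = min(nearest, float(np.linalg.norm(pos - mark)))
        return nearest

    children: dict[int, list[int]] = {}
    for i, p in enumerate(parents):
        children.setdefault(int(p), []).append(i)

    graph = VesselGraph(provenance=f"synthetic(seed={params.seed})")
    seg_end_pos: dict[int, np.ndarray] = {}
    seg_end_dir: dict[int, np.ndarray] = {}
    seg_end_node: dict[int, int] = {}
    seg_n_steps: dict[int, int] = {}
    branch_axis: dict[int, np.ndarray] = {}  # shared rotation plane per junction

    order = [i for i in range(n_seg)]  # parents precede children by construction
    for seg in order:
        parent = int(parents[seg])
        if parent == -1:
            start = root_pos[int(trees[seg])]
            direction = _unit((extents / 2 - start) + 20.0 * _random_unit(rng))
            start_node = graph.add_node(start, ENDPOINT)
            sibling = -1
        else:
            start = seg_end_pos[parent]
            if parent not in branch_axis:
                axis = np.cross(seg_end_dir[parent], _random_unit(rng))
                branch_axis[parent] = _unit(axis)
            # the two children open in opposite directions within one plane,
            # guaranteeing a wide angular separation at the junction
            angle = math.radians(rng.uniform(30.0, 50.0))
            sign = 1.0 if children[parent].index(seg) == 0 else -1.0
            direction = _unit(_rotate(seg_end_dir[parent], branch_axis[parent], sign * angle))
            start_node = seg_end_node[parent]
            sibs = children[parent]
            sibling = sibs[1 - sibs.index(seg)] if len(sibs) == 2 else -1

        n_steps = max(2, math.ceil(lengths[seg] / params.step_um))
        step_len = lengths[seg] / n_steps
        pos = start.copy()
        points = [pos.copy()]
        near_junction_steps = max(3, int(np.ceil(1.2 * params.clearance_um / step_len)))
        parent_len = seg_n_steps.get(parent, 0)
        for k in range(n_steps):
            direction = _unit(
                params.direction_persistence * direction + 0.5 * _random_unit(rng)
            )
            cand = pos + step_len * direction
            for ax in range(3):  # reflect at margins
                if cand[ax] < lo[ax] or cand[ax] > hi[ax]:
                    direction[ax] = -direction[ax]
            cand = pos + step_len * direction
            sibling_ok = sibling if k < near_junction_steps else -2

            def _hazard(p: np.ndarray) -> float:
                return hazard_distance(p, seg, parent, parent_len, sibling_ok, k)

            if _hazard(cand) < params.clearance_um:
                # steer away: evaluate rotated candidates, keep the first with
                # full clearance, else the one farthest from any blocking mark
                best_dir, best_cand, best_score = direction, cand, _hazard(cand)
                for _try in range(24):
                    alt = _unit(
                        _rotate(direction, _random_unit(rng), math.radians(rng.uniform(30, 150)))
                    )
                    alt_cand = pos + step_len * alt
                    if not (np.all(alt_cand > lo) and np.all(alt_cand < hi)):
                        continue
                    score = _hazard(alt_cand)
                    if score >= params.clearance_um:
                        best_dir, best_cand = alt, alt_cand
                        break
                    if score > best_score:
                        best_dir, best_cand, best_score = alt, alt_cand, score
                direction, cand = best_dir, best_cand
            pos = cand
            points.append(pos.copy())
            occupy(pos, seg, k)
        polyline = np.array(points)
        end_kind = BRANCH if children.get(seg) else ENDPOINT
        end_node = graph.add_node(pos.copy(), end_kind)
        graph.add_edge(
            start_node, end_node, polyline, np.full(len(polyline), radii[seg])
        )
        seg_end_pos[seg] = pos
        seg_end_dir[seg] = direction
        seg_end_node[seg] = end_node
        seg_n_steps[seg] = n_steps

    total_length = float(lengths.sum())
    truth = SyntheticGroundTruth(
        graph=graph,
        branch_point_count=len(graph.branch_points()),
        segment_lengths_um=lengths,
        total_length_um=total_length,
        mean_diameter_um=float(np.sum(lengths * 2 * radii) / total_length),
        total_volume_um3=float(np.pi * np.sum(lengths * radii**2)),
        imaging_volume_um3=params.imaging_volume_um3,
    )
    return graph, truth


# ---------------------------------------------------------------------------
# rasterization and corruption
# ---------------------------------------------------------------------------

def rasterize(
    graph: VesselGraph,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    vessel_intensity: float = 300.0,
    background_intensity: float = 20.0,
) -> tuple[ImageStack, BinaryMask]:
    """Capsule-rasterize a vessel graph onto the voxel grid.

    A voxel belongs to the clean mask iff its center lies within the locally
    interpolated tube radius of any polyline interval (capsule test, so
    segment ends carry hemispherical caps).  The clean stack is uniform
    background with vessel intensity on the mask.
    """
    spacing_arr = np.asarray(spacing, dtype=float)
    shape = np.asarray(grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    for e in graph.edges:
        pts, rads = e.polyline, e.radii
        for a in range(len(pts) - 1):
            p0, p1 = pts[a], pts[a + 1]
            r0, r1 = rads[a], rads[a + 1]
            rmax = max(r0, r1)
            bmin = np.minimum(p0, p1) - rmax
            bmax = np.maximum(p0, p1) + rmax
            i0 = np.maximum(np.floor(bmin / spacing_arr).astype(int), 0)
            i1 = np.minimum(np.ceil(bmax / spacing_arr).astype(int) + 1, shape)
            if np.any(i0 >= i1):
                continue
            zz, yy, xx = np.meshgrid(
                *[np.arange(i0[d], i1[d]) * spacing_arr[d] for d in range(3)],
                indexing="ij",
            )
            centers = np.stack([zz, yy, xx], axis=-1)
            d = p1 - p0
            dd = float(np.dot(d, d))
            if dd == 0:
                t = np.zeros(centers.shape[:-1])
            else:
                t = np.clip(np.tensordot(centers - p0, d, axes=([-1], [0])) / dd, 0.0, 1.0)
            nearest = p0 + t[..., None] * d
            dist = np.linalg.norm(centers - nearest, axis=-1)
            inside = dist <= (r0 + (r1 - r0) * t)
            sl = tuple(slice(i0[d], i1[d]) for d in range(3))
            mask[sl] |= inside
    stack = np.full(grid_shape, float(background_intensity))
    stack[mask] = float(vessel_intensity)
    return ImageStack(stack, spacing), BinaryMask(mask, spacing)


def corrupt(
    stack: ImageStack, params: SynthParams, clean_mask: BinaryMask | None = None
) -> ImageStack:
    """Blur, noise and distractor objects, seed-deterministically.

    Bright spheres (near-unit sphericity, standing in for nonspecific
    labelled cells) are placed clear of the vessel mask when one is given;
    then a Gaussian blur of ``blur_sigma_um`` and additive Gaussian noise
    (clipped at zero) are applied.  The distractor voxels are recorded on
    the returned stack as ``distractor_mask`` for audit.
    """
    rng = np.random.default_rng([params.seed, 7])
    spacing_arr = np.asarray(stack.spacing)
    shape = np.asarray(stack.shape)
    extents = shape * spacing_arr
    voxels = stack.voxels.astype(float).copy()
    distractors = np.zeros(stack.shape, dtype=bool)
    for _ in range(params.n_distractor_spheres):
        radius = rng.uniform(*params.distractor_radius_um)
        placed = False
        for _attempt in range(50):
            center = radius + 2.0 + rng.random(3) * (extents - 2 * (radius + 2.0))
            i0 = np.maximum(np.floor((center - radius) / spacing_arr).astype(int), 0)
            i1 = np.minimum(np.ceil((center + radius) / spacing_arr).astype(int) + 1, shape)
            zz, yy, xx = np.meshgrid(
                *[np.arange(i0[d], i1[d]) * spacing_arr[d] for d in range(3)],
                indexing="ij",
            )
            ball = (
                np.linalg.norm(np.stack([zz, yy, xx], -1) - center, axis=-1) <= radius
            )
            sl = tuple(slice(i0[d], i1[d]) for d in range(3))
            if clean_mask is not None:
                # keep distractors separated from vessels so they stay
                # distinct objects after blurring
                grown = tuple(
                    slice(max(i0[d] - 4, 0), min(i1[d] + 4, shape[d])) for d in range(3)
                )
                if clean_mask.voxels[grown].any():
                    continue
            distractors[sl] |= ball
            placed = True
            break
        if not placed:
            continue
    voxels[distractors] = params.vessel_intensity
    if params.blur_sigma_um > 0:
        voxels = ndimage.gaussian_filter(
            voxels, sigma=params.blur_sigma_um / spacing_arr, mode="nearest"
        )
    if params.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, params.noise_sd, size=voxels.shape)
    np.clip(voxels, 0.0, None, out=voxels)
    out = ImageStack(voxels, stack.spacing, stack.channel_name)
    out.distractor_mask = BinaryMask(distractors, stack.spacing)
    return out


def generate_phantom(
    params: SynthParams,
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Convenience: grow, rasterize and corrupt one phantom.

    Returns the corrupted stack plus the ground truth with clean mask and
    distractor audit mask attached.
    """
    graph, truth = generate_network(params)
    clean_stack, clean_mask = rasterize(
        graph,
        params.grid_shape,
        params.spacing,
        params.vessel_intensity,
        params.background_intensity,
    )
    truth.clean_mask = clean_mask
    truth.clean_mask_volume_um3 = clean_mask.foreground_volume_um3
    stack = corrupt(clean_stack, params, clean_mask=clean_mask)
    truth.distractor_mask = stack.distractor_mask
    return stack, truth


# ---------------------------------------------------------------------------
# effect-size preset pairs
# ---------------------------------------------------------------------------

PRESET_PAIR_NAMES = (
    "lyve1_geometry",
    "lyve1_caliber",
    "lyve1_segments",
    "vegfr3_geometry",
)

# pairs whose arms must be generated with the SAME seed so that the treated
# arm reuses the reference topology (the effect is a pure scaling)
TOPOLOGY_PAIRED_PRESETS = ("lyve1_caliber", "lyve1_segments", "vegfr3_geometry")

_BASE_PRESET = dict(
    grid_shape=(128, 256, 256),
    spacing=(2.0, 1.24, 1.24),
    n_roots=8,
    target_branch_count=100,
    target_total_length_um=8000.0,
    radius_mean_um=4.0,
    radius_taper=1.0,
)


def preset_pair(name: str) -> tuple[SynthParams, SynthParams]:
    """Named (reference, treated) parameter pairs with exact ground-truth
    effect sizes on the normalized metrics.

    - ``lyve1_geometry``: branch-point density ×2.01, total-length density
      ×1.75, radius scale ×0.997 (so filament-volume density ≈ ×1.74).
    - ``lyve1_caliber``: identical topology, radius scale ×0.92 (mean
      diameter −8%).
    - ``lyve1_segments``: identical branch structure, segment lengths ×0.78
      (average segment length −22%).
    - ``vegfr3_geometry``: identical topology, total-length density ×1.68,
      radius scale ×1.047 (filament-volume density ≈ ×1.84).

    Both arms always share grid extents and spacing, so imaging-volume
    normalization cancels in the group comparison.  For pairs listed in
    ``TOPOLOGY_PAIRED_PRESETS``, generate corresponding reference/treated
    phantoms with the same seed: the treated parameters do not consume
    additional randomness, so the topology is reused exactly.
    """
    reference = SynthParams(**_BASE_PRESET)
    if name == "lyve1_geometry":
        treated = replace(
            reference,
            target_branch_count=201,  # 2.01 × 100
            target_total_length_um=14000.0,  # 1.75 × 8000
            radius_scale=0.997,
        )
    elif name == "lyve1_caliber":
        treated = replace(reference, radius_scale=0.92)
    elif name == "lyve1_segments":
        treated = replace(reference, length_scale=0.78)
    elif name == "vegfr3_geometry":
        treated = replace(
            reference,
            target_total_length_um=13440.0,  # 1.68 × 8000
            radius_scale=1.047,
        )
    else:
        raise ValueError(
            f"unknown preset pair {name!r}; available: {PRESET_PAIR_NAMES}"
        )
    return reference, treated
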
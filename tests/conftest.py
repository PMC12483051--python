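import numpy as np
import pytest

from lymphmorph.graphs import VesselGraph
from lymphmorph.stacks import BinaryMask, ImageStack


@pytest.fixture
def iso_spacing():
    return (1.0, 1.0, 1.0)


@pytest.fixture
def aniso_spacing():
    return (2.0, 1.24, 1.24)


def make_ball_mask(radius_vox: float, spacing=(1.0, 1.0, 1.0), pad: int = 3) -> BinaryMask:
    """Digital ball: voxels whose center lies within radius_vox (in voxels,
    isotropically scaled by spacing for the distance test)."""
    half = int(np.ceil(radius_vox)) + pad
    n = 2 * half + 1
    zz, yy, xx = np.mgrid[:n, :n, :n] - half
    ball = zz**2 + yy**2 + xx**2 <= radius_vox**2
    return BinaryMask(ball, spacing)


def make_tube_mask(
    radius_um: float,
    length_vox: int,
    spacing=(1.0, 1.0, 1.0),
    axis: int = 2,
    pad: int = 4,
) -> BinaryMask:
    """Straight digital tube along one axis with physical radius in µm."""
    spacing = np.asarray(spacing, dtype=float)
    r_vox = np.ceil(radius_um / spacing).astype(int) + pad
    shape = np.full(3, 1)
    shape[axis] = length_vox
    shape += 2 * r_vox
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    center = (np.asarray(shape) - 1) / 2.0
    sq = 0.0
    for d in range(3):
        if d == axis:
            continue
        sq = sq + ((grids[d] - center[d]) * spacing[d]) ** 2
    mask = sq <= radius_um**2
    axial = np.abs(grids[axis] - center[axis]) <= (length_vox - 1) / 2.0
    return BinaryMask(mask & axial, tuple(spacing))


def straight_edge_graph(p0, p1, radius: float, n_points: int = 2) -> VesselGraph:
    g = VesselGraph()
    a = g.add_node(p0)
    b = g.add_node(p1)
    poly = np.linspace(p0, p1, n_points)
    g.add_edge(a, b, poly, np.full(n_points, radius))
    return g


def y_graph(edge_length: float = 50.0, radius: float = 3.0) -> VesselGraph:
    """One branch node at the origin with three straight limbs."""
    g = VesselGraph()
    center = g.add_node([0.0, 0.0, 0.0], kind="branch")
    for d in ([1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]):
        tip = np.asarray(d) * edge_length
        n = g.add_node(tip)
        poly = np.linspace([0, 0, 0], tip, 11)
        g.add_edge(center, n, poly, np.full(11, radius))
    return g


@pytest.fixture
def stack_from_mask():
    def _make(mask: BinaryMask, fg=200.0, bg=0.0) -> ImageStack:
        vox = np.full(mask.shape, float(bg))
        vox[mask.voxels] = fg
        return ImageStack(vox, mask.spacing)

    return _make
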
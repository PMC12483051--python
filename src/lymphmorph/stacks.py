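"""Core voxel containers: intensity stacks and binary masks.

Axis order is (z, y, x) everywhere in this package, matching planewise TIFF
storage.  Voxel coordinates are 0-based indices; the physical position of a
voxel center is ``index * spacing`` in micrometres.  Spacing is never
defaulted implicitly — every container carries an explicit (z, y, x) step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "BinaryMask", "voxel_volume"]


def _validate_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have three entries (z, y, x), got {spacing!r}")
    if any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"all spacing entries must be positive and finite, got {spacing!r}")
    return spacing


def voxel_volume(spacing: tuple[float, float, float]) -> float:
    """Physical volume of one voxel in µm³."""
    z, y, x = _validate_spacing(spacing)
    return z * y * x


@dataclass
class ImageStack:
    """A 3D single-channel fluorescence stack with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (Z, Y, X)
        Nonnegative finite intensities.
    spacing : (float, float, float)
        Physical step per axis in µm, ordered (z, y, x).
    channel_name : str
        Free-text marker name, e.g. ``"LYVE-1"`` or ``"VEGFR-3"``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"stack must be 3D with >=1 voxel per axis, got shape {self.voxels.shape}")
        if np.issubdtype(self.voxels.dtype, np.floating):
            if not np.all(np.isfinite(self.voxels)):
                raise ValueError("stack intensities must be finite")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("stack intensities must be nonnegative")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def imaging_volume_um3(self) -> float:
        """Physical volume of the whole acquired grid (extents × voxel size)."""
        return float(np.prod(self.voxels.shape)) * voxel_volume(self.spacing)


@dataclass
class BinaryMask:
    """A 3D boolean grid sharing the shape and spacing of its parent stack."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"mask must be 3D with >=1 voxel per axis, got shape {self.voxels.shape}")
        if self.voxels.dtype != bool:
            self.voxels = self.voxels.astype(bool)
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def foreground_volume_um3(self) -> float:
        return self.foreground_count * voxel_volume(self.spacing)

    @property
    def imaging_volume_um3(self) -> float:
        return float(np.prod(self.voxels.shape)) * voxel_volume(self.spacing)
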
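"""Published channel parameter presets for the two lymphatic markers.

The object filters and tracing gates are standardized per channel and
applied uniformly across all samples of an experiment to minimize bias;
only the absolute intensity threshold is sample-specific (it absorbs
per-mouse background variation and has no universal default).
"""

from __future__ import annotations

from .filaments import FilamentParams
from .segmentation import SegmentationParams

__all__ = ["CHANNEL_PRESETS", "segmentation_params", "filament_params"]

CHANNEL_PRESETS: dict[str, dict] = {
    "lyve1": {
        "channel_name": "LYVE-1",
        "min_voxel_count": 173,
        "sphericity_min": 0.0566,
        "sphericity_max": 0.563,
        "seed_intensity_threshold": 273.0,
        "diameter_min": 1.0,
        "diameter_max": 30.0,
    },
    "vegfr3": {
        "channel_name": "VEGFR-3",
        "min_voxel_count": 75,
        "sphericity_min": 0.0519,
        "sphericity_max": 0.665,
        "seed_intensity_threshold": 120.0,
        "diameter_min": 1.0,
        "diameter_max": 30.0,
    },
}


def segmentation_params(
    channel: str,
    intensity_threshold: float,
    connectivity: int = 26,
    keep_border_components: bool = True,
) -> SegmentationParams:
    """Segmentation parameters for a channel preset plus the sample-specific
    absolute intensity threshold."""
    p = CHANNEL_PRESETS[channel]
    return SegmentationParams(
        intensity_threshold=intensity_threshold,
        min_voxel_count=p["min_voxel_count"],
        sphericity_min=p["sphericity_min"],
        sphericity_max=p["sphericity_max"],
        connectivity=connectivity,
        keep_border_components=keep_border_components,
    )


def filament_params(channel: str, min_twig_length_factor: float = 2.0) -> FilamentParams:
    p = CHANNEL_PRESETS[channel]
    return FilamentParams(
        diameter_min=p["diameter_min"],
        diameter_max=p["diameter_max"],
        seed_intensity_threshold=p["seed_intensity_threshold"],
        min_twig_length_factor=min_twig_length_factor,
    )
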
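"""End-to-end orchestration: segment → trace → quantify → compare.

One channel preset object is shared across every sample of a run, so the
standardized filters cannot drift between groups; the only sample-specific
knob is the absolute intensity threshold.  Runs are deterministic: identical
configuration and inputs give identical outputs, and the resolved
configuration plus library versions are written next to the results.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import image_io
from .compare import GroupComparison, percent_change
from .filaments import trace_mask
from .graphs import VesselGraph
from .morphometry import MorphometryReport, measure, normalize
from .preprocess import PointSpreadFunction, median_denoise, richardson_lucy
from .presets import filament_params, segmentation_params
from .segmentation import segment_stack
from .stacks import BinaryMask, ImageStack

__all__ = ["SampleSpec", "PipelineConfig", "PipelineError", "analyze_stack", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage and sample it occurred in."""

    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample


@dataclass
class SampleSpec:
    name: str
    stack_path: str
    group: str  # "reference" or "treated"
    intensity_threshold: float | None = None  # the only per-sample override
    exclusion_path: str | None = None
    spacing_override: tuple[float, float, float] | None = None


@dataclass
class PipelineConfig:
    channel: str  # "lyve1" | "vegfr3"
    intensity_threshold: float
    samples: list[SampleSpec] = field(default_factory=list)
    denoise_radius_vox: int = 0
    deconvolve: bool = False
    psf_path: str | None = None
    rl_iterations: int = 20
    normalize_all_metrics: bool = False
    min_twig_length_factor: float = 2.0
    output_dir: str = "results"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
        return cls(samples=samples, **raw)


def analyze_stack(
    stack: ImageStack,
    channel: str,
    intensity_threshold: float,
    exclusion: BinaryMask | None = None,
    denoise_radius_vox: int = 0,
    psf: PointSpreadFunction | None = None,
    rl_iterations: int = 20,
    normalize_all_metrics: bool = False,
    min_twig_length_factor: float = 2.0,
    sample: str = "",
) -> tuple[BinaryMask, VesselGraph, MorphometryReport]:
    """Run every stage on one in-memory stack; returns mask, graph, report."""
    if denoise_radius_vox > 0:
        stack = median_denoise(stack, denoise_radius_vox)
    if psf is not None:
        stack = richardson_lucy(stack, psf, rl_iterations)
    seg = segmentation_params(channel, intensity_threshold)
    mask = segment_stack(stack, seg, exclusion=exclusion)
    graph = trace_mask(mask, stack, filament_params(channel, min_twig_length_factor))
    report = measure(graph, stack.shape, stack.spacing, sample=sample, channel=channel)
    report = normalize(report, all_metrics=normalize_all_metrics)
    return mask, graph, report


def _versions() -> dict:
    import networkx
    import numpy
    import scipy
    import skimage
    import tifffile

    import lymphmorph

    return {
        "lymphmorph": lymphmorph.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "tifffile": tifffile.__version__,
        "networkx": networkx.__version__,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Process every sample and compare treated vs reference groups.

    Per sample, writes ``<name>_mask.tif``, ``<name>_graph.swc`` and a pooled
    ``reports.csv``; writes ``comparison.csv`` when both groups are present,
    plus the resolved configuration and library versions.  Any stage error
    aborts with the stage name and sample id.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, MorphometryReport] = {}
    results: dict = {"reports": reports, "masks": {}, "graphs": {}}
    for sample in config.samples:
        try:
            stack = image_io.read_stack(
                sample.stack_path, sample.spacing_override, channel_name=config.channel
            )
        except Exception as exc:  # noqa: BLE001 - rewrap with context
            raise PipelineError("read_stack", sample.name, exc) from exc
        exclusion = None
        if sample.exclusion_path:
            try:
                exclusion = image_io.read_mask(sample.exclusion_path, stack.spacing)
            except Exception as exc:
                raise PipelineError("read_exclusion", sample.name, exc) from exc
        psf = None
        if config.deconvolve:
            if not config.psf_path:
                raise PipelineError(
                    "deconvolve", sample.name, ValueError("deconvolve=true requires psf_path")
                )
            psf_stack = image_io.read_stack(config.psf_path, stack.spacing)
            psf = PointSpreadFunction(psf_stack.voxels, psf_stack.spacing)
        threshold = (
            sample.intensity_threshold
            if sample.intensity_threshold is not None
            else config.intensity_threshold
        )
        try:
            mask, graph, report = analyze_stack(
                stack,
                config.channel,
                threshold,
                exclusion=exclusion,
                denoise_radius_vox=config.denoise_radius_vox,
                psf=psf,
                rl_iterations=config.rl_iterations,
                normalize_all_metrics=config.normalize_all_metrics,
                min_twig_length_factor=config.min_twig_length_factor,
                sample=sample.name,
            )
        except Exception as exc:
            raise PipelineError("analyze", sample.name, exc) from exc
        image_io.write_mask(mask, out_dir / f"{sample.name}_mask.tif")
        image_io.write_graph_swc(graph, out_dir / f"{sample.name}_graph.swc")
        reports[sample.name] = report
        results["masks"][sample.name] = mask
        results["graphs"][sample.name] = graph

    image_io.write_report(list(reports.values()), out_dir / "reports.csv")
    reference = [reports[s.name] for s in config.samples if s.group == "reference"]
    treated = [reports[s.name] for s in config.samples if s.group == "treated"]
    if reference and treated:
        comparison: GroupComparison = percent_change(reference, treated)
        comparison.to_frame().to_csv(out_dir / "comparison.csv", index=False)
        results["comparison"] = comparison
    config.to_yaml(out_dir / "resolved_config.yaml")
    (out_dir / "versions.json").write_text(json.dumps(_versions(), indent=2))
    return results
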
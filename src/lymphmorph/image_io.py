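"""Reading and writing stacks, masks, skeleton graphs and reports.

Stacks and masks travel as (OME-)TIFF with explicit physical voxel spacing;
skeleton graphs as SWC (positions and radii in µm); morphometry reports as
CSV.  Axis order on disk and in memory is (z, y, x): TIFF pages are z-planes.
Spacing is never silently defaulted — a stack without spacing metadata must
be read with an explicit override.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .graphs import BRANCH, ENDPOINT, VesselGraph
from .stacks import BinaryMask, ImageStack

__all__ = [
    "MissingSpacingError",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_graph_swc",
    "read_graph_swc",
    "write_report",
    "read_report",
]


class MissingSpacingError(ValueError):
    """Raised when a file carries no voxel-spacing metadata and no override is given."""


def _ome_metadata(spacing: tuple[float, float, float]) -> dict:
    z, y, x = spacing
    return {
        "axes": "ZYX",
        "PhysicalSizeZ": z,
        "PhysicalSizeY": y,
        "PhysicalSizeX": x,
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
    }


def _spacing_from_ome(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if not tif.ome_metadata:
        return None
    try:
        meta = tifffile.xml2dict(tif.ome_metadata)
        pixels = meta["OME"]["Image"]
        if isinstance(pixels, list):
            pixels = pixels[0]
        pixels = pixels["Pixels"]
        return (
            float(pixels["PhysicalSizeZ"]),
            float(pixels["PhysicalSizeY"]),
            float(pixels["PhysicalSizeX"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with PhysicalSize spacing metadata in µm."""
    tifffile.imwrite(
        str(path),
        stack.voxels,
        ome=True,
        photometric="minisblack",
        metadata=_ome_metadata(stack.spacing),
    )


def read_stack(
    path: str | Path,
    spacing_override: tuple[float, float, float] | None = None,
    channel_name: str = "",
) -> ImageStack:
    """Read a single-channel grayscale 3D TIFF/OME-TIFF.

    Spacing comes from OME ``PhysicalSize*`` metadata when present, else from
    ``spacing_override``; if neither is available a
    :class:`MissingSpacingError` is raised.  Multi-channel files are rejected:
    split channels upstream.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        spacing = _spacing_from_ome(tif)
    data = np.squeeze(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel 3D stack, got array of shape {data.shape}; "
            "split multi-channel files upstream"
        )
    if spacing is None:
        if spacing_override is None:
            raise MissingSpacingError(
                f"{path}: no voxel spacing in metadata and no spacing_override given"
            )
        spacing = spacing_override
    return ImageStack(data, spacing, channel_name=channel_name)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as uint8 OME-TIFF (0 = background, 1 = foreground)."""
    tifffile.imwrite(
        str(path),
        mask.voxels.astype(np.uint8),
        ome=True,
        photometric="minisblack",
        metadata=_ome_metadata(mask.spacing),
    )


def read_mask(
    path: str | Path, spacing: tuple[float, float, float] | None = None
) -> BinaryMask:
    """Read a binary mask; spacing from OME metadata unless overridden."""
    with tifffile.TiffFile(str(path)) as tif:
        data = np.squeeze(tif.asarray())
        meta_spacing = _spacing_from_ome(tif)
    if data.ndim == 2:
        data = data[None]
    if spacing is None:
        spacing = meta_spacing
    if spacing is None:
        raise MissingSpacingError(f"{path}: no voxel spacing available for mask")
    return BinaryMask(data > 0, spacing)


# ---------------------------------------------------------------------------
# SWC skeleton interchange
# ---------------------------------------------------------------------------

def write_graph_swc(graph: VesselGraph, path: str | Path) -> None:
    """Write a vessel graph as SWC (one row per polyline point).

    SWC columns: index, type, x, y, z, radius, parent — positions and radii
    in µm, x/y/z from the package's (z, y, x) convention.  SWC encodes
    forests; each non-tree edge of a cyclic component is broken at its far
    node (the closing point is written as a duplicate row) and the count of
    broken cycles is recorded in a ``.cycles.json`` sidecar.
    """
    path = Path(path)
    rows: list[tuple[int, int, float, float, float, float, int]] = []
    node_row: dict[int, int] = {}
    broken_cycles = 0

    def emit(position, radius, parent_row) -> int:
        idx = len(rows) + 1
        z, y, x = position
        rows.append((idx, 0, float(x), float(y), float(z), float(radius), parent_row))
        return idx

    nxg = graph.to_networkx()
    import networkx as nx

    for comp in nx.connected_components(nxg):
        comp_edges = [e for e in graph.edges if e.u in comp]
        root = min(comp)
        root_radius = 0.0
        for e in comp_edges:
            if e.u == root:
                root_radius = e.radii[0]
                break
            if e.v == root:
                root_radius = e.radii[-1]
                break
        node_row[root] = emit(graph.nodes[root].position, root_radius, -1)
        visited_nodes = {root}
        frontier = [root]
        remaining = list(comp_edges)
        while frontier:
            current = frontier.pop()
            for e in list(remaining):
                if current not in (e.u, e.v):
                    continue
                remaining.remove(e)
                oriented = e if e.u == current else e.reversed()
                parent_row = node_row[current]
                for pos, rad in zip(oriented.polyline[1:-1], oriented.radii[1:-1]):
                    parent_row = emit(pos, rad, parent_row)
                if oriented.v in visited_nodes:
                    # closing a cycle: duplicate the far node's row
                    emit(oriented.polyline[-1], oriented.radii[-1], parent_row)
                    broken_cycles += 1
                else:
                    node_row[oriented.v] = emit(
                        oriented.polyline[-1], oriented.radii[-1], parent_row
                    )
                    visited_nodes.add(oriented.v)
                    frontier.append(oriented.v)

    with open(path, "w") as fh:
        fh.write("# SWC export; positions/radii in um; columns: id type x y z radius parent\n")
        for r in rows:
            fh.write(f"{r[0]} {r[1]} {r[2]:.6f} {r[3]:.6f} {r[4]:.6f} {r[5]:.6f} {r[6]}\n")
    if broken_cycles:
        sidecar = path.with_suffix(path.suffix + ".cycles.json")
        sidecar.write_text(json.dumps({"broken_cycles": broken_cycles}))


def read_graph_swc(path: str | Path) -> VesselGraph:
    """Re-import an SWC file written by :func:`write_graph_swc`.

    Junction detection is structural: rows with exactly one child and a
    parent are polyline interior points; all other rows become graph nodes.
    """
    positions: dict[int, np.ndarray] = {}
    radii: dict[int, float] = {}
    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        idx, _typ = int(parts[0]), int(parts[1])
        x, y, z, rad = map(float, parts[2:6])
        par = int(parts[6])
        positions[idx] = np.array([z, y, x])
        radii[idx] = rad
        parent[idx] = par
        children.setdefault(idx, [])
        if par != -1:
            children.setdefault(par, []).append(idx)

    def degree(idx: int) -> int:
        return len(children[idx]) + (parent[idx] != -1)

    graph = VesselGraph(provenance=str(path))
    row_node: dict[int, int] = {}
    for idx in positions:
        d = degree(idx)
        if d != 2 or parent[idx] == -1:
            kind = BRANCH if d >= 3 else ENDPOINT
            row_node[idx] = graph.add_node(positions[idx], kind)
    for start in row_node:
        for child in children[start]:
            chain_pos = [positions[start]]
            chain_rad = [radii[start]]
            cur = child
            while cur not in row_node:
                chain_pos.append(positions[cur])
                chain_rad.append(radii[cur])
                nxt = children[cur]
                if not nxt:
                    break
                cur = nxt[0]
            if cur in row_node:
                chain_pos.append(positions[cur])
                chain_rad.append(radii[cur])
                graph.add_edge(row_node[start], row_node[cur], np.array(chain_pos), np.array(chain_rad))
            else:
                end = graph.add_node(chain_pos[-1], ENDPOINT)
                graph.add_edge(row_node[start], end, np.array(chain_pos), np.array(chain_rad))
    graph.refresh_node_kinds()
    return graph


# ---------------------------------------------------------------------------
# Tabular reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "sample",
    "channel",
    "branch_point_count",
    "total_filament_length_um",
    "avg_segment_length_um",
    "mean_diameter_um",
    "total_filament_volume_um3",
    "n_segments",
    "imaging_volume_um3",
    "branch_point_density_per_um3",
    "filament_length_density_per_um3",
    "filament_volume_density",
    "norm_avg_segment_length_um",
    "norm_mean_diameter_um",
]


def write_report(reports, path: str | Path) -> None:
    """Write one or more morphometry reports as CSV, one row per sample×channel."""
    if not isinstance(reports, (list, tuple)):
        reports = [reports]
    rows = [r.to_row() for r in reports]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(str(path), index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path))
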
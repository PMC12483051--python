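"""Spatial vessel graphs: the skeleton-derived "filament" representation.

A :class:`VesselGraph` is a spatial multigraph.  Nodes are branch points
(degree >= 3), endpoints (degree 1), or loop anchors (an arbitrary degree-2
node retained so an isolated cycle can be stored as a single closed edge).
Edges carry an ordered polyline of physical positions in µm with a local
vessel radius at every polyline point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["VesselNode", "VesselEdge", "VesselGraph"]

ENDPOINT = "endpoint"
BRANCH = "branch"
LOOP = "loop"


@dataclass(eq=False)
class VesselNode:
    id: int
    position: np.ndarray  # (3,) µm, (z, y, x)
    kind: str = ENDPOINT

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass(eq=False)
class VesselEdge:
    """A maximal node-free vessel segment.

    ``polyline`` is an (N, 3) array of (z, y, x) positions in µm ordered from
    node ``u`` to node ``v``; ``radii`` holds the local vessel radius in µm at
    each polyline point.  ``u == v`` encodes a closed loop.
    """

    u: int
    v: int
    polyline: np.ndarray
    radii: np.ndarray = None

    def __post_init__(self) -> None:
        self.polyline = np.atleast_2d(np.asarray(self.polyline, dtype=float))
        if self.polyline.shape[1] != 3:
            raise ValueError("polyline must be an (N, 3) array of (z, y, x) positions")
        if self.radii is None:
            self.radii = np.zeros(len(self.polyline))
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.shape != (len(self.polyline),):
            raise ValueError("radii must have one entry per polyline point")
        if len(self.radii) and self.radii.min() < 0:
            raise ValueError("radii must be nonnegative")

    @property
    def length(self) -> float:
        """Sum of consecutive-point Euclidean distances, in µm."""
        if len(self.polyline) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1).sum())

    @property
    def median_diameter(self) -> float:
        return float(2.0 * np.median(self.radii)) if len(self.radii) else 0.0

    def reversed(self) -> "VesselEdge":
        return VesselEdge(self.v, self.u, self.polyline[::-1].copy(), self.radii[::-1].copy())


class VesselGraph:
    """Spatial multigraph of vessel centerlines."""

    def __init__(self, provenance: str = "") -> None:
        self.nodes: dict[int, VesselNode] = {}
        self.edges: list[VesselEdge] = []
        self.provenance = provenance
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def add_node(self, position, kind: str = ENDPOINT, node_id: int | None = None) -> int:
        if node_id is None:
            node_id = self._next_id
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id}")
        self.nodes[node_id] = VesselNode(node_id, position, kind)
        self._next_id = max(self._next_id, node_id + 1)
        return node_id

    def add_edge(self, u: int, v: int, polyline, radii=None) -> VesselEdge:
        if u not in self.nodes or v not in self.nodes:
            raise KeyError("edge endpoints must be existing nodes")
        edge = VesselEdge(u, v, polyline, radii)
        self.edges.append(edge)
        return edge

    def copy(self) -> "VesselGraph":
        g = VesselGraph(self.provenance)
        for n in self.nodes.values():
            g.add_node(n.position.copy(), n.kind, node_id=n.id)
        for e in self.edges:
            g.add_edge(e.u, e.v, e.polyline.copy(), e.radii.copy())
        return g

    # -- queries ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node_id: int) -> int:
        d = 0
        for e in self.edges:
            d += (e.u == node_id) + (e.v == node_id)
        return d

    def branch_points(self) -> list[VesselNode]:
        return [n for n in self.nodes.values() if n.kind == BRANCH]

    def endpoints(self) -> list[VesselNode]:
        return [n for n in self.nodes.values() if n.kind == ENDPOINT]

    @property
    def total_length(self) -> float:
        return float(sum(e.length for e in self.edges))

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, position=n.position, kind=n.kind)
        for i, e in enumerate(self.edges):
            g.add_edge(e.u, e.v, key=i, length=e.length, edge=e)
        return g

    def connected_components(self) -> list["VesselGraph"]:
        """Split into connected filament components (isolated nodes dropped)."""
        g = self.to_networkx()
        out = []
        for comp in nx.connected_components(g):
            sub = VesselGraph(self.provenance)
            for nid in comp:
                n = self.nodes[nid]
                sub.add_node(n.position.copy(), n.kind, node_id=nid)
            for e in self.edges:
                if e.u in comp:
                    sub.add_edge(e.u, e.v, e.polyline.copy(), e.radii.copy())
            out.append(sub)
        return out

    def refresh_node_kinds(self) -> None:
        """Reclassify nodes by degree (1 -> endpoint, >=3 -> branch)."""
        for n in self.nodes.values():
            d = self.degree(n.id)
            if d >= 3:
                n.kind = BRANCH
            elif d == 1:
                n.kind = ENDPOINT
            elif d == 2:
                n.kind = LOOP

    def drop_isolated_nodes(self) -> None:
        used = set()
        for e in self.edges:
            used.add(e.u)
            used.add(e.v)
        self.nodes = {i: n for i, n in self.nodes.items() if i in used}

    def dissolve_degree2_nodes(self) -> None:
        """Merge the two incident edges of every non-loop degree-2 node.

        Needed after pruning: removing an edge at a former branch point can
        leave a degree-2 junction that is no longer a real branch.
        """
        changed = True
        while changed:
            changed = False
            for n in list(self.nodes.values()):
                incident = [e for e in self.edges if n.id in (e.u, e.v)]
                if len(incident) != 2:
                    continue
                a, b = incident
                if a is b or a.u == a.v or b.u == b.v:
                    continue  # self-loop at this node: keep as loop anchor
                if a.v != n.id:
                    a = a.reversed()
                if b.u != n.id:
                    b = b.reversed()
                merged = VesselEdge(
                    a.u,
                    b.v,
                    np.vstack([a.polyline, b.polyline[1:]]),
                    np.concatenate([a.radii, b.radii[1:]]),
                )
                self.edges = [e for e in self.edges if e not in incident]
                self.edges.append(merged)
                changed = True
                break
        self.drop_isolated_nodes()
        self.refresh_node_kinds()
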
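"""Centerline volume -> 1D vascular graph.

Every nonzero centerline voxel becomes a pressure node; nodes within one
voxel of each other (26-connectivity, diagonals included) are linked by an
edge whose length is the physical distance between voxel centers. When the
imaging yields several disconnected fragments, the largest connected
component is taken to represent the vessel tree. Degree-1 nodes are the open
ends: one of them (by convention the catheterized feeding vessel, i.e. the
thickest open end) is the pressurized root, the rest are outflow terminals;
everything else is interior.

Node ids are the flattened voxel indices of the source volume, which makes
builds deterministic and lets per-node results be painted back into image
space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from emboflow.errors import GraphError
from emboflow.volume import CenterlineVolume

ROLE_ROOT = "root"
ROLE_INTERIOR = "interior"
ROLE_TERMINAL = "terminal"

# half of the 26-neighborhood offsets; the other half is covered by symmetry
_HALF_OFFSETS = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
]


@dataclass
class VascularGraph:
    """Undirected vascular graph with physical node/edge geometry.

    Wraps a :class:`networkx.Graph` whose node attributes are ``ijk`` (voxel
    index triple), ``xyz`` (position, mm), ``radius`` (mm) and — once
    classified — ``role`` (root/interior/terminal); edge attributes are
    ``length_mm`` and ``radius_mm``.
    """

    g: nx.Graph
    root: int | None = None
    shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None
    _nodes: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._nodes = sorted(self.g.nodes)

    @property
    def nodes(self) -> list[int]:
        """Node ids in deterministic (sorted) order."""
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def terminals(self) -> list[int]:
        return [n for n in self._nodes if self.g.nodes[n].get("role") == ROLE_TERMINAL]

    def degree(self, n: int) -> int:
        return self.g.degree[n]

    def position(self, n: int) -> np.ndarray:
        return np.asarray(self.g.nodes[n]["xyz"], dtype=float)

    def radius(self, n: int) -> float:
        return float(self.g.nodes[n]["radius"])

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize nodes and edges (ids, voxel indices, mm geometry, roles)."""
        payload = {
            "root": self.root,
            "shape": list(self.shape) if self.shape else None,
            "affine": np.asarray(self.affine).tolist() if self.affine is not None else None,
            "nodes": [
                {
                    "id": int(n),
                    "ijk": [int(v) for v in self.g.nodes[n]["ijk"]],
                    "xyz_mm": [float(v) for v in self.g.nodes[n]["xyz"]],
                    "radius_mm": float(self.g.nodes[n]["radius"]),
                    "role": self.g.nodes[n].get("role"),
                }
                for n in self._nodes
            ],
            "edges": [
                {
                    "i": int(i),
                    "j": int(j),
                    "length_mm": float(d["length_mm"]),
                    "radius_mm": float(d.get("radius_mm", 0.0)),
                }
                for i, j, d in sorted(self.g.edges(data=True))
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "VascularGraph":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        g = nx.Graph()
        for nd in payload["nodes"]:
            g.add_node(
                nd["id"],
                ijk=tuple(nd["ijk"]),
                xyz=np.asarray(nd["xyz_mm"], dtype=float),
                radius=nd["radius_mm"],
                **({"role": nd["role"]} if nd.get("role") else {}),
            )
        for ed in payload["edges"]:
            g.add_edge(ed["i"], ed["j"], length_mm=ed["length_mm"], radius_mm=ed["radius_mm"])
        affine = payload.get("affine")
        return cls(
            g=g,
            root=payload.get("root"),
            shape=tuple(payload["shape"]) if payload.get("shape") else None,
            affine=np.asarray(affine) if affine is not None else None,
        )


def build_components(vol: CenterlineVolume) -> list[VascularGraph]:
    """Connected 26-neighborhood components of the centerline, largest first.

    Each nonzero voxel becomes a node; voxels within one step in every axis
    (diagonals included) are joined by an edge whose length is the Euclidean
    distance between the voxel centers under the volume affine. Components
    are sorted by node count descending, ties broken by the smallest
    flattened voxel index they contain.
    """
    values = vol.values
    shape = values.shape
    idx = np.argwhere(values > 0)
    if idx.shape[0] == 0:
        raise GraphError("volume has no centerline voxels")
    lin = np.ravel_multi_index(tuple(idx.T), shape)
    occupied = np.zeros(shape, dtype=bool)
    occupied[tuple(idx.T)] = True

    xyz = vol.voxel_to_world(idx)
    g = nx.Graph()
    for row, l in enumerate(lin):
        g.add_node(int(l), ijk=tuple(int(v) for v in idx[row]), xyz=xyz[row],
                   radius=float(values[tuple(idx[row])]))

    for off in _HALF_OFFSETS:
        nbr = idx + np.asarray(off)
        inside = np.all((nbr >= 0) & (nbr < np.asarray(shape)), axis=1)
        if not inside.any():
            continue
        sub = nbr[inside]
        hit = occupied[tuple(sub.T)]
        src = lin[inside][hit]
        dst = np.ravel_multi_index(tuple(sub[hit].T), shape)
        src_xyz = xyz[inside][hit]
        dst_xyz = vol.voxel_to_world(sub[hit])
        lengths = np.linalg.norm(src_xyz - dst_xyz, axis=1)
        for s, d, L in zip(src, dst, lengths):
            g.add_edge(int(s), int(d), length_mm=float(L))

    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return [
        VascularGraph(g=g.subgraph(c).copy(), shape=shape, affine=vol.affine.copy())
        for c in comps
    ]


def select_largest(components: list[VascularGraph]) -> VascularGraph:
    """The component with the most nodes (ties: lowest flattened voxel index)."""
    if not components:
        raise GraphError("no components to select from")
    return components[0]


def pick_root(vg: VascularGraph) -> int:
    """Default root: the degree-1 node with the largest radius.

    Anatomically the feeding (catheterized) artery is the thickest open end
    of the tree. Ties break to the smallest node id.
    """
    ends = [n for n in vg.nodes if vg.degree(n) == 1]
    if not ends:
        raise GraphError("graph has no degree-1 node to serve as root")
    return max(ends, key=lambda n: (vg.radius(n), -n))


def classify_nodes(vg: VascularGraph, root: int) -> VascularGraph:
    """Assign node roles: the given root, terminals (other degree-1 nodes),
    and interior nodes (degree >= 2). The root must be an open end."""
    if root not in vg.g:
        raise GraphError(f"root node {root} not in graph")
    if vg.degree(root) != 1:
        raise GraphError(
            f"root must have degree 1 (a pressurized open end), got degree {vg.degree(root)}"
        )
    for n in vg.nodes:
        if n == root:
            role = ROLE_ROOT
        elif vg.degree(n) == 1:
            role = ROLE_TERMINAL
        else:
            role = ROLE_INTERIOR
        vg.g.nodes[n]["role"] = role
    vg.root = root
    return vg


def edge_geometry(vg: VascularGraph, vol: CenterlineVolume | None = None) -> VascularGraph:
    """Attach per-edge radius (mean of endpoint radii, mm) and verify lengths.

    Raises if any node on the component carries a non-positive radius: a
    centerline voxel without a valid signed-distance radius cannot define a
    vessel segment.
    """
    for n in vg.nodes:
        if vg.radius(n) <= 0:
            raise GraphError(f"node {n} has non-positive radius {vg.radius(n)}")
    for i, j, d in vg.g.edges(data=True):
        d["radius_mm"] = 0.5 * (vg.radius(i) + vg.radius(j))
        if d["length_mm"] <= 0:
            raise GraphError(f"edge ({i},{j}) has non-positive length")
    return vg


def paint_nodes(vg: VascularGraph, values: dict[int, float]) -> np.ndarray:
    """Paint per-node values back into a volume of the graph's source shape.

    Node ids are flattened voxel indices, so this is the inverse of the
    voxel->node mapping; voxels off the graph stay zero.
    """
    if vg.shape is None:
        raise GraphError("graph carries no source volume shape")
    out = np.zeros(vg.shape, dtype=float)
    flat = out.ravel()
    for n, v in values.items():
        flat[n] = v
    return out


def build_graph(vol: CenterlineVolume, root_ijk: tuple[int, int, int] | None = None) -> VascularGraph:
    """Full conversion: components -> largest -> edge geometry -> node roles.

    ``root_ijk`` overrides the default largest-radius-open-end root with an
    explicit voxel index (the catheter tip location, when known).
    """
    vg = select_largest(build_components(vol))
    edge_geometry(vg, vol)
    if root_ijk is not None:
        root = int(np.ravel_multi_index(tuple(root_ijk), vol.values.shape))
        if root not in vg.g:
            raise GraphError(f"requested root voxel {root_ijk} is not on the selected component")
    else:
        root = pick_root(vg)
    return classify_nodes(vg, root)
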
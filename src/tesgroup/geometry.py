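"""Geometric substrate: triangulated cortical surfaces and tetrahedral head meshes.

Coordinates are millimetres in a right-handed frame (x right, y anterior,
z superior); node indices are 0-based.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TISSUES",
    "CorticalSurface",
    "TetMesh",
    "compute_node_normals",
    "compute_node_areas",
    "tissue_volumes",
    "icosphere",
]

#: Recognised tissue labels, outermost to innermost.
TISSUES = ("scalp", "skull", "csf", "gm", "wm")

_DEGENERATE_AREA = 1e-12  # mm^2; triangles below this poison area-weighted normals


def _triangle_normals_areas(nodes: np.ndarray, triangles: np.ndarray):
    """Per-triangle (non-unit) normal vectors and areas.

    The cross product of two edges has magnitude twice the triangle area, so
    ``normals / 2`` is the area-weighted normal used for node averaging.
    """
    p0, p1, p2 = (nodes[triangles[:, k]] for k in range(3))
    cross = np.cross(p1 - p0, p2 - p0)
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    return cross, areas


def _orient_consistently(triangles: np.ndarray) -> np.ndarray:
    """Flip triangle windings so adjacent triangles agree, via BFS over edges.

    Two triangles sharing an edge are consistently oriented when the shared
    edge appears in opposite vertex orders. Raises for non-orientable input.
    """
    tri = triangles.copy()
    n_tri = len(tri)
    edge_map: dict[tuple[int, int], list[int]] = {}
    for t in range(n_tri):
        a, b, c = tri[t]
        for u, v in ((a, b), (b, c), (c, a)):
            edge_map.setdefault((min(u, v), max(u, v)), []).append(t)

    visited = np.zeros(n_tri, dtype=bool)
    for seed in range(n_tri):
        if visited[seed]:
            continue
        visited[seed] = True
        queue = deque([seed])
        while queue:
            t = queue.popleft()
            a, b, c = tri[t]
            directed = {(a, b), (b, c), (c, a)}
            for u, v in list(directed):
                for s in edge_map[(min(u, v), max(u, v))]:
                    if s == t:
                        continue
                    sa, sb, sc = tri[s]
                    s_directed = {(sa, sb), (sb, sc), (sc, sa)}
                    consistent = (v, u) in s_directed
                    if not visited[s]:
                        if not consistent:
                            tri[s] = tri[s][::-1]
                        visited[s] = True
                        queue.append(s)
                    elif not consistent:
                        raise ValueError(
                            f"surface is not orientable (conflict at triangles {t} and {s})"
                        )
    return tri


@dataclass
class CorticalSurface:
    """Triangulated cortical (or scalp) surface with node normals and areas.

    Node normals are area-weighted averages of adjacent triangle normals;
    node areas are one third of the summed adjacent triangle areas, so that
    node areas partition the total surface area.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    node_normals: np.ndarray = field(init=False, repr=False)
    node_areas: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be an (N, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be an (M, 3) array")
        if len(self.triangles) == 0:
            raise ValueError("surface has no triangles")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.nodes):
            raise ValueError("triangle index out of range")
        _, areas = _triangle_normals_areas(self.nodes, self.triangles)
        bad = np.flatnonzero(areas < _DEGENERATE_AREA)
        if bad.size:
            raise ValueError(f"degenerate (zero-area) triangles at indices {bad.tolist()}")
        self.triangles = _orient_consistently(self.triangles)
        # Prefer outward orientation for closed surfaces: the divergence
        # theorem gives positive enclosed volume when windings point outward.
        cross, _ = _triangle_normals_areas(self.nodes, self.triangles)
        signed_volume = np.einsum("ij,ij->", self.nodes[self.triangles[:, 0]], cross) / 6.0
        if signed_volume < 0:
            self.triangles = self.triangles[:, ::-1].copy()
        self.node_normals = compute_node_normals(self)
        self.node_areas = compute_node_areas(self)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total_area(self) -> float:
        _, areas = _triangle_normals_areas(self.nodes, self.triangles)
        return float(areas.sum())

    def unit_directions(self) -> np.ndarray:
        """Unit vectors from the origin to each node (radial directions)."""
        r = np.linalg.norm(self.nodes, axis=1)
        return self.nodes / r[:, None]


def compute_node_normals(surface: CorticalSurface) -> np.ndarray:
    """Unit node normals: area-weighted average of adjacent triangle normals.

    Every node must belong to at least one triangle and the weighted sum must
    not vanish; both conditions are reported with the offending node index.
    """
    nodes, triangles = surface.nodes, surface.triangles
    cross, _ = _triangle_normals_areas(nodes, triangles)
    # cross/2 is already area * unit_normal, i.e. the area-weighted normal
    acc = np.zeros_like(nodes)
    counts = np.zeros(len(nodes), dtype=np.int64)
    for k in range(3):
        np.add.at(acc, triangles[:, k], cross / 2.0)
        np.add.at(counts, triangles[:, k], 1)
    orphan = np.flatnonzero(counts == 0)
    if orphan.size:
        raise ValueError(f"node {orphan[0]} belongs to no triangle")
    norms = np.linalg.norm(acc, axis=1)
    zero = np.flatnonzero(norms < 1e-300)
    if zero.size:
        raise ValueError(f"zero resultant normal at node {zero[0]}")
    return acc / norms[:, None]


def compute_node_areas(surface: CorticalSurface) -> np.ndarray:
    """Node areas A_i: one third of the summed areas of adjacent triangles (mm^2)."""
    _, areas = _triangle_normals_areas(surface.nodes, surface.triangles)
    node_areas = np.zeros(len(surface.nodes))
    for k in range(3):
        np.add.at(node_areas, surface.triangles[:, k], areas / 3.0)
    return node_areas


@dataclass
class TetMesh:
    """Tetrahedral volume mesh with a tissue label per element.

    Tetrahedra are reordered at construction so every signed volume is
    positive; labels must come from :data:`TISSUES`.
    """

    nodes: np.ndarray
    tetrahedra: np.ndarray
    tissue_labels: np.ndarray  # array of strings, one per tetrahedron

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tetrahedra = np.ascontiguousarray(self.tetrahedra, dtype=np.int64)
        self.tissue_labels = np.asarray(self.tissue_labels, dtype=object)
        if self.tetrahedra.ndim != 2 or self.tetrahedra.shape[1] != 4:
            raise ValueError("tetrahedra must be an (M, 4) array")
        if len(self.tissue_labels) != len(self.tetrahedra):
            raise ValueError("one tissue label per tetrahedron required")
        unknown = set(self.tissue_labels) - set(TISSUES)
        if unknown:
            raise ValueError(f"unknown tissue labels: {sorted(unknown)}; expected {TISSUES}")
        vols = self._signed_volumes()
        flip = vols < 0
        if flip.any():
            tets = self.tetrahedra.copy()
            tets[flip, 2], tets[flip, 3] = self.tetrahedra[flip, 3], self.tetrahedra[flip, 2]
            self.tetrahedra = tets

    def _signed_volumes(self) -> np.ndarray:
        p = self.nodes[self.tetrahedra]
        return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0

    @property
    def volumes(self) -> np.ndarray:
        return np.abs(self._signed_volumes())


def tissue_volumes(mesh: TetMesh) -> dict[str, float]:
    """Total volume (mm^3) per tissue, summing |det|/6 over its tetrahedra.

    Tissues with no elements are absent from the result.
    """
    vols = mesh.volumes
    out: dict[str, float] = {}
    for tissue in TISSUES:
        mask = mesh.tissue_labels == tissue
        if mask.any():
            out[tissue] = float(vols[mask].sum())
    return out


def icosphere(subdivisions: int = 3, radius: float = 1.0) -> CorticalSurface:
    """Geodesic sphere from repeated icosahedron subdivision.

    ``subdivisions`` of 2/3/4 give 162/642/2562 nodes.
    """
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return CorticalSurface(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces))
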
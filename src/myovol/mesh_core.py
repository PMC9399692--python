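"""Core triangle-mesh geometry.

Areas, area-weighted centroids, enclosed volumes, boundary-loop extraction,
watertightness checks and principal-component alignment of boundary curves
onto a reference plane.  All coordinates are millimetres in a right-handed
frame; face indices are 0-based.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeshError",
    "TriangleMesh",
    "SurfacePatch",
    "BoundaryLoop",
    "PlanarPolygon",
    "surface_area",
    "area_weighted_centroid",
    "enclosed_volume",
    "signed_volume",
    "extract_boundary_loops",
    "is_watertight",
    "align_boundary_to_plane",
    "connected_face_components",
]


class MeshError(ValueError):
    """Raised for invalid mesh input (open meshes, degenerate patches, ...)."""


@dataclass
class TriangleMesh:
    """Indexed triangle surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    faces : (m, 3) int array
        0-based vertex indices, counter-clockwise when viewed from outside.
    name : str
        Identifier used in reports and file output.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "mesh"

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshError(f"{self.name}: face index out of range")

    # -- derived quantities -------------------------------------------------
    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_cross(self) -> np.ndarray:
        tri = self.triangles
        return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross(), axis=1)

    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def bbox_diagonal(self) -> float:
        lo, hi = self.bbox()
        return float(np.linalg.norm(hi - lo))

    def copy(self, name: str | None = None) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            self.name if name is None else name)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "TriangleMesh":
        """Rigidly move the mesh: ``v -> R v + t``."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriangleMesh(v, self.faces.copy(), self.name)

    def merge_duplicate_vertices(self, decimals: int = 9) -> "TriangleMesh":
        """Weld vertices that coincide after rounding to ``decimals``."""
        key = np.round(self.vertices, decimals=decimals)
        _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
        faces = inverse[self.faces]
        keep = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 2] != faces[:, 0])
        return TriangleMesh(self.vertices[first], faces[keep], self.name)


@dataclass
class SurfacePatch:
    """A 'painted' face subset of a bone mesh (an attachment area)."""

    parent: TriangleMesh
    face_ids: np.ndarray
    role: str = "origin"

    def __post_init__(self) -> None:
        self.face_ids = np.unique(np.asarray(self.face_ids, dtype=np.int64).ravel())
        if self.face_ids.size == 0:
            raise MeshError("empty selection")
        if self.face_ids.min() < 0 or self.face_ids.max() >= len(self.parent.faces):
            raise MeshError("selection references faces outside the parent mesh")
        if self.role not in ("origin", "insertion"):
            raise MeshError(f"invalid patch role {self.role!r}")
        if len(connected_face_components(self.parent.faces[self.face_ids])) > 1:
            warnings.warn(f"patch on {self.parent.name!r} is not edge-connected",
                          stacklevel=2)

    @property
    def faces(self) -> np.ndarray:
        return self.parent.faces[self.face_ids]

    def largest_component(self) -> "SurfacePatch":
        """Patch restricted to its largest edge-connected face component."""
        comps = connected_face_components(self.faces)
        if len(comps) == 1:
            return self
        areas = self.parent.face_areas()[self.face_ids]
        best = max(comps, key=lambda c: areas[c].sum())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return SurfacePatch(self.parent, self.face_ids[best], self.role)


@dataclass
class BoundaryLoop:
    """Closed ordered polyline bounding a surface patch (closure implicit)."""

    points: np.ndarray
    orientation: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) < 3:
            raise MeshError("boundary loop needs at least 3 points")

    @property
    def length(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


@dataclass
class PlanarPolygon:
    """A boundary loop projected to its best-fit plane.

    ``transform`` is a 4x4 rigid transform whose columns are the plane axes
    (x, y), the plane normal (z) and the plane origin; it maps plane
    coordinates ``(u, v, 0)`` back to world coordinates.
    """

    points2d: np.ndarray
    transform: np.ndarray

    def __post_init__(self) -> None:
        self.points2d = np.asarray(self.points2d, dtype=np.float64).reshape(-1, 2)
        self.transform = np.asarray(self.transform, dtype=np.float64).reshape(4, 4)

    def to_world(self, points2d: np.ndarray | None = None) -> np.ndarray:
        p = self.points2d if points2d is None else np.asarray(points2d, dtype=float)
        h = np.column_stack([p, np.zeros(len(p)), np.ones(len(p))])
        return (h @ self.transform.T)[:, :3]

    @property
    def area(self) -> float:
        return abs(signed_polygon_area(self.points2d))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def surface_area(patch: SurfacePatch) -> float:
    """Total area (mm^2) of the patch faces; degenerate faces contribute 0."""
    return float(patch.parent.face_areas()[patch.face_ids].sum())


def area_weighted_centroid(patch: SurfacePatch) -> np.ndarray:
    """Area-weighted centroid (mm) of the patch faces."""
    areas = patch.parent.face_areas()[patch.face_ids]
    total = areas.sum()
    if total <= 0.0:
        raise MeshError("degenerate patch")
    cent = patch.parent.face_centroids()[patch.face_ids]
    return (cent * areas[:, None]).sum(axis=0) / total


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)


def is_watertight(mesh: TriangleMesh) -> bool:
    """True iff every edge is shared by exactly two consistently wound faces.

    A mesh with several disjoint closed components is watertight.
    """
    if len(mesh.faces) == 0:
        return False
    de = _directed_edges(mesh.faces)
    if np.any(de[:, 0] == de[:, 1]):
        return False
    # orientable: every directed edge occurs exactly once ...
    _, counts = np.unique(de, axis=0, return_counts=True)
    if np.any(counts != 1):
        return False
    # ... and its reverse occurs exactly once too.
    und = np.sort(de, axis=1)
    _, ucounts = np.unique(und, axis=0, return_counts=True)
    return bool(np.all(ucounts == 2))


def signed_volume(mesh: TriangleMesh) -> float:
    """Signed volume via the divergence theorem (no watertightness check)."""
    tri = mesh.triangles
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def enclosed_volume(mesh: TriangleMesh) -> float:
    """Volume (mm^3) enclosed by a watertight mesh."""
    if not is_watertight(mesh):
        raise MeshError("volume undefined for open mesh")
    return abs(signed_volume(mesh))


def extract_boundary_loops(patch: SurfacePatch) -> list[BoundaryLoop]:
    """Chain the once-used edges of a patch into closed loops.

    Loops are ordered by descending total length; within a loop, points follow
    the winding of the faces owning the boundary edges.
    """
    faces = patch.faces
    de = _directed_edges(faces)
    und = np.sort(de, axis=1)
    uniq, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary_mask = counts[inverse] == 1
    boundary = de[boundary_mask]
    if len(boundary) == 0:
        raise MeshError("patch has no boundary")

    succ: dict[int, list[int]] = {}
    for a, b in boundary:
        succ.setdefault(int(a), []).append(int(b))
    for v in succ.values():
        v.sort()

    loops: list[BoundaryLoop] = []
    while succ:
        start = min(succ)
        chain = [start]
        cur = start
        while True:
            nxts = succ[cur]
            nxt = nxts.pop(0)
            if not nxts:
                del succ[cur]
            if nxt == start:
                break
            chain.append(nxt)
            cur = nxt
        if len(chain) >= 3:
            loops.append(BoundaryLoop(patch.parent.vertices[chain]))
    loops.sort(key=lambda lp: lp.length, reverse=True)
    return loops


def signed_polygon_area(points2d: np.ndarray) -> float:
    """Shoelace area of a closed 2D polygon (positive = counter-clockwise)."""
    p = np.asarray(points2d, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def align_boundary_to_plane(loop: BoundaryLoop) -> PlanarPolygon:
    """Project a boundary loop onto its two largest principal directions.

    The plane is the least-squares best-fit plane (PCA): the two
    largest-variance directions become the plane axes and the smallest the
    normal.  Deterministic sign conventions: the first plane axis points so
    that the loop's first point has a non-negative first coordinate, and the
    second axis is chosen so the projected loop winds counter-clockwise.
    """
    pts = loop.points
    c = pts.mean(axis=0)
    x = pts - c
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise MeshError("degenerate boundary")
    e1, e2 = vt[0], vt[1]
    if x[0] @ e1 < 0:
        e1 = -e1
    u = x @ e1
    v = x @ e2
    if signed_polygon_area(np.column_stack([u, v])) < 0:
        e2 = -e2
        v = -v
    n = np.cross(e1, e2)
    t = np.eye(4)
    t[:3, 0], t[:3, 1], t[:3, 2], t[:3, 3] = e1, e2, n, c
    return PlanarPolygon(np.column_stack([u, v]), t)


def connected_face_components(faces: np.ndarray) -> list[np.ndarray]:
    """Partition faces into edge-connected components.

    Returns a list of index arrays into ``faces``, largest first.
    """
    m = len(faces)
    if m == 0:
        return []
    parent = np.arange(m)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edge_owner: dict[tuple[int, int], int] = {}
    for fi in range(m):
        a, b, c = faces[fi]
        for e in ((a, b), (b, c), (c, a)):
            key = (int(min(e)), int(max(e)))
            other = edge_owner.get(key)
            if other is None:
                edge_owner[key] = fi
            else:
                ra, rb = find(fi), find(other)
                if ra != rb:
                    parent[ra] = rb
    roots: dict[int, list[int]] = {}
    for fi in range(m):
        roots.setdefault(find(fi), []).append(fi)
    comps = [np.asarray(v, dtype=np.int64) for v in roots.values()]
    comps.sort(key=len, reverse=True)
    return comps
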
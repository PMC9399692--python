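"""Mesh Boolean operations for overlap removal.

A plane-based BSP solid-modelling kernel (split/clip in the style of the
classic CSG.js algorithm) computes intersections and differences between
watertight triangle meshes.  Outputs are re-welded and T-junctions are
stitched so results stay watertight.  Exactly coplanar inputs that defeat
the kernel are retried once with a deterministic 1e-6 mm jitter of the
cutter.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .mesh_core import (
    MeshError,
    TriangleMesh,
    connected_face_components,
    enclosed_volume,
    is_watertight,
    signed_volume,
)

__all__ = ["BooleanError", "OverlapReport", "intersection_volume", "subtract",
           "resolve_overlaps"]

_PLANE_EPS = 1e-6    # plane-distance classification tolerance (mm)
_WELD_TOL = 1e-7     # vertex weld radius (mm)
_TJOIN_TOL = 2e-6    # point-on-edge tolerance for T-junction stitching (mm)
_JITTER = 1e-5       # coplanarity-breaking jitter amplitude (mm), > _PLANE_EPS
_INFLATE = 1e-4      # cutter inflation for tangential (surface-on-surface) contact (mm)

_COPLANAR, _FRONT, _BACK, _SPANNING = 0, 1, 2, 3


class BooleanError(MeshError):
    """A Boolean operation failed to produce a valid solid."""


class _Poly:
    """Convex polygon: a list of xyz tuples plus its plane.

    Plain tuples and scalar arithmetic keep the clipping hot path fast; numpy
    enters only at mesh conversion boundaries.
    """

    __slots__ = ("pts", "normal", "w")

    def __init__(self, pts, normal=None, w=None):
        self.pts = pts
        if normal is None:
            # Newell's method: robust for convex polygons
            nx = ny = nz = 0.0
            n_pts = len(pts)
            for i in range(n_pts):
                (x1, y1, z1) = pts[i]
                (x2, y2, z2) = pts[(i + 1) % n_pts]
                nx += (y1 - y2) * (z1 + z2)
                ny += (z1 - z2) * (x1 + x2)
                nz += (x1 - x2) * (y1 + y2)
            norm = (nx * nx + ny * ny + nz * nz) ** 0.5
            if norm < 1e-300:
                self.normal, self.w = None, 0.0
                return
            self.normal = (nx / norm, ny / norm, nz / norm)
            x0, y0, z0 = pts[0]
            self.w = self.normal[0] * x0 + self.normal[1] * y0 + self.normal[2] * z0
        else:
            self.normal, self.w = normal, w

    def flipped(self):
        p = _Poly.__new__(_Poly)
        p.pts = self.pts[::-1]
        if self.normal is None:
            p.normal = None
        else:
            p.normal = (-self.normal[0], -self.normal[1], -self.normal[2])
        p.w = -self.w
        return p


def _split_poly(normal, w, poly, cofront, coback, front, back):
    nx, ny, nz = normal
    pts = poly.pts
    ds = []
    ptype = 0
    for (x, y, z) in pts:
        d = nx * x + ny * y + nz * z - w
        ds.append(d)
        if d < -_PLANE_EPS:
            ptype |= _BACK
        elif d > _PLANE_EPS:
            ptype |= _FRONT
    if ptype == _COPLANAR:
        pn = poly.normal
        same = nx * pn[0] + ny * pn[1] + nz * pn[2] > 0
        (cofront if same else coback).append(poly)
    elif ptype == _FRONT:
        front.append(poly)
    elif ptype == _BACK:
        back.append(poly)
    else:
        n = len(pts)
        f, b = [], []
        for i in range(n):
            j = (i + 1) % n
            di, dj = ds[i], ds[j]
            vi = pts[i]
            ti = _BACK if di < -_PLANE_EPS else (_FRONT if di > _PLANE_EPS else _COPLANAR)
            tj = _BACK if dj < -_PLANE_EPS else (_FRONT if dj > _PLANE_EPS else _COPLANAR)
            if ti != _BACK:
                f.append(vi)
            if ti != _FRONT:
                b.append(vi)
            if (ti | tj) == _SPANNING:
                t = di / (di - dj)
                vj = pts[j]
                v = (vi[0] + t * (vj[0] - vi[0]),
                     vi[1] + t * (vj[1] - vi[1]),
                     vi[2] + t * (vj[2] - vi[2]))
                f.append(v)
                b.append(v)
        if len(f) >= 3:
            front.append(_Poly(f, poly.normal, poly.w))
        if len(b) >= 3:
            back.append(_Poly(b, poly.normal, poly.w))


class _Node:
    __slots__ = ("normal", "w", "front", "back", "polys")

    def __init__(self, polys=None):
        self.normal = None
        self.w = 0.0
        self.front = None
        self.back = None
        self.polys = []
        if polys:
            self.build(polys)

    def build(self, polys):
        stack = [(self, polys)]
        while stack:
            node, plist = stack.pop()
            plist = [p for p in plist if p.normal is not None]
            if not plist:
                continue
            if node.normal is None:
                node.normal, node.w = plist[0].normal, plist[0].w
            front, back = [], []
            for p in plist:
                _split_poly(node.normal, node.w, p, node.polys, node.polys, front, back)
            if front:
                if node.front is None:
                    node.front = _Node()
                stack.append((node.front, front))
            if back:
                if node.back is None:
                    node.back = _Node()
                stack.append((node.back, back))

    def invert(self):
        stack = [self]
        while stack:
            node = stack.pop()
            node.polys = [p.flipped() for p in node.polys]
            if node.normal is not None:
                node.normal = (-node.normal[0], -node.normal[1], -node.normal[2])
                node.w = -node.w
            node.front, node.back = node.back, node.front
            if node.front is not None:
                stack.append(node.front)
            if node.back is not None:
                stack.append(node.back)

    def clip_polygons(self, polys):
        """Clip polygons against this solid, discarding interior parts."""
        out = []
        stack = [(self, polys)]
        while stack:
            node, plist = stack.pop()
            if node.normal is None:
                out.extend(plist)
                continue
            front, back = [], []
            for p in plist:
                _split_poly(node.normal, node.w, p, front, back, front, back)
            if node.front is not None:
                stack.append((node.front, front))
            else:
                out.extend(front)
            if node.back is not None:
                stack.append((node.back, back))
            # polygons behind a leaf plane are inside the solid: discarded
        return out

    def clip_to(self, other):
        stack = [self]
        while stack:
            node = stack.pop()
            node.polys = other.clip_polygons(node.polys)
            if node.front is not None:
                stack.append(node.front)
            if node.back is not None:
                stack.append(node.back)

    def all_polygons(self):
        out = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.extend(node.polys)
            if node.front is not None:
                stack.append(node.front)
            if node.back is not None:
                stack.append(node.back)
        return out


def _mesh_to_polys(mesh: TriangleMesh):
    polys = []
    for tri in mesh.triangles:
        p = _Poly([tuple(tri[0]), tuple(tri[1]), tuple(tri[2])])
        if p.normal is not None:
            polys.append(p)
    return polys


def _soup_volume(polys) -> float:
    total = 0.0
    for p in polys:
        pts = p.pts
        x0, y0, z0 = pts[0]
        for i in range(1, len(pts) - 1):
            x1, y1, z1 = pts[i]
            x2, y2, z2 = pts[i + 1]
            total += (x0 * (y1 * z2 - z1 * y2)
                      + y0 * (z1 * x2 - x1 * z2)
                      + z0 * (x1 * y2 - y1 * x2))
    return total / 6.0


def _poly_outside_bbox(poly, bbox) -> bool:
    (lox, loy, loz), (hix, hiy, hiz) = bbox
    xs = [p[0] for p in poly.pts]
    if max(xs) < lox or min(xs) > hix:
        return True
    ys = [p[1] for p in poly.pts]
    if max(ys) < loy or min(ys) > hiy:
        return True
    zs = [p[2] for p in poly.pts]
    return max(zs) < loz or min(zs) > hiz


def _overlap_bbox(apolys, bpolys, pad=1e-2):
    """Padded intersection of the two polygon soups' bounding boxes."""
    def soup_box(polys):
        pts = [p for poly in polys for p in poly.pts]
        return ((min(p[0] for p in pts), min(p[1] for p in pts),
                 min(p[2] for p in pts)),
                (max(p[0] for p in pts), max(p[1] for p in pts),
                 max(p[2] for p in pts)))

    (alo, ahi), (blo, bhi) = soup_box(apolys), soup_box(bpolys)
    lo = tuple(max(a, b) - pad for a, b in zip(alo, blo))
    hi = tuple(min(a, b) + pad for a, b in zip(ahi, bhi))
    return lo, hi


def _partition(polys, bbox):
    near, far = [], []
    for p in polys:
        (far if _poly_outside_bbox(p, bbox) else near).append(p)
    return near, far


_RAY = (0.5773502691896258, 0.2113248654051871, 0.7886751345948129)


def _point_in_soup(point, polys) -> bool:
    """Ray-casting parity test (Moeller-Trumbore against fan triangles)."""
    px, py, pz = point
    dx, dy, dz = _RAY
    crossings = 0
    for poly in polys:
        pts = poly.pts
        for i in range(1, len(pts) - 1):
            (ax, ay, az), (bx, by, bz), (cx, cy, cz) = pts[0], pts[i], pts[i + 1]
            e1 = (bx - ax, by - ay, bz - az)
            e2 = (cx - ax, cy - ay, cz - az)
            hx = dy * e2[2] - dz * e2[1]
            hy = dz * e2[0] - dx * e2[2]
            hz = dx * e2[1] - dy * e2[0]
            det = e1[0] * hx + e1[1] * hy + e1[2] * hz
            if -1e-12 < det < 1e-12:
                continue
            inv = 1.0 / det
            sx, sy, sz = px - ax, py - ay, pz - az
            u = (sx * hx + sy * hy + sz * hz) * inv
            if u < 0.0 or u > 1.0:
                continue
            qx = sy * e1[2] - sz * e1[1]
            qy = sz * e1[0] - sx * e1[2]
            qz = sx * e1[1] - sy * e1[0]
            v = (dx * qx + dy * qy + dz * qz) * inv
            if v < 0.0 or u + v > 1.0:
                continue
            t = (e2[0] * qx + e2[1] * qy + e2[2] * qz) * inv
            if t > 1e-9:
                crossings += 1
    return crossings % 2 == 1


def _poly_centroid(poly):
    n = len(poly.pts)
    return (sum(p[0] for p in poly.pts) / n,
            sum(p[1] for p in poly.pts) / n,
            sum(p[2] for p in poly.pts) / n)


def _csg_subtract(apolys, bpolys):
    """a - b, clipping only inside the bbox-overlap region.

    Target polygons wholly outside the overlap region cannot meet the cutter
    and pass through unchanged; cutter polygons there cannot contribute cut
    surface and are dropped.  This keeps far-field geometry pristine and
    prunes the cascade of splits by far-away (infinite) BSP planes.
    """
    bbox = _overlap_bbox(apolys, bpolys)
    a_near, a_far = _partition(apolys, bbox)
    b_near, _ = _partition(bpolys, bbox)
    if not b_near:
        # no cutter boundary near the target: target fully inside or outside
        if _point_in_soup(_poly_centroid(apolys[0]), bpolys):
            return []
        return list(apolys)
    if not a_near:
        # no target boundary near the cutter: cutter is a void or irrelevant
        if _point_in_soup(_poly_centroid(bpolys[0]), apolys):
            return list(apolys) + [p.flipped() for p in bpolys]
        return list(apolys)
    a, b = _Node(a_near), _Node(b_near)
    a.invert()
    a.clip_to(b)
    b.clip_to(a)
    b.invert()
    b.clip_to(a)
    b.invert()
    a.build(b.all_polygons())
    a.invert()
    return a_far + a.all_polygons()


def _csg_intersect(apolys, bpolys):
    """a intersect b; the result lies inside the bbox-overlap region."""
    bbox = _overlap_bbox(apolys, bpolys)
    a_near, _ = _partition(apolys, bbox)
    b_near, _ = _partition(bpolys, bbox)
    if not a_near:
        # the cutter region contains no target boundary: all or nothing
        return list(bpolys) if _point_in_soup(_poly_centroid(bpolys[0]), apolys) else []
    if not b_near:
        return list(apolys) if _point_in_soup(_poly_centroid(apolys[0]), bpolys) else []
    a, b = _Node(a_near), _Node(b_near)
    a.invert()
    b.clip_to(a)
    b.invert()
    a.clip_to(b)
    b.clip_to(a)
    a.build(b.all_polygons())
    a.invert()
    return a.all_polygons()


# -- soup -> watertight mesh ------------------------------------------------

def _merge_map(points: np.ndarray, radius: float) -> np.ndarray:
    """Union-find map merging every vertex cluster of the given radius."""
    parent = np.arange(len(points))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(points)
    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    return np.asarray([find(i) for i in range(len(points))])


def _weld(polys, name: str) -> TriangleMesh:
    """Merge coincident (within _WELD_TOL) vertices and fan-triangulate."""
    if not polys:
        return TriangleMesh(np.zeros((3, 3)), np.empty((0, 3), dtype=np.int64), name)
    pts = np.vstack([p.pts for p in polys])
    root = _merge_map(pts, _WELD_TOL)
    _, first, remap = np.unique(root, return_index=True, return_inverse=True)
    verts = pts[first]
    faces = []
    offset = 0
    for p in polys:
        n = len(p.pts)
        ids = remap[offset:offset + n]
        offset += n
        dedup = [ids[0]]
        for i in ids[1:]:
            if i != dedup[-1]:
                dedup.append(i)
        if len(dedup) > 1 and dedup[-1] == dedup[0]:
            dedup.pop()
        for k in range(1, len(dedup) - 1):
            tri = (int(dedup[0]), int(dedup[k]), int(dedup[k + 1]))
            if len(set(tri)) == 3:
                faces.append(tri)
    if not faces:
        return TriangleMesh(np.zeros((3, 3)), np.empty((0, 3), dtype=np.int64), name)
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64), name)


def _boundary_edges(faces: np.ndarray):
    de = faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    und = np.sort(de, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    mask = counts[inv] != 2
    face_of = np.repeat(np.arange(len(faces)), 3)
    return de[mask], face_of[mask]


def _merge_boundary_vertices(verts: np.ndarray, faces: np.ndarray) -> np.ndarray | None:
    """Collapse near-duplicate vertices incident to open edges; None if no-op."""
    bedges, _ = _boundary_edges(faces)
    if len(bedges) == 0:
        return None
    bverts = np.unique(bedges)
    root = _merge_map(verts[bverts], _TJOIN_TOL)
    if np.all(root == np.arange(len(bverts))):
        return None
    remap = np.arange(len(verts))
    remap[bverts] = bverts[root]
    faces = remap[faces]
    keep = ((faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
            & (faces[:, 2] != faces[:, 0]))
    return faces[keep]


def _drop_collinear_slivers(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Remove triangles flatter than the stitch tolerance (their apex lies on
    the opposite edge); the T-junction pass re-splits the neighbours."""
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(cross, axis=1)  # twice the area
    edges = np.stack([tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1],
                      tri[:, 0] - tri[:, 2]])
    longest = np.linalg.norm(edges, axis=2).max(axis=0)
    height = area2 / np.maximum(longest, 1e-300)
    return faces[height > 0.5 * _TJOIN_TOL]


def _stitch_tjunctions(mesh: TriangleMesh, max_passes: int = 24) -> TriangleMesh:
    """Split edges at collinear vertices until every edge is shared twice."""
    verts = mesh.vertices
    faces = mesh.faces
    for _ in range(max_passes):
        faces = _drop_collinear_slivers(verts, faces)
        merged = _merge_boundary_vertices(verts, faces)
        if merged is not None:
            faces = merged
        bedges, bfaces = _boundary_edges(faces)
        if len(bedges) == 0:
            break
        cand = np.unique(faces)  # any referenced vertex may be a T-vertex
        cpts = verts[cand]
        new_faces = list(map(tuple, faces))
        touched: set[int] = set()
        changed = False
        for (a, b), fi in zip(bedges, bfaces):
            if fi in touched:
                continue
            pa, pb = verts[a], verts[b]
            ab = pb - pa
            ln2 = ab @ ab
            if ln2 < 1e-24:
                continue
            t = (cpts - pa) @ ab / ln2
            on = (t > 1e-9) & (t < 1 - 1e-9)
            if not np.any(on):
                continue
            proj = pa + t[:, None] * ab
            dist = np.linalg.norm(cpts - proj, axis=1)
            on &= dist < _TJOIN_TOL
            on &= (cand != a) & (cand != b)
            if not np.any(on):
                continue
            pick = int(cand[np.where(on)[0][np.argmin(t[on])]])
            fa, fb, fc = faces[fi]
            # rotate so the split edge is (fa, fb)
            for _ in range(3):
                if (fa, fb) == (a, b) or (fa, fb) == (b, a):
                    break
                fa, fb, fc = fb, fc, fa
            new_faces[fi] = (fa, pick, fc)
            new_faces.append((pick, fb, fc))
            touched.add(fi)
            changed = True
        if not changed:
            break
        faces = np.asarray(new_faces, dtype=np.int64)
    return TriangleMesh(verts, faces, mesh.name)


def _remove_duplicate_faces(faces: np.ndarray) -> np.ndarray:
    """Drop repeated faces: same-orientation copies keep one, an
    opposite-orientation pair is a null wall and both are dropped."""
    seen: dict[tuple, list[int]] = {}
    for i, f in enumerate(faces):
        seen.setdefault(tuple(sorted(map(int, f))), []).append(i)
    keep = np.ones(len(faces), dtype=bool)
    for ids in seen.values():
        if len(ids) == 1:
            continue
        def orient(fi):  # canonical rotation preserving winding
            f = list(map(int, faces[fi]))
            k = f.index(min(f))
            return tuple(f[k:] + f[:k])
        groups: dict[tuple, list[int]] = {}
        for fi in ids:
            groups.setdefault(orient(fi), []).append(fi)
        orientations = list(groups.values())
        if len(orientations) == 2:  # both windings present: cancel pairwise
            n_pairs = min(len(orientations[0]), len(orientations[1]))
            for g in orientations:
                for fi in g[:n_pairs]:
                    keep[fi] = False
                for fi in g[n_pairs + 1:]:
                    keep[fi] = False
        else:
            for g in orientations:
                for fi in g[1:]:
                    keep[fi] = False
    return faces[keep]


def _polys_to_mesh(polys, name: str) -> TriangleMesh:
    mesh = _weld(polys, name)
    if len(mesh.faces) == 0:
        return mesh
    mesh = TriangleMesh(mesh.vertices, _remove_duplicate_faces(mesh.faces), name)
    return _stitch_tjunctions(mesh)


# -- public operations ------------------------------------------------------

def _require_watertight(*meshes: TriangleMesh) -> None:
    for m in meshes:
        if not is_watertight(m):
            raise MeshError(f"{m.name}: open mesh; Boolean operations need "
                            "watertight input")


def _bbox_disjoint(a: TriangleMesh, b: TriangleMesh, pad: float = 0.0) -> bool:
    alo, ahi = a.bbox()
    blo, bhi = b.bbox()
    return bool(np.any(ahi + pad < blo) or np.any(bhi + pad < alo))


def _jittered(mesh: TriangleMesh, seed: int = 0) -> TriangleMesh:
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-_JITTER, _JITTER, size=mesh.vertices.shape)
    return TriangleMesh(mesh.vertices + noise, mesh.faces.copy(), mesh.name)


def _inflated(mesh: TriangleMesh, eps: float = _INFLATE) -> TriangleMesh:
    """Push every vertex outward along its area-weighted normal."""
    fn = mesh.face_cross()
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1)
    ok = norms > 1e-300
    vn[ok] /= norms[ok, None]
    return TriangleMesh(mesh.vertices + eps * vn, mesh.faces.copy(), mesh.name)


def _tangential_contact(target: TriangleMesh, cutter: TriangleMesh) -> bool:
    """True if any target vertex lies (nearly) on a cutter face plane.

    Surface-on-surface contact defeats plane-based clipping; callers switch
    to an epsilon-inflated cutter in that case.
    """
    n = cutter.face_cross()
    norms = np.linalg.norm(n, axis=1)
    valid = norms > 1e-12
    n = n[valid] / norms[valid, None]
    w = np.einsum("ij,ij->i", n, cutter.triangles[valid, 0])
    d = np.abs(target.vertices @ n.T - w)
    near_plane = d < 10 * _PLANE_EPS
    return bool(near_plane.any())


def intersection_volume(a: TriangleMesh, b: TriangleMesh) -> float:
    """Volume (mm^3) of the Boolean intersection of two watertight meshes."""
    _require_watertight(a, b)
    if _bbox_disjoint(a, b):
        return 0.0
    polys = _csg_intersect(_mesh_to_polys(a), _mesh_to_polys(b))
    return abs(_soup_volume(polys))


def subtract(target: TriangleMesh, cutter: TriangleMesh,
             name: str | None = None) -> TriangleMesh:
    """Watertight Boolean difference ``target - cutter``."""
    _require_watertight(target, cutter)
    name = name or target.name
    if _bbox_disjoint(target, cutter):
        return target.copy(name=name)
    vol_t = enclosed_volume(target)

    face_budget = 60 * (len(target.faces) + len(cutter.faces)) + 1000

    def attempt(cut: TriangleMesh) -> TriangleMesh | None:
        polys = _csg_subtract(_mesh_to_polys(target), _mesh_to_polys(cut))
        if len(polys) > face_budget:
            return None  # clipping cascade: a different strategy is needed
        mesh = _polys_to_mesh(polys, name)
        if len(mesh.faces) == 0:
            return mesh  # cutter swallowed the target entirely
        if not is_watertight(mesh):
            return None
        if abs(signed_volume(mesh)) > vol_t * (1 + 1e-6):
            return None
        if signed_volume(mesh) < 0:
            mesh.faces = mesh.faces[:, ::-1].copy()
        return mesh

    if _tangential_contact(target, cutter):
        # surface-on-surface contact: clip against a hair-inflated cutter so
        # every intersection is transversal (volume bias ~ area * _INFLATE)
        attempts = [_inflated(cutter), _jittered(_inflated(cutter))]
    else:
        attempts = [cutter, _inflated(cutter), _jittered(cutter)]
    result = None
    for i, cut in enumerate(attempts):
        if i > 0:
            warnings.warn(f"Boolean {target.name} - {cutter.name} degenerate; "
                          "retrying with perturbed cutter", stacklevel=2)
        result = attempt(cut)
        if result is not None:
            break
    if result is None:
        raise BooleanError(
            f"Boolean difference {target.name} - {cutter.name} failed "
            f"(likely exact coplanarity); hint: jitter inputs by ~{_JITTER:g} mm")
    return result


@dataclass
class OverlapReport:
    """One handled overlap: which pair intersected and which mesh was cut."""

    pair: tuple[str, str]
    intersection_volume: float
    resolved: bool
    loser: str

    def to_dict(self) -> dict:
        return {"pair": list(self.pair),
                "intersection_volume": self.intersection_volume,
                "resolved": self.resolved, "loser": self.loser}


def _largest_closed_component(mesh: TriangleMesh) -> TriangleMesh:
    comps = connected_face_components(mesh.faces)
    if len(comps) <= 1:
        return mesh
    warnings.warn(f"{mesh.name}: subtraction split the mesh into "
                  f"{len(comps)} components; keeping the largest", stacklevel=2)
    best, best_vol = None, -1.0
    for c in comps:
        sub = TriangleMesh(mesh.vertices, mesh.faces[c], mesh.name)
        v = abs(signed_volume(sub))
        if v > best_vol:
            best, best_vol = sub, v
    return best.merge_duplicate_vertices(decimals=12)


def resolve_overlaps(muscles, bones, priority=None):
    """Subtract bone overlap from every muscle, then resolve muscle pairs.

    For each intersecting muscle pair the lower-priority muscle is cut by the
    higher-priority one.  ``priority`` is an ordered list of muscle names
    (earlier wins); default is creation order.  Returns the updated muscles
    and a report of every nonzero overlap handled.
    """
    muscles = list(muscles)
    names = [m.name for m in muscles]
    if priority is None:
        priority = names
    rank = {n: i for i, n in enumerate(priority)}
    missing = [n for n in names if n not in rank]
    if missing:
        raise MeshError(f"priority list missing muscles: {missing}")

    reports: list[OverlapReport] = []

    def tol(mesh: TriangleMesh) -> float:
        return max(1e-6 * abs(signed_volume(mesh)), 1e-9)

    for i, muscle in enumerate(muscles):
        mesh = muscle.mesh
        for bone in bones:
            iv = intersection_volume(mesh, bone)
            if iv > tol(mesh):
                mesh = _largest_closed_component(subtract(mesh, bone))
                residual = intersection_volume(mesh, bone)
                reports.append(OverlapReport((muscle.name, bone.name), iv,
                                             residual <= tol(mesh), muscle.name))
        if mesh is not muscle.mesh:
            muscles[i] = replace(muscle, mesh=mesh)

    order = sorted(range(len(muscles)), key=lambda i: rank[muscles[i].name])
    for a_pos in range(len(order)):
        for b_pos in range(a_pos + 1, len(order)):
            hi, lo = muscles[order[a_pos]], muscles[order[b_pos]]
            iv = intersection_volume(hi.mesh, lo.mesh)
            if iv > tol(lo.mesh):
                cut = _largest_closed_component(subtract(lo.mesh, hi.mesh))
                residual = intersection_volume(hi.mesh, cut)
                muscles[order[b_pos]] = replace(lo, mesh=cut)
                reports.append(OverlapReport((hi.name, lo.name), iv,
                                             residual <= tol(cut), lo.name))
    return muscles, reports
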
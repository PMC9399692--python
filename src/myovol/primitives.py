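"""Simple procedural meshes used by fixtures and tests."""
from __future__ import annotations

import numpy as np

from .mesh_core import TriangleMesh

__all__ = ["box", "icosphere", "closed_cylinder", "grid_plane"]

# corner order: binary xyz
_BOX_FACES = np.array([
    [0, 1, 3], [0, 3, 2],      # x = lo
    [4, 7, 5], [4, 6, 7],      # x = hi
    [0, 5, 1], [0, 4, 5],      # y = lo
    [2, 3, 7], [2, 7, 6],      # y = hi
    [0, 2, 6], [0, 6, 4],      # z = lo
    [1, 5, 7], [1, 7, 3],      # z = hi
], dtype=np.int64)


def box(center=(0.0, 0.0, 0.0), size=(1.0, 1.0, 1.0), name: str = "box") -> TriangleMesh:
    """Axis-aligned closed box with outward-facing triangles."""
    center = np.asarray(center, dtype=float)
    half = 0.5 * np.asarray(size, dtype=float)
    corners = np.array([[x, y, z] for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)], dtype=float)
    verts = center + corners * half
    mesh = TriangleMesh(verts, _BOX_FACES.copy(), name)
    # _BOX_FACES above is written for the x-fastest corner order; fix winding
    # globally in case of sign slips.
    from .mesh_core import signed_volume
    if signed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def icosphere(radius: float = 1.0, subdivisions: int = 2,
              center=(0.0, 0.0, 0.0), name: str = "icosphere") -> TriangleMesh:
    """Icosahedron subdivided ``subdivisions`` times, projected to a sphere."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [v / np.linalg.norm(v) for v in verts]

    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            idx = cache.get(key)
            if idx is None:
                m = verts[a] + verts[b]
                verts.append(m / np.linalg.norm(m))
                idx = len(verts) - 1
                cache[key] = idx
            return idx

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces

    v = np.asarray(verts) * radius + np.asarray(center, dtype=float)
    return TriangleMesh(v, np.asarray(faces, dtype=np.int64), name)


def closed_cylinder(radius: float, length: float, sections: int = 32,
                    center=(0.0, 0.0, 0.0), name: str = "cylinder") -> TriangleMesh:
    """Closed polygonal cylinder along +z, base at z=0 relative to center."""
    ang = 2 * np.pi * np.arange(sections) / sections
    ring = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(sections)])
    bottom = ring.copy()
    top = ring + [0, 0, length]
    verts = np.vstack([bottom, top, [[0, 0, 0]], [[0, 0, length]]])
    cb, ct = 2 * sections, 2 * sections + 1
    faces = []
    for i in range(sections):
        j = (i + 1) % sections
        faces += [(i, j, sections + j), (i, sections + j, sections + i)]
        faces += [(cb, j, i), (ct, sections + i, sections + j)]
    verts = verts + np.asarray(center, dtype=float)
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64), name)


def grid_plane(extent: float = 5.0, divisions: int = 10, name: str = "grid") -> TriangleMesh:
    """Flat triangulated square grid in the z=0 plane, centred on the origin."""
    coords = np.linspace(-extent, extent, divisions + 1)
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    n = divisions + 1
    faces = []
    for i in range(divisions):
        for j in range(divisions):
            a = i * n + j
            b = (i + 1) * n + j
            faces += [(a, b, a + 1), (a + 1, b, b + 1)]
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64), name)
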
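"""Mesh and selection-file input/output.

Supported mesh formats: Wavefront OBJ, ASCII PLY and ASCII STL (read and
write).  Files carry no unit field; coordinates are millimetres by
convention.  Attachment selections are JSON sidecars::

    {"mesh": "<mesh name>", "muscle": "<muscle name>",
     "role": "origin" | "insertion", "faces": [0-based face indices]}
"""
from __future__ import annotations

import json
import os

import numpy as np

from .mesh_core import MeshError, SurfacePatch, TriangleMesh

__all__ = ["load_mesh", "save_mesh", "load_selection", "save_selection",
           "patch_from_selection"]


def load_mesh(path: str, name: str | None = None) -> TriangleMesh:
    """Load a triangle mesh, dispatching on file extension."""
    ext = os.path.splitext(path)[1].lower()
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    if ext == ".obj":
        return _read_obj(path, name)
    if ext == ".ply":
        return _read_ply(path, name)
    if ext == ".stl":
        return _read_stl(path, name)
    raise MeshError(f"unsupported mesh format: {path}")


def save_mesh(mesh: TriangleMesh, path: str) -> None:
    """Write a triangle mesh, dispatching on file extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obj":
        _write_obj(mesh, path)
    elif ext == ".ply":
        _write_ply(mesh, path)
    elif ext == ".stl":
        _write_stl(mesh, path)
    else:
        raise MeshError(f"unsupported mesh format: {path}")


# -- OBJ --------------------------------------------------------------------

def _read_obj(path: str, name: str) -> TriangleMesh:
    verts: list[list[float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = []
                for token in parts[1:]:
                    i = int(token.split("/")[0])
                    idx.append(i - 1 if i > 0 else len(verts) + i)
                for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                    faces.append((idx[0], idx[k], idx[k + 1]))
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64), name)


def _write_obj(mesh: TriangleMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"o {mesh.name}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# -- PLY (ascii) ------------------------------------------------------------

def _read_ply(path: str, name: str) -> TriangleMesh:
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise MeshError(f"{path}: not a PLY file")
        n_vert = n_face = 0
        vert_props: list[str] = []
        element = None
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "format":
                if parts[1] != "ascii":
                    raise MeshError(f"{path}: only ascii PLY is supported")
            elif parts[0] == "element":
                element = parts[1]
                if element == "vertex":
                    n_vert = int(parts[2])
                elif element == "face":
                    n_face = int(parts[2])
            elif parts[0] == "property" and element == "vertex":
                vert_props.append(parts[-1])
            elif parts[0] == "end_header":
                break
        try:
            cols = [vert_props.index(ax) for ax in ("x", "y", "z")]
        except ValueError as exc:
            raise MeshError(f"{path}: vertex x/y/z properties missing") from exc
        verts = np.empty((n_vert, 3))
        for i in range(n_vert):
            vals = fh.readline().split()
            verts[i] = [float(vals[c]) for c in cols]
        faces = []
        for _ in range(n_face):
            vals = [int(x) for x in fh.readline().split()]
            idx = vals[1:1 + vals[0]]
            for k in range(1, len(idx) - 1):
                faces.append((idx[0], idx[k], idx[k + 1]))
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64), name)


def _write_ply(mesh: TriangleMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment {mesh.name}\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# -- STL (ascii) ------------------------------------------------------------

def _read_stl(path: str, name: str) -> TriangleMesh:
    verts: list[tuple[float, float, float]] = []
    index: dict[tuple[float, float, float], int] = {}
    faces: list[tuple[int, int, int]] = []
    tri: list[int] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "vertex":
                p = (float(parts[1]), float(parts[2]), float(parts[3]))
                i = index.get(p)
                if i is None:
                    i = len(verts)
                    verts.append(p)
                    index[p] = i
                tri.append(i)
                if len(tri) == 3:
                    faces.append(tuple(tri))
                    tri = []
    if not faces:
        raise MeshError(f"{path}: no facets found (binary STL is not supported)")
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64), name)


def _write_stl(mesh: TriangleMesh, path: str) -> None:
    tri = mesh.triangles
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1)
    normals = np.where(norms[:, None] > 0, normals / np.maximum(norms, 1e-300)[:, None], 0.0)
    with open(path, "w") as fh:
        fh.write(f"solid {mesh.name}\n")
        for t, n in zip(tri, normals):
            fh.write(f"facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n outer loop\n")
            for v in t:
                fh.write(f"  vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write(f"endsolid {mesh.name}\n")


# -- selections -------------------------------------------------------------

def load_selection(path: str) -> dict:
    """Read an attachment-selection sidecar and validate its fields."""
    with open(path) as fh:
        sel = json.load(fh)
    for key in ("mesh", "muscle", "role", "faces"):
        if key not in sel:
            raise MeshError(f"{path}: selection missing field {key!r}")
    if sel["role"] not in ("origin", "insertion"):
        raise MeshError(f"{path}: role must be 'origin' or 'insertion'")
    sel["faces"] = [int(i) for i in sel["faces"]]
    return sel


def save_selection(selection: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"mesh": selection["mesh"], "muscle": selection["muscle"],
                   "role": selection["role"],
                   "faces": [int(i) for i in selection["faces"]]}, fh, indent=1)
        fh.write("\n")


def patch_from_selection(selection: dict, meshes: dict[str, TriangleMesh]) -> SurfacePatch:
    """Resolve a selection record against a name -> mesh mapping."""
    name = selection["mesh"]
    if name not in meshes:
        raise MeshError(f"selection references unknown mesh {name!r}")
    return SurfacePatch(meshes[name], np.asarray(selection["faces"], dtype=np.int64),
                        selection["role"])
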
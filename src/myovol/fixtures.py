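"""Deterministic synthetic scenes with analytic ground truth.

Every fixture provides bone meshes, attachment selections and an ``expected``
table of closed-form quantities (with explicit tolerances) so the whole
pipeline can be exercised without any real specimen data.  Builders are pure
functions of their arguments: regenerating with the same inputs is
bit-identical.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .io import save_mesh, save_selection
from .mesh_core import TriangleMesh

__all__ = ["FixtureScene", "make_parallel_plates", "make_curved_channel",
           "make_overlap_pair", "polygon_disc_area", "lens_area"]


@dataclass
class FixtureScene:
    """A generated test scene plus its analytic expectation table."""

    bones: list[TriangleMesh]
    selections: list[dict]
    offsets: list[dict] = field(default_factory=list)
    sweep: dict = field(default_factory=dict)
    priority: list[str] = field(default_factory=list)
    expected: dict = field(default_factory=dict)
    seed: int = 0

    def write(self, out_dir: str) -> str:
        """Write meshes, selections, expectations and a runnable config.

        Returns the path of the generated config JSON.
        """
        os.makedirs(out_dir, exist_ok=True)
        bone_paths = []
        for bone in self.bones:
            p = f"{bone.name}.obj"
            save_mesh(bone, os.path.join(out_dir, p))
            bone_paths.append(p)
        sel_paths = []
        for sel in self.selections:
            p = f"sel_{sel['muscle']}_{sel['role']}.json"
            save_selection(sel, os.path.join(out_dir, p))
            sel_paths.append(p)
        with open(os.path.join(out_dir, "expected.json"), "w") as fh:
            json.dump(self.expected, fh, indent=1)
        config = {"bones": bone_paths, "selections": sel_paths,
                  "offsets": self.offsets, "sweep": self.sweep,
                  "priority": self.priority, "stress": 0.3, "seed": self.seed}
        cfg_path = os.path.join(out_dir, "config.json")
        with open(cfg_path, "w") as fh:
            json.dump(config, fh, indent=1)
        return cfg_path


def polygon_disc_area(radius: float, k: int) -> float:
    """Area of the inscribed regular k-gon (the discretized disc)."""
    return 0.5 * k * radius * radius * float(np.sin(2 * np.pi / k))


def lens_area(radius: float, offset: float) -> float:
    """Intersection area of two congruent circles with centre distance
    ``offset`` (circular-segment lens formula)."""
    if offset >= 2 * radius:
        return 0.0
    if offset <= 0:
        return float(np.pi * radius * radius)
    return float(2 * radius * radius * np.arccos(offset / (2 * radius))
                 - 0.5 * offset * np.sqrt(4 * radius * radius - offset * offset))


def _puck(center, axes: np.ndarray, patch_radius: float, outer_radius: float,
          thickness: float, k: int, name: str) -> tuple[TriangleMesh, np.ndarray]:
    """Closed plate with an explicit inscribed-polygon patch on its face.

    ``axes`` columns are (e1, e2, n); the patch surface lies in the plane
    through ``center`` with normal ``n`` (the plate body extends behind it).
    Returns the mesh and the face ids of the circular patch (a k-triangle fan
    whose area is exactly the inscribed k-gon area).
    """
    ang = 2 * np.pi * np.arange(k) / k
    ca, sa = np.cos(ang), np.sin(ang)
    zeros = np.zeros(k)
    inner = np.column_stack([patch_radius * ca, patch_radius * sa, zeros])
    outer_top = np.column_stack([outer_radius * ca, outer_radius * sa, zeros])
    outer_bot = outer_top + [0, 0, -thickness]
    local = np.vstack([[[0, 0, 0]], inner, outer_top, outer_bot, [[0, 0, -thickness]]])
    bc = 3 * k + 1
    faces = []
    for i in range(k):
        j = (i + 1) % k
        faces.append((0, 1 + i, 1 + j))                                # patch fan
    for i in range(k):
        j = (i + 1) % k
        faces.append((1 + i, 1 + k + i, 1 + k + j))                    # annulus
        faces.append((1 + i, 1 + k + j, 1 + j))
        faces.append((1 + k + i, 1 + 2 * k + i, 1 + 2 * k + j))        # wall
        faces.append((1 + k + i, 1 + 2 * k + j, 1 + k + j))
        faces.append((bc, 1 + 2 * k + j, 1 + 2 * k + i))               # bottom
    world = np.asarray(center, dtype=float) + local @ np.asarray(axes, dtype=float).T
    mesh = TriangleMesh(world, np.asarray(faces, dtype=np.int64), name)
    return mesh, np.arange(k, dtype=np.int64)


def _frame(normal, e1) -> np.ndarray:
    n = np.asarray(normal, dtype=float)
    e1 = np.asarray(e1, dtype=float)
    e2 = np.cross(n, e1)
    return np.column_stack([e1, e2, n])


def make_parallel_plates(radius: float, gap: float, resolution: int = 64,
                         seed: int = 0, insertion_radius: float | None = None) -> FixtureScene:
    """Two facing plates carrying circular patches: a straight cylindrical
    muscle with analytic area/centroid/length/volume expectations."""
    if radius <= 0 or gap <= 0:
        raise ValueError("radius and gap must be positive")
    r_ins = radius if insertion_radius is None else insertion_radius
    k = resolution
    outer = 1.5 * max(radius, r_ins, 1.0)
    plate_o, patch_o = _puck((0, 0, 0), _frame((0, 0, 1), (1, 0, 0)),
                             radius, outer, 1.0, k, "plate_origin")
    plate_i, patch_i = _puck((0, 0, gap), _frame((0, 0, -1), (1, 0, 0)),
                             r_ins, outer, 1.0, k, "plate_insertion")
    a_or = polygon_disc_area(radius, k)
    a_ins = polygon_disc_area(r_ins, k)
    mean_r2 = (radius**2 + radius * r_ins + r_ins**2) / 3.0  # conical frustum
    expected = {
        "origin_area": {"value": float(np.pi * radius**2), "tol": 0.01, "cmp": "rel"},
        "insertion_area": {"value": float(np.pi * r_ins**2), "tol": 0.01, "cmp": "rel"},
        "origin_centroid": {"value": [0.0, 0.0, 0.0], "tol": 1e-6, "cmp": "abs"},
        "insertion_centroid": {"value": [0.0, 0.0, gap], "tol": 1e-6, "cmp": "abs"},
        "linear_length": {"value": gap, "tol": 1e-9, "cmp": "rel"},
        "muscle_length": {"value": gap, "tol": 1e-9, "cmp": "rel"},
        "volume": {"value": float(np.pi * mean_r2 * gap),
                   "tol": 0.03 if r_ins != radius else 0.02, "cmp": "rel"},
        "exact_origin_area": {"value": a_or, "tol": 1e-9, "cmp": "rel"},
        "exact_insertion_area": {"value": a_ins, "tol": 1e-9, "cmp": "rel"},
    }
    selections = [
        {"mesh": "plate_origin", "muscle": "muscle", "role": "origin",
         "faces": patch_o.tolist()},
        {"mesh": "plate_insertion", "muscle": "muscle", "role": "insertion",
         "faces": patch_i.tolist()},
    ]
    return FixtureScene(bones=[plate_o, plate_i], selections=selections,
                        sweep={"ring_vertex_count": k, "blend": "linear_blend",
                               "n_control": 2, "n_samples": 8},
                        priority=["muscle"], expected=expected, seed=seed)


def make_curved_channel(radius_curve: float, radius_xsec: float,
                        resolution: int = 64, seed: int = 0) -> FixtureScene:
    """Quarter-circle muscle: exercises curved- vs linear-length divergence.

    The centerline control points are pushed onto a quarter arc of radius
    ``radius_curve`` in the XY plane; the circular cross-section has radius
    ``radius_xsec``.  Expected values follow from closed forms (arc length,
    chord length, Pappus' centroid theorem).
    """
    if radius_curve <= radius_xsec:
        raise ValueError("radius_curve must exceed radius_xsec")
    big_r, r = float(radius_curve), float(radius_xsec)
    k = resolution
    outer = 1.5 * max(r, 1.0)
    p0 = np.array([big_r, 0.0, 0.0])
    p1 = np.array([0.0, big_r, 0.0])
    plate_o, patch_o = _puck(p0, _frame((0, 1, 0), (1, 0, 0)), r, outer, 1.0, k,
                             "plate_origin")
    plate_i, patch_i = _puck(p1, _frame((1, 0, 0), (0, 1, 0)), r, outer, 1.0, k,
                             "plate_insertion")

    n_control = 9
    t = np.linspace(0.0, 1.0, n_control)[:, None]
    straight = p0 * (1 - t) + p1 * t
    theta = (np.pi / 2) * np.linspace(0.0, 1.0, n_control)
    arc = np.column_stack([big_r * np.cos(theta), big_r * np.sin(theta),
                           np.zeros(n_control)])
    offsets = [[int(i)] + list(arc[i] - straight[i]) for i in range(1, n_control - 1)]

    curved = np.pi * big_r / 2
    linear = big_r * np.sqrt(2.0)
    expected = {
        "origin_area": {"value": float(np.pi * r * r), "tol": 0.01, "cmp": "rel"},
        "linear_length": {"value": float(linear), "tol": 1e-6, "cmp": "rel"},
        "muscle_length": {"value": float(curved), "tol": 0.01, "cmp": "rel"},
        "volume": {"value": float(np.pi * r * r * curved), "tol": 0.03, "cmp": "rel"},
        "pct_diff_length": {"value": float(100.0 * (1 - linear / curved)),
                            "tol": 0.5, "cmp": "abs"},
    }
    selections = [
        {"mesh": "plate_origin", "muscle": "muscle", "role": "origin",
         "faces": patch_o.tolist()},
        {"mesh": "plate_insertion", "muscle": "muscle", "role": "insertion",
         "faces": patch_i.tolist()},
    ]
    return FixtureScene(bones=[plate_o, plate_i], selections=selections,
                        offsets=[{"muscle": "muscle", "offsets": offsets}],
                        sweep={"ring_vertex_count": k, "blend": "linear_blend",
                               "n_control": n_control, "n_samples": 33},
                        priority=["muscle"], expected=expected, seed=seed)


def make_overlap_pair(offset: float, seed: int = 0, radius: float = 3.0,
                      length: float = 20.0, resolution: int = 32) -> FixtureScene:
    """Two congruent parallel cylindrical muscles with lateral centre offset.

    Their intersection volume has the closed form lens_area x length, so the
    Boolean overlap-resolution stage can be checked against an oracle.
    """
    k = resolution
    outer = 1.5 * max(radius, 1.0)
    bones, selections = [], []
    for mname, cx in (("A", 0.0), ("B", float(offset))):
        po, fo = _puck((cx, 0, 0), _frame((0, 0, 1), (1, 0, 0)), radius, outer,
                       1.0, k, f"plate_{mname}_origin")
        pi, fi = _puck((cx, 0, length), _frame((0, 0, -1), (1, 0, 0)), radius,
                       outer, 1.0, k, f"plate_{mname}_insertion")
        bones += [po, pi]
        selections += [
            {"mesh": po.name, "muscle": mname, "role": "origin", "faces": fo.tolist()},
            {"mesh": pi.name, "muscle": mname, "role": "insertion", "faces": fi.tolist()},
        ]
    cyl = polygon_disc_area(radius, k) * length
    lens = lens_area(radius, float(offset)) * length
    expected = {
        "cylinder_volume": {"value": float(cyl), "tol": 0.01, "cmp": "rel"},
        "intersection_volume": {"value": float(lens), "tol": 0.02, "cmp": "rel"},
        "loser": {"value": "B", "tol": 0.0, "cmp": "exact"},
    }
    return FixtureScene(bones=bones, selections=selections,
                        sweep={"ring_vertex_count": k, "blend": "linear_blend",
                               "n_control": 2, "n_samples": 8},
                        priority=["A", "B"], expected=expected, seed=seed)
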
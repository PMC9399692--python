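"""Muscle volume generation.

The origin attachment boundary is projected to its best-fit plane, resampled
to a fixed vertex count and extruded along the centerline in
rotation-minimizing frames.  Under ``linear_blend`` the cross-section morphs
vertex-wise from the origin shape to the insertion shape; the swept tube is
capped at both ends, yielding a watertight mesh.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import LinearRing

from .centerline import CenterlineCurve
from .mesh_core import (
    MeshError,
    PlanarPolygon,
    SurfacePatch,
    TriangleMesh,
    align_boundary_to_plane,
    area_weighted_centroid,
    extract_boundary_loops,
    is_watertight,
    signed_polygon_area,
    signed_volume,
    surface_area,
)

__all__ = ["SweepParams", "MuscleModel", "resample_loop", "build_frames",
           "sweep_muscle", "scale_ring"]


@dataclass
class SweepParams:
    """Knobs of the sweep: ring resolution, blending mode, per-ring scaling."""

    ring_vertex_count: int = 64
    blend: str = "linear_blend"  # or "origin_only"
    scale_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ring_vertex_count < 3:
            raise MeshError("ring_vertex_count must be >= 3")
        if self.blend not in ("origin_only", "linear_blend"):
            raise MeshError(f"unknown blend mode {self.blend!r}")
        if self.scale_profile is not None:
            self.scale_profile = np.asarray(self.scale_profile, dtype=float).ravel()


@dataclass
class MuscleModel:
    """A generated muscle: watertight mesh tied to its patches and curve."""

    name: str
    mesh: TriangleMesh
    origin: SurfacePatch
    insertion: SurfacePatch
    curve: CenterlineCurve
    loops: list = field(default_factory=list)  # (k, 3) vertex rings, in order
    frames: tuple | None = None               # (r, s, t) unit-vector arrays

    @property
    def ring_count(self) -> int:
        return len(self.loops)

    def ring_vertex_indices(self, ring_index: int) -> np.ndarray:
        k = len(self.loops[0])
        return np.arange(ring_index * k, (ring_index + 1) * k)


def resample_loop(polygon: PlanarPolygon | np.ndarray, n: int) -> np.ndarray:
    """``n`` points equally spaced by arc length along a closed 2D polygon.

    The result is counter-clockwise with its seam at the polygon's first
    point.  Perimeter never increases (chord shortening); area error is
    O(1/n^2) for smooth shapes.
    """
    if n < 3:
        raise MeshError("need at least 3 ring vertices")
    pts = polygon.points2d if isinstance(polygon, PlanarPolygon) else np.asarray(polygon, float)
    if signed_polygon_area(pts) < 0:
        pts = np.vstack([pts[:1], pts[:0:-1]])  # reverse, keep seam vertex first
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise MeshError("degenerate boundary")
    targets = np.arange(n) * total / n
    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.maximum(seg[idx], 1e-300)
    return closed[idx] * (1 - frac)[:, None] + closed[idx + 1] * frac[:, None]


def build_frames(curve: CenterlineCurve, initial_normal=None):
    """Rotation-minimizing frames along the curve samples.

    Returns ``(r, s, t)`` arrays where ``t`` is the unit tangent and
    ``(r, s)`` span the normal plane; successive frames are related by the
    minimal rotation (double-reflection transport), so a straight curve gets
    identical frames everywhere.
    """
    x = curve.samples
    m = len(x)
    t = np.empty((m, 3))
    t[0] = x[1] - x[0]
    t[-1] = x[-1] - x[-2]
    if m > 2:
        t[1:-1] = x[2:] - x[:-2]
    t /= np.linalg.norm(t, axis=1)[:, None]

    if initial_normal is not None:
        r0 = np.asarray(initial_normal, dtype=float)
        r0 = r0 - (r0 @ t[0]) * t[0]
    else:
        r0 = np.zeros(3)
    if np.linalg.norm(r0) < 1e-9:
        pick = np.eye(3)[np.argmin(np.abs(t[0]))]
        r0 = pick - (pick @ t[0]) * t[0]
    r = np.empty((m, 3))
    r[0] = r0 / np.linalg.norm(r0)

    for i in range(m - 1):  # double reflection (Wang et al.)
        v1 = x[i + 1] - x[i]
        c1 = v1 @ v1
        rl = r[i] - (2.0 / c1) * (v1 @ r[i]) * v1
        tl = t[i] - (2.0 / c1) * (v1 @ t[i]) * v1
        v2 = t[i + 1] - tl
        c2 = v2 @ v2
        if c2 < 1e-30:
            r[i + 1] = rl
        else:
            r[i + 1] = rl - (2.0 / c2) * (v2 @ rl) * v2
        r[i + 1] -= (r[i + 1] @ t[i + 1]) * t[i + 1]
        r[i + 1] /= np.linalg.norm(r[i + 1])
    s = np.cross(t, r)
    return r, s, t


def _aligned_ring(patch: SurfacePatch, k: int) -> tuple[np.ndarray, PlanarPolygon]:
    """Project the patch boundary and resample it to a centred 2D ring."""
    comp = patch.largest_component()
    loops = extract_boundary_loops(comp)
    if len(loops) > 1:
        warnings.warn(f"{patch.role} patch has {len(loops)} boundary loops; "
                      "using the longest", stacklevel=2)
    poly = align_boundary_to_plane(loops[0])
    if not LinearRing(poly.points2d).is_simple:
        raise MeshError("self-intersecting attachment boundary")
    ring = resample_loop(poly, k)
    centroid = _polygon_centroid(ring)
    return ring - centroid, poly


def _polygon_centroid(pts: np.ndarray) -> np.ndarray:
    """Area centroid of a simple closed 2D polygon."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-300:
        return pts.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def _frame_projected_ring(patch: SurfacePatch, center: np.ndarray,
                          r: np.ndarray, s: np.ndarray, k: int):
    """Patch boundary projected into the sweep's end frame.

    Returns ``(ring2d, plane_normal)``; the ring is None if the projection
    self-intersects (caller falls back to PCA alignment).
    """
    comp = patch.largest_component()
    loops = extract_boundary_loops(comp)
    if len(loops) > 1:
        warnings.warn(f"{patch.role} patch has {len(loops)} boundary loops; "
                      "using the longest", stacklevel=3)
    poly = align_boundary_to_plane(loops[0])
    rel = loops[0].points - center
    pts2d = np.column_stack([rel @ r, rel @ s])
    if abs(signed_polygon_area(pts2d)) < 1e-12 or not LinearRing(pts2d).is_simple:
        return None, poly.transform[:3, 2]
    ring = resample_loop(pts2d, k)
    return ring - _polygon_centroid(ring), poly.transform[:3, 2]


def _patch_plane_axes(normal: np.ndarray, r: np.ndarray, s: np.ndarray,
                      t: np.ndarray):
    """In-plane axes for a terminal ring lying flush in the patch plane.

    The transported frame (r, s) is rotated onto the plane with the given
    normal (sign-aligned to the tangent) so winding and seam continuity are
    preserved.  Returns None when the plane is too oblique to the tangent.
    """
    align = float(normal @ t)
    if abs(align) < 0.5:
        return None
    n = normal if align > 0 else -normal
    e1 = r - (r @ n) * n
    norm = np.linalg.norm(e1)
    if norm < 1e-9:
        return None
    e1 /= norm
    return e1, np.cross(n, e1)


def _best_cyclic_shift(a: np.ndarray, b: np.ndarray) -> int:
    """Cyclic offset of ``b`` minimizing summed squared distance to ``a``."""
    best, best_cost = 0, np.inf
    for shift in range(len(b)):
        cost = float(((a - np.roll(b, -shift, axis=0)) ** 2).sum())
        if cost < best_cost:
            best, best_cost = shift, cost
    return best


def sweep_muscle(origin: SurfacePatch, insertion: SurfacePatch,
                 curve: CenterlineCurve, params: SweepParams | None = None,
                 name: str = "muscle") -> MuscleModel:
    """Extrude the origin cross-section along the centerline into a muscle.

    The projected origin boundary is placed at every curve sample in its
    rotation-minimizing frame (plane normal along the local tangent) and the
    rings are stitched into a closed tube, fan-capped at both ends.  Under
    ``linear_blend`` the ring shape interpolates vertex-wise (after seam
    alignment) to the insertion boundary by normalized arc length.
    """
    params = params or SweepParams()
    k = params.ring_vertex_count
    if surface_area(origin) <= 0 or surface_area(insertion) <= 0:
        raise MeshError("attachment patch has zero area")

    oc = area_weighted_centroid(origin)
    ic = area_weighted_centroid(insertion)
    samples = curve.samples
    tol = 1e-6 * max(1.0, float(np.linalg.norm(ic - oc)))
    if np.linalg.norm(samples[0] - oc) > tol or np.linalg.norm(samples[-1] - ic) > tol:
        raise MeshError("curve endpoints do not coincide with patch centroids")

    ring_o, poly_o = _aligned_ring(origin, k)
    r, s, t = build_frames(curve, initial_normal=poly_o.transform[:3, 0])

    if params.blend == "linear_blend":
        # Project the insertion boundary into the transported end frame so
        # the vertex correspondence is independent of scene orientation.
        ring_i, normal_i = _frame_projected_ring(insertion, ic, r[-1], s[-1], k)
        if ring_i is None:
            ring_i, poly_i = _aligned_ring(insertion, k)
            normal_i = poly_i.transform[:3, 2]
        ring_i = np.roll(ring_i, -_best_cyclic_shift(ring_o, ring_i), axis=0)
    else:
        ring_i = ring_o
        _, normal_i = _frame_projected_ring(insertion, ic, r[-1], s[-1], k)

    m = len(samples)
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    tpar = np.concatenate([[0.0], np.cumsum(seg)])
    tpar /= tpar[-1]

    scale = params.scale_profile
    if scale is not None and len(scale) != m:
        raise MeshError(f"scale_profile length {len(scale)} != ring count {m}")

    # terminal rings lie flush in their patch planes (the muscle is joined to
    # the attachment areas); interior rings follow the transported frames
    axes = [(r[j], s[j]) for j in range(m)]
    origin_axes = _patch_plane_axes(poly_o.transform[:3, 2], r[0], s[0], t[0])
    if origin_axes is not None:
        axes[0] = origin_axes
    insertion_axes = _patch_plane_axes(normal_i, r[-1], s[-1], t[-1])
    if insertion_axes is not None:
        axes[-1] = insertion_axes

    rings = np.empty((m, k, 3))
    loops: list[np.ndarray] = []
    for j in range(m):
        shape = ring_o * (1 - tpar[j]) + ring_i * tpar[j]
        if scale is not None:
            shape = shape * scale[j]
        e1, e2 = axes[j]
        world = samples[j] + shape[:, 0:1] * e1 + shape[:, 1:2] * e2
        rings[j] = world
        loops.append(world)

    mesh = _stitch_tube(rings, samples[0], samples[-1], name)
    if not is_watertight(mesh):
        raise MeshError("sweep not watertight")
    if abs(signed_volume(mesh)) <= 0:
        raise MeshError("sweep produced zero volume")
    return MuscleModel(name, mesh, origin, insertion, curve, loops, (r, s, t))


def _stitch_tube(rings: np.ndarray, apex_lo: np.ndarray, apex_hi: np.ndarray,
                 name: str) -> TriangleMesh:
    m, k, _ = rings.shape
    verts = np.vstack([rings.reshape(-1, 3), apex_lo[None], apex_hi[None]])
    ao, ai = m * k, m * k + 1
    faces = []
    for j in range(m - 1):
        base, nxt = j * k, (j + 1) * k
        for a in range(k):
            b = (a + 1) % k
            faces.append((base + a, base + b, nxt + b))
            faces.append((base + a, nxt + b, nxt + a))
    last = (m - 1) * k
    for a in range(k):
        b = (a + 1) % k
        faces.append((ao, b, a))               # origin cap
        faces.append((ai, last + a, last + b))  # insertion cap
    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64), name)
    if signed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
    return mesh


def scale_ring(muscle: MuscleModel, ring_index: int, factor: float) -> MuscleModel:
    """Scale one interior cross-section ring about its curve sample point.

    The ring is scaled within its frame plane; curve, attachments and the
    terminal rings are unchanged.
    """
    m = muscle.ring_count
    if ring_index <= 0 or ring_index >= m - 1:
        raise MeshError("attachment rings are fixed")
    if factor <= 0:
        raise MeshError("scale factor must be positive")
    center = muscle.curve.samples[ring_index]
    verts = muscle.mesh.vertices.copy()
    ids = muscle.ring_vertex_indices(ring_index)
    verts[ids] = center + factor * (verts[ids] - center)
    mesh = TriangleMesh(verts, muscle.mesh.faces.copy(), muscle.mesh.name)
    loops = [lp.copy() for lp in muscle.loops]
    loops[ring_index] = verts[ids]
    return replace(muscle, mesh=mesh, loops=loops)
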
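import numpy as np
import pytest

from myovol.centerline import CenterlineCurve, curve_length, default_centerline
from myovol.fixtures import make_curved_channel, make_parallel_plates
from myovol.mesh_core import MeshError, enclosed_volume, is_watertight, signed_polygon_area
from myovol.sweep import (
    SweepParams,
    build_frames,
    resample_loop,
    scale_ring,
    sweep_muscle,
)

from conftest import build_scene_muscles, random_rotation


def shoelace(pts):
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def perimeter(pts):
    closed = np.vstack([pts, pts[:1]])
    return np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()


class TestResampleLoop:
    def test_circle_area_preserved(self):
        theta = 2 * np.pi * np.arange(64) / 64
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        ring = resample_loop(circle, 64)
        assert shoelace(ring) == pytest.approx(np.pi, rel=5e-3)

    def test_square_hits_corners_and_midpoints(self):
        square = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        ring = resample_loop(square, 8)
        assert perimeter(ring) == pytest.approx(8.0)
        for corner in square:
            assert np.min(np.linalg.norm(ring - corner, axis=1)) < 1e-12

    def test_seam_at_first_point(self):
        square = np.array([[1, 1], [3, 1], [3, 3], [1, 3]], float)
        ring = resample_loop(square, 16)
        assert ring[0] == pytest.approx([1, 1])

    @pytest.mark.parametrize("seed", range(4))
    def test_perimeter_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        rad = rng.uniform(1, 3, 12)
        poly = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        for n in (3, 7, 16, 100):
            assert perimeter(resample_loop(poly, n)) <= perimeter(poly) + 1e-9

    def test_n_below_3_rejected(self):
        with pytest.raises(MeshError):
            resample_loop(np.array([[0, 0], [1, 0], [0, 1]], float), 2)

    def test_output_counter_clockwise(self):
        cw = np.array([[0, 0], [0, 2], [2, 2], [2, 0]], float)  # clockwise input
        ring = resample_loop(cw, 8)
        assert signed_polygon_area(ring) > 0


class TestBuildFrames:
    def test_straight_curve_constant_frames(self):
        curve = default_centerline((0, 0, 0), (0, 0, 10), 8)
        r, s, t = build_frames(curve)
        assert np.ptp(r, axis=0) == pytest.approx(0.0, abs=1e-12)
        assert t == pytest.approx(np.tile([0, 0, 1.0], (8, 1)))
        # orthonormality
        assert np.einsum("ij,ij->i", r, t) == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(s, axis=1) == pytest.approx(1.0)

    def test_planar_arc_zero_twist(self):
        theta = np.linspace(0, np.pi / 2, 33)
        arc = np.column_stack([20 * np.cos(theta), 20 * np.sin(theta), np.zeros_like(theta)])
        curve = CenterlineCurve(arc, n_samples=33)
        r, s, t = build_frames(curve, initial_normal=[0, 0, 1.0])
        # the out-of-plane direction is transported without any twist
        assert r == pytest.approx(np.tile([0, 0, 1.0], (len(r), 1)), abs=1e-9)

    def test_coarse_matches_dense_transport(self):
        # oracle: double-reflection on a 16x denser sampling of the same helix
        def helix(n):
            u = np.linspace(0, 4 * np.pi, n)
            return np.column_stack([5 * np.cos(u), 5 * np.sin(u), u])

        rd, *_ = build_frames(CenterlineCurve(helix(1025), n_samples=1025),
                              initial_normal=[1.0, 0, 0])
        dots = []
        for n in (65, 257):
            rc, *_ = build_frames(CenterlineCurve(helix(n), n_samples=n),
                                  initial_normal=[1.0, 0, 0])
            dots.append(rc[-1] @ rd[-1])
        assert dots[0] > 0.995
        assert dots[1] > dots[0]  # converges with refinement

    def test_rmf_stable_where_frenet_flips(self):
        # planar S-curve: two tangent half-circle arcs; curvature changes sign
        t1 = np.linspace(-np.pi / 2, np.pi / 2, 33)
        arc1 = np.column_stack([np.cos(t1), np.sin(t1) + 1, np.zeros_like(t1)])
        t2 = np.linspace(np.pi / 2, 3 * np.pi / 2, 33)
        arc2 = np.column_stack([-np.cos(t2 + np.pi), np.sin(t2 + np.pi) - 1,
                                np.zeros_like(t2)])[1:]
        pts = np.vstack([arc1[::-1], arc2])
        curve = CenterlineCurve(pts, n_samples=len(pts))
        r, s, t = build_frames(curve, initial_normal=[0, 0, 1.0])
        assert np.min(np.einsum("ij,ij->i", r[:-1], r[1:])) > 0.99
        # Frenet-style principal normals flip across the inflection
        tn = np.diff(curve.samples, axis=0)
        tn /= np.linalg.norm(tn, axis=1)[:, None]
        frenet = np.diff(tn, axis=0)
        norms = np.linalg.norm(frenet, axis=1)
        keep = norms > 1e-9
        frenet = frenet[keep] / norms[keep][:, None]
        assert np.min(np.einsum("ij,ij->i", frenet[:-1], frenet[1:])) < -0.5


class TestSweepMuscle:
    def test_cylinder_volume(self):
        scene = make_parallel_plates(3.0, 20.0, resolution=64)
        (muscle,), _ = build_scene_muscles(scene)
        assert is_watertight(muscle.mesh)
        assert enclosed_volume(muscle.mesh) == pytest.approx(np.pi * 9 * 20, rel=0.02)

    def test_cone_limit(self):
        scene = make_parallel_plates(3.0, 20.0, resolution=64,
                                     insertion_radius=3e-4)
        (muscle,), _ = build_scene_muscles(scene)
        assert enclosed_volume(muscle.mesh) == pytest.approx(np.pi * 9 * 20 / 3, rel=0.03)

    def test_origin_only_blend_ignores_insertion_shape(self):
        scene = make_parallel_plates(3.0, 20.0, resolution=32, insertion_radius=1.0)
        meshes = {b.name: b for b in scene.bones}
        from myovol.io import patch_from_selection
        from myovol.mesh_core import area_weighted_centroid
        o = patch_from_selection(scene.selections[0], meshes)
        i = patch_from_selection(scene.selections[1], meshes)
        curve = default_centerline(area_weighted_centroid(o), area_weighted_centroid(i), 8)
        muscle = sweep_muscle(o, i, curve, SweepParams(ring_vertex_count=32,
                                                       blend="origin_only"))
        assert enclosed_volume(muscle.mesh) == pytest.approx(np.pi * 9 * 20, rel=0.02)

    def test_quarter_torus_pappus(self):
        scene = make_curved_channel(20.0, 2.0, resolution=64)
        (muscle,), _ = build_scene_muscles(scene)
        assert curve_length(muscle.curve) == pytest.approx(np.pi * 10, rel=0.01)
        assert enclosed_volume(muscle.mesh) == pytest.approx(
            np.pi * 4 * np.pi * 10, rel=0.03)

    def test_ring_structure(self, cylinder_muscle):
        m = cylinder_muscle
        assert m.ring_count == len(m.curve.samples)
        # rings ordered monotonically along the straight curve
        z = [lp[:, 2].mean() for lp in m.loops]
        assert np.all(np.diff(z) > 0)

    def test_rigid_motion_invariance(self):
        scene = make_parallel_plates(3.0, 20.0, resolution=32)
        (muscle,), _ = build_scene_muscles(scene)
        v0 = enclosed_volume(muscle.mesh)
        rot, trans = random_rotation(11), np.array([4.0, -9.0, 2.5])
        moved = make_parallel_plates(3.0, 20.0, resolution=32)
        moved.bones = [b.transformed(rot, trans) for b in moved.bones]
        (muscle2,), _ = build_scene_muscles(moved)
        assert enclosed_volume(muscle2.mesh) == pytest.approx(v0, rel=1e-6)

    def test_endpoint_mismatch_rejected(self, plates_scene):
        from myovol.io import patch_from_selection
        meshes = {b.name: b for b in plates_scene.bones}
        o = patch_from_selection(plates_scene.selections[0], meshes)
        i = patch_from_selection(plates_scene.selections[1], meshes)
        bad = default_centerline((1, 0, 0), (0, 0, 20), 8)
        with pytest.raises(MeshError, match="centroid"):
            sweep_muscle(o, i, bad, SweepParams(ring_vertex_count=16))


class TestScaleRing:
    def test_identity(self, cylinder_muscle):
        out = scale_ring(cylinder_muscle, 3, 1.0)
        assert enclosed_volume(out.mesh) == pytest.approx(
            enclosed_volume(cylinder_muscle.mesh), rel=1e-12)

    def test_monotone_increase(self, cylinder_muscle):
        v0 = enclosed_volume(cylinder_muscle.mesh)
        out = scale_ring(cylinder_muscle, 3, 2.0)
        assert enclosed_volume(out.mesh) > v0
        assert is_watertight(out.mesh)

    @pytest.mark.parametrize("idx", [0, 7])
    def test_terminal_ring_fixed(self, cylinder_muscle, idx):
        with pytest.raises(MeshError, match="fixed"):
            scale_ring(cylinder_muscle, idx, 1.5)

    def test_scaled_cylinder_limit(self):
        # all interior rings scaled by s -> volume ratio -> s^2 as rings densify
        s = 1.5
        ratios = []
        for n in (17, 65):
            scene = make_parallel_plates(3.0, 20.0, resolution=32)
            (m,), _ = build_scene_muscles(scene, n_control=n, n_samples=n)
            v0 = enclosed_volume(m.mesh)
            for j in range(1, m.ring_count - 1):
                m = scale_ring(m, j, s)
            ratios.append(enclosed_volume(m.mesh) / v0)
        assert abs(ratios[1] - s * s) < abs(ratios[0] - s * s)
        assert ratios[1] == pytest.approx(s * s, rel=0.02)
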
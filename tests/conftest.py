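import numpy as np
import pytest

from myovol.centerline import apply_control_offsets, default_centerline
from myovol.io import patch_from_selection
from myovol.mesh_core import area_weighted_centroid
from myovol.sweep import SweepParams, sweep_muscle


def random_rotation(seed: int) -> np.ndarray:
    """Uniform-ish random rotation matrix (QR of a Gaussian matrix)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def build_scene_muscles(scene, n_control=8, n_samples=None):
    """Run attachment -> curve -> sweep for every muscle of a FixtureScene."""
    meshes = {b.name: b for b in scene.bones}
    offsets = {o["muscle"]: o["offsets"] for o in scene.offsets}
    params = SweepParams(ring_vertex_count=scene.sweep["ring_vertex_count"])
    names = sorted({s["muscle"] for s in scene.selections})
    muscles = []
    for name in names:
        sels = {s["role"]: s for s in scene.selections if s["muscle"] == name}
        origin = patch_from_selection(sels["origin"], meshes)
        insertion = patch_from_selection(sels["insertion"], meshes)
        nc = scene.sweep.get("n_control", n_control) if name in offsets else n_control
        curve = default_centerline(area_weighted_centroid(origin),
                                   area_weighted_centroid(insertion), nc)
        if name in offsets:
            curve = apply_control_offsets(curve, offsets[name])
        ns = n_samples or scene.sweep.get("n_samples", 8)
        curve = curve.resampled(ns)
        muscles.append(sweep_muscle(origin, insertion, curve, params, name=name))
    return muscles, meshes


@pytest.fixture
def plates_scene():
    from myovol.fixtures import make_parallel_plates
    return make_parallel_plates(3.0, 20.0, resolution=32)


@pytest.fixture
def cylinder_muscle(plates_scene):
    (muscle,), _ = build_scene_muscles(plates_scene)
    return muscle
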
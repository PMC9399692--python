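"""Muscle centerline curves.

The curve starts at the origin-attachment centroid and ends at the
insertion-attachment centroid.  Interior control points may be displaced to
model muscle curvature (the headless surrogate for interactive adjustment);
samples are recomputed with a clamped interpolating Catmull-Rom spline that
passes through every control point.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import MeshError

__all__ = ["CenterlineCurve", "default_centerline", "apply_control_offsets",
           "curve_length", "linear_length"]

DEFAULT_N_SAMPLES = 32


def _catmull_rom(control: np.ndarray, n_samples: int) -> np.ndarray:
    """Sample a clamped interpolating Catmull-Rom spline.

    Parameters run uniformly over the control polygon; knot parameters are
    always included so every control point appears among the samples.
    """
    control = np.asarray(control, dtype=float)
    m = len(control)
    if m == 2:
        t = np.linspace(0.0, 1.0, max(n_samples, 2))[:, None]
        return control[0] * (1 - t) + control[1] * t
    padded = np.vstack([control[0], control, control[-1]])
    tangents = 0.5 * (padded[2:] - padded[:-2])  # one per control point

    u = np.union1d(np.linspace(0.0, m - 1.0, max(n_samples, 2)), np.arange(m))
    # drop params that collide with a knot to within float noise
    keep = np.ones(len(u), dtype=bool)
    keep[1:] = np.diff(u) > 1e-9
    u = u[keep]

    seg = np.clip(np.floor(u).astype(int), 0, m - 2)
    s = (u - seg)[:, None]
    p0, p1 = control[seg], control[seg + 1]
    t0, t1 = tangents[seg], tangents[seg + 1]
    h00 = 2 * s**3 - 3 * s**2 + 1
    h10 = s**3 - 2 * s**2 + s
    h01 = -2 * s**3 + 3 * s**2
    h11 = s**3 - s**2
    return h00 * p0 + h10 * t0 + h01 * p1 + h11 * t1


@dataclass
class CenterlineCurve:
    """Ordered centerline from origin centroid to insertion centroid.

    ``samples`` is the densified polyline actually used for sweeping and
    length measurement; it interpolates every control point in order.
    """

    control_points: np.ndarray
    n_samples: int = DEFAULT_N_SAMPLES
    samples: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=np.float64).reshape(-1, 3)
        if len(self.control_points) < 2:
            raise MeshError("centerline needs at least 2 control points")
        if self.n_samples < 2:
            raise MeshError("n_samples must be >= 2")
        samples = _catmull_rom(self.control_points, self.n_samples)
        # enforce distinct consecutive samples
        keep = np.ones(len(samples), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(samples, axis=0), axis=1) > 1e-12
        self.samples = samples[keep]

    def resampled(self, n_samples: int) -> "CenterlineCurve":
        """Same control polygon, different sampling density."""
        return CenterlineCurve(self.control_points.copy(), n_samples)


def default_centerline(origin_centroid, insertion_centroid,
                       n_samples: int = DEFAULT_N_SAMPLES) -> CenterlineCurve:
    """Straight centerline with ``n_samples`` equally spaced control points."""
    a = np.asarray(origin_centroid, dtype=float)
    b = np.asarray(insertion_centroid, dtype=float)
    if np.linalg.norm(b - a) <= 1e-12:
        raise MeshError("zero-length muscle")
    if n_samples < 2:
        raise MeshError("n_samples must be >= 2")
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    return CenterlineCurve(a * (1 - t) + b * t, n_samples)


def apply_control_offsets(curve: CenterlineCurve, offsets) -> CenterlineCurve:
    """Displace interior control points; endpoints stay pinned to centroids.

    ``offsets`` is an iterable of ``(index, displacement)`` pairs (or flat
    ``[index, dx, dy, dz]`` records as read from a run config).
    """
    control = curve.control_points.copy()
    last = len(control) - 1
    for entry in offsets:
        if len(entry) == 2:
            idx, disp = entry
        else:
            idx, disp = entry[0], entry[1:4]
        idx = int(idx)
        if idx <= 0 or idx >= last:
            raise MeshError("endpoints are pinned to centroids")
        control[idx] += np.asarray(disp, dtype=float)
    return CenterlineCurve(control, curve.n_samples)


def curve_length(curve: CenterlineCurve) -> float:
    """Sum of Euclidean lengths of consecutive sample segments (mm)."""
    return float(np.linalg.norm(np.diff(curve.samples, axis=0), axis=1).sum())


def linear_length(origin_centroid, insertion_centroid) -> float:
    """Euclidean centroid-to-centroid distance (mm)."""
    a = np.asarray(origin_centroid, dtype=float)
    b = np.asarray(insertion_centroid, dtype=float)
    return float(np.linalg.norm(b - a))
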
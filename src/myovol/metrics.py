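"""Muscle metrics and frustum/PCSA/force comparison statistics.

Frustum volumes use the truncated-cone formula
``V = (l/3) * (A_or + A_ins + sqrt(A_or * A_ins))`` with the *linear*
(centroid-to-centroid) length; three-dimensional quantities use the mesh
volume and the *curved* centerline length.  PCSA assumes a parallel-fibred
muscle with fibre length equal to muscle length; muscle force is PCSA times
an isometric muscle stress (default 0.3 N/mm^2).
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .centerline import curve_length, linear_length as _linear_length
from .mesh_core import MeshError, area_weighted_centroid, enclosed_volume, surface_area

__all__ = ["MuscleMetrics", "DEFAULT_STRESS", "frustum_volume", "pcsa",
           "muscle_force", "percent_difference", "compute_metrics",
           "write_metrics_csv", "read_metrics_csv", "comparison_row",
           "CSV_COLUMNS"]

DEFAULT_STRESS = 0.3  # N / mm^2


def frustum_volume(a_or: float, a_ins: float, l: float) -> float:
    """Truncated-cone volume (mm^3) from the two attachment areas (mm^2)
    and the linear centroid-to-centroid length (mm).

    Symmetric in the two areas; equals ``A * l`` when the areas are equal and
    ``A_or * l / 3`` when the insertion area vanishes.
    """
    if a_or < 0 or a_ins < 0 or l < 0:
        raise MeshError("frustum inputs must be non-negative")
    if a_or == a_ins:
        return a_or * l  # cylinder limit, kept exact in floating point
    return (l / 3.0) * (a_or + a_ins + math.sqrt(a_or * a_ins))


def pcsa(volume: float, length: float) -> float:
    """Physiological cross-sectional area (mm^2): volume / length.

    Use the linear length for frustum volumes and the curved muscle length
    for three-dimensional volumes.
    """
    if length <= 0:
        raise MeshError("zero length")
    return volume / length


def muscle_force(pcsa_value: float, stress: float = DEFAULT_STRESS) -> float:
    """Isometric force (N): PCSA (mm^2) times muscle stress (N/mm^2)."""
    if pcsa_value < 0:
        raise MeshError("PCSA must be non-negative")
    if stress <= 0:
        raise MeshError("stress must be positive")
    return pcsa_value * stress


def percent_difference(value_3d: float, value_frustum: float) -> float:
    """``100 * (value_3d - value_frustum) / value_3d`` (sign preserved)."""
    if value_3d == 0:
        raise MeshError("zero three-dimensional value")
    return 100.0 * (value_3d - value_frustum) / value_3d


@dataclass
class MuscleMetrics:
    """One exported CSV row: measured metrics plus derived comparisons."""

    name: str
    origin_area: float
    insertion_area: float
    origin_centroid: np.ndarray
    insertion_centroid: np.ndarray
    linear_length: float
    muscle_length: float
    volume: float
    frustum_volume: float
    pcsa_frustum: float
    pcsa_3d: float
    force_frustum: float
    force_3d: float
    pct_diff_length: float
    pct_diff_volume: float
    pct_diff_force: float
    stress: float = DEFAULT_STRESS

    def __post_init__(self) -> None:
        self.origin_centroid = np.asarray(self.origin_centroid, dtype=float).reshape(3)
        self.insertion_centroid = np.asarray(self.insertion_centroid, dtype=float).reshape(3)
        if min(self.origin_area, self.insertion_area, self.linear_length,
               self.muscle_length, self.volume) < 0:
            raise MeshError("negative metric")
        if self.stress <= 0:
            raise MeshError("stress must be positive")


def derive_metrics(name: str, origin_area: float, insertion_area: float,
                   origin_centroid, insertion_centroid,
                   linear_len: float, muscle_len: float, volume: float,
                   stress: float = DEFAULT_STRESS) -> MuscleMetrics:
    """Fill every derived field from the measured quantities."""
    v_frustum = frustum_volume(origin_area, insertion_area, linear_len)
    p_fr = pcsa(v_frustum, linear_len)
    p_3d = pcsa(volume, muscle_len)
    f_fr = muscle_force(p_fr, stress)
    f_3d = muscle_force(p_3d, stress)
    return MuscleMetrics(
        name=name, origin_area=origin_area, insertion_area=insertion_area,
        origin_centroid=origin_centroid, insertion_centroid=insertion_centroid,
        linear_length=linear_len, muscle_length=muscle_len, volume=volume,
        frustum_volume=v_frustum, pcsa_frustum=p_fr, pcsa_3d=p_3d,
        force_frustum=f_fr, force_3d=f_3d,
        pct_diff_length=percent_difference(muscle_len, linear_len),
        pct_diff_volume=percent_difference(volume, v_frustum),
        pct_diff_force=percent_difference(f_3d, f_fr),
        stress=stress)


def compute_metrics(muscle, stress: float = DEFAULT_STRESS) -> MuscleMetrics:
    """Measure a (post-Boolean) MuscleModel and derive all comparison fields."""
    oc = area_weighted_centroid(muscle.origin)
    ic = area_weighted_centroid(muscle.insertion)
    return derive_metrics(
        muscle.name,
        surface_area(muscle.origin), surface_area(muscle.insertion),
        oc, ic,
        _linear_length(oc, ic), curve_length(muscle.curve),
        enclosed_volume(muscle.mesh), stress)


CSV_COLUMNS = [
    "name", "origin_area", "insertion_area",
    "origin_centroid_x", "origin_centroid_y", "origin_centroid_z",
    "insertion_centroid_x", "insertion_centroid_y", "insertion_centroid_z",
    "linear_length", "muscle_length", "muscle_volume",
    "frustum_volume", "pcsa_frustum", "pcsa_3d",
    "force_frustum", "force_3d",
    "pct_diff_length", "pct_diff_volume", "pct_diff_force", "stress",
]


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_metrics_csv(rows: list[MuscleMetrics], path: str) -> None:
    """Write one header line plus one row per muscle (6 significant digits)."""
    if not rows:
        raise MeshError("no metrics rows to write")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in rows:
            writer.writerow([r.name]
                            + [_fmt(v) for v in (r.origin_area, r.insertion_area,
                                                 *r.origin_centroid, *r.insertion_centroid,
                                                 r.linear_length, r.muscle_length, r.volume,
                                                 r.frustum_volume, r.pcsa_frustum, r.pcsa_3d,
                                                 r.force_frustum, r.force_3d,
                                                 r.pct_diff_length, r.pct_diff_volume,
                                                 r.pct_diff_force, r.stress)])


def read_metrics_csv(path: str) -> list[MuscleMetrics]:
    """Companion reader; round-trips :func:`write_metrics_csv` output."""
    out: list[MuscleMetrics] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in CSV_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise MeshError(f"metrics CSV missing columns: {missing}")
        for rec in reader:
            out.append(MuscleMetrics(
                name=rec["name"],
                origin_area=float(rec["origin_area"]),
                insertion_area=float(rec["insertion_area"]),
                origin_centroid=[float(rec[f"origin_centroid_{ax}"]) for ax in "xyz"],
                insertion_centroid=[float(rec[f"insertion_centroid_{ax}"]) for ax in "xyz"],
                linear_length=float(rec["linear_length"]),
                muscle_length=float(rec["muscle_length"]),
                volume=float(rec["muscle_volume"]),
                frustum_volume=float(rec["frustum_volume"]),
                pcsa_frustum=float(rec["pcsa_frustum"]),
                pcsa_3d=float(rec["pcsa_3d"]),
                force_frustum=float(rec["force_frustum"]),
                force_3d=float(rec["force_3d"]),
                pct_diff_length=float(rec["pct_diff_length"]),
                pct_diff_volume=float(rec["pct_diff_volume"]),
                pct_diff_force=float(rec["pct_diff_force"]),
                stress=float(rec["stress"])))
    return out


def comparison_row(name: str, a_or: float, a_ins: float, linear_len: float,
                   muscle_len: float, volume_3d: float,
                   stress: float = DEFAULT_STRESS) -> dict:
    """Frustum-vs-3D comparison cells from measured inputs (one table row)."""
    v_fr = frustum_volume(a_or, a_ins, linear_len)
    p_fr = pcsa(v_fr, linear_len)
    p_3d = pcsa(volume_3d, muscle_len)
    f_fr = muscle_force(p_fr, stress)
    f_3d = muscle_force(p_3d, stress)
    return {
        "name": name,
        "A_or": a_or, "A_ins": a_ins,
        "linear_length": linear_len, "muscle_length": muscle_len,
        "volume_3d": volume_3d,
        "frustum_volume": v_fr,
        "pcsa_frustum": p_fr, "pcsa_3d": p_3d,
        "force_frustum": f_fr, "force_3d": f_3d,
        "pct_diff_length": percent_difference(muscle_len, linear_len),
        "pct_diff_volume": percent_difference(volume_3d, v_fr),
        "pct_diff_force": percent_difference(f_3d, f_fr),
    }
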
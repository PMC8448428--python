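"""Discrete anatomical descriptors and the ischiofemoral distance.

All measures are computed from landmarks and labelled vertex regions, so
they are invariant under a common rigid transform of both bones and only
need the dense correspondence, not any particular pose.  Signed angles
(anteversion, lesser-trochanter retroversion) are referenced to the
posterior condylar line with the anterior direction derived from the
mesh's own chirality (distal shaft axis x lateral-to-medial condylar
direction), so mirroring a hip flips their sign while every unsigned
measure is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh import LandmarkMesh, DegenerateGeometryError, fit_sphere

__all__ = [
    "MorphometricRecord",
    "ClosestPair",
    "ischiofemoral_distance",
    "measure_femur",
    "measure_pelvis",
    "measure_hip",
    "measure_cohort",
    "FemurMeasures",
    "PelvisMeasures",
]


@dataclass(frozen=True)
class ClosestPair:
    """The minimizing vertex pair of a nearest-neighbor distance query."""

    point_on_femur: np.ndarray
    point_on_pelvis: np.ndarray
    distance: float


@dataclass(frozen=True)
class FemurMeasures:
    neck_shaft_angle: float
    femoral_anteversion: float
    femoral_offset: float
    head_radius: float
    lt_retroversion: float
    femoral_length: float
    head_center: np.ndarray


@dataclass(frozen=True)
class PelvisMeasures:
    pelvic_width: float
    interspinous_distance: float
    ischial_spine_ratio: float


@dataclass(frozen=True)
class MorphometricRecord:
    """The ten discrete measures plus the ischiofemoral distance."""

    neck_shaft_angle: float
    femoral_anteversion: float
    femoral_offset: float
    head_radius: float
    lt_retroversion: float
    femoral_length: float
    pelvic_width: float
    interspinous_distance: float
    ischial_spine_ratio: float
    ischiofemoral_distance: float
    sample_id: int = 0
    sex: str = "female"


def ischiofemoral_distance(femur: LandmarkMesh, pelvis: LandmarkMesh,
                           method: str = "vertex") -> ClosestPair:
    """Shortest distance between the lesser-trochanter area and the pelvis.

    ``method="vertex"`` (default) is a nearest-neighbor search between the
    lesser-trochanter vertex set and the full pelvic vertex set; the
    KD-tree is exact, equal to an exhaustive all-pairs scan.
    ``method="surface"`` measures vertex-to-triangle distance against the
    pelvic surface instead.
    """
    src = femur.region_points("lesser_trochanter_area")
    if pelvis.n_vertices == 0:
        raise DegenerateGeometryError("pelvis mesh has no vertices")
    if method == "vertex":
        dists, idx = cKDTree(pelvis.vertices).query(src)
        k = int(np.argmin(dists))
        return ClosestPair(src[k].copy(), pelvis.vertices[idx[k]].copy(), float(dists[k]))
    if method == "surface":
        from trimesh.triangles import closest_point as tri_closest

        if not pelvis.faces.size:
            raise DegenerateGeometryError("surface distance needs pelvis triangles")
        tris = pelvis.vertices[pelvis.faces]            # (m, 3, 3)
        best = ClosestPair(src[0], src[0], np.inf)
        for p in src:                                   # all-pairs point-triangle scan
            cand = tri_closest(tris, np.broadcast_to(p, (len(tris), 3)))
            d = np.linalg.norm(cand - p, axis=1)
            j = int(np.argmin(d))
            if d[j] < best.distance:
                best = ClosestPair(p.copy(), cand[j].copy(), float(d[j]))
        return best
    raise ValueError(f"unknown method {method!r}; use 'vertex' or 'surface'")


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise DegenerateGeometryError("degenerate region: zero-length principal axis")
    return vt[0]


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateGeometryError(f"degenerate axis: {what}")
    return v / n


def measure_femur(femur: LandmarkMesh) -> FemurMeasures:
    """Femoral descriptors from regions and landmarks.

    head: least-squares sphere on the ``femoral_head`` region;
    shaft axis: principal axis of the ``shaft`` region, oriented distally;
    neck axis: neck-base landmark -> head center;
    neck-shaft angle: 3D angle between neck axis and distal shaft axis;
    offset: perpendicular head-center-to-shaft-axis distance;
    anteversion / LT retroversion: signed angles against the posterior
    condylar line in the plane normal to the shaft axis;
    length: head center to mid-condylar landmark.
    """
    for lm in ("neck_base", "lt_apex", "condyle_post_medial", "condyle_post_lateral", "condyle_mid"):
        if lm not in femur.landmarks:
            raise KeyError(f"femur is missing landmark {lm!r}")
    sphere = fit_sphere(femur.region_points("femoral_head"))
    C = sphere.center

    shaft_pts = femur.region_points("shaft")
    centroid = shaft_pts.mean(axis=0)
    axis = _principal_axis(shaft_pts)
    mid_condyle = femur.landmark_point("condyle_mid")
    if axis @ (mid_condyle - C) < 0:
        axis = -axis                                  # orient distally
    neck = _unit(C - femur.landmark_point("neck_base"), "neck axis")

    nsa = float(np.degrees(np.arccos(np.clip(neck @ axis, -1.0, 1.0))))
    w = C - centroid
    offset = float(np.linalg.norm(w - (w @ axis) * axis))

    cm = femur.landmark_point("condyle_post_medial")
    cl = femur.landmark_point("condyle_post_lateral")
    condylar = _unit(cm - cl, "posterior condylar line")          # lateral -> medial
    anterior = _unit(np.cross(axis, condylar), "anterior reference")

    def project(v):
        return v - (v @ axis) * axis

    nproj = _unit(project(neck), "projected neck axis")
    anteversion = float(np.degrees(np.arctan2(nproj @ anterior, nproj @ condylar)))

    apex = femur.landmark_point("lt_apex")
    wa = apex - centroid
    lt_vec = _unit(project(wa - (wa @ axis) * axis), "lesser trochanter direction")
    retroversion = float(np.degrees(np.arctan2(lt_vec @ -anterior, lt_vec @ condylar)))

    length = float(np.linalg.norm(C - mid_condyle))
    return FemurMeasures(
        neck_shaft_angle=nsa, femoral_anteversion=anteversion, femoral_offset=offset,
        head_radius=float(sphere.radius), lt_retroversion=retroversion,
        femoral_length=length, head_center=C,
    )


def measure_pelvis(pelvis: LandmarkMesh) -> PelvisMeasures:
    """Pelvic width, interspinous distance and their ratio (spine/width)."""
    for lm in ("iliac_lateral_left", "iliac_lateral_right",
               "ischial_spine_left", "ischial_spine_right"):
        if lm not in pelvis.landmarks:
            raise KeyError(f"pelvis is missing landmark {lm!r}")
    width = float(np.linalg.norm(pelvis.landmark_point("iliac_lateral_left")
                                 - pelvis.landmark_point("iliac_lateral_right")))
    isd = float(np.linalg.norm(pelvis.landmark_point("ischial_spine_left")
                               - pelvis.landmark_point("ischial_spine_right")))
    if width < 1e-9 or isd < 1e-9:
        raise DegenerateGeometryError("coincident left/right pelvic landmarks")
    return PelvisMeasures(pelvic_width=width, interspinous_distance=isd,
                          ischial_spine_ratio=isd / width)


def measure_hip(pelvis: LandmarkMesh, femur: LandmarkMesh, sample_id: int = 0,
                sex: str | None = None, method: str = "vertex") -> MorphometricRecord:
    fm = measure_femur(femur)
    pm = measure_pelvis(pelvis)
    pair = ischiofemoral_distance(femur, pelvis, method=method)
    d = asdict(fm)
    d.pop("head_center")
    return MorphometricRecord(
        **d, **asdict(pm), ischiofemoral_distance=pair.distance,
        sample_id=sample_id, sex=sex if sex is not None else "female",
    )


_RECORD_COLUMNS = [
    "sample_id", "sex", "neck_shaft_angle", "femoral_anteversion", "femoral_offset",
    "head_radius", "lt_retroversion", "femoral_length", "pelvic_width",
    "interspinous_distance", "ischial_spine_ratio", "ischiofemoral_distance",
]


def measure_cohort(hips, sex: str | None = None, method: str = "vertex") -> pd.DataFrame:
    """Measure a corresponded cohort of ``(pelvis, femur)`` pairs.

    Returns one row per sample ordered by sample id; a failure on any
    sample is re-raised with the offending sample id in the message.
    """
    rows = []
    for i, (pelvis, femur) in enumerate(hips):
        try:
            rec = measure_hip(pelvis, femur, sample_id=i, sex=sex or "female", method=method)
        except Exception as exc:
            raise type(exc)(f"sample {i}: {exc}") from exc
        rows.append(asdict(rec))
    df = pd.DataFrame(rows)
    return df[_RECORD_COLUMNS].sort_values("sample_id", ignore_index=True)
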
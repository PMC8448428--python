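"""Parametric virtual hip generator.

This module is the study-data stand-in: it builds corresponded pelvis +
femur surface meshes whose discrete anatomical measures (neck-shaft
angle, anteversion, offset, head radius, lesser-trochanter retroversion,
femoral length, pelvic width, interspinous distance) and the neutral-pose
ischiofemoral gap are *direct parameters* of the construction, drawn from
sex-specific normal distributions. Because every bone is assembled from
the same fixed parametric patch grids, all generated meshes share one
topology and are in exact dense correspondence by construction.

Construction overview (right hip, neutral pose, femoral head center at
the origin, pelvic midline plane at x = -85 mm):

* the femoral head is an exact sphere of ``head_radius``;
* the shaft is a symmetric cylinder whose principal axis is the anatomical
  shaft axis; the neck base sits on that axis so the neck axis makes
  exactly ``neck_shaft_angle`` with it and the head center lies exactly
  ``femoral_offset`` off the axis;
* the lesser trochanter is a spherical bump whose apex points
  posteromedially at ``lt_retroversion`` from the posterior condylar line;
* the ischial surface is a vertical cylindrical patch placed so that its
  grid vertex nearest the lesser-trochanter apex lies exactly
  ``ifd_gap`` away along the apex's outward direction — the headline
  distance is therefore a recoverable ground truth, not an emergent
  byproduct;
* ischial spines and iliac wings carry landmark vertices placed exactly
  ``interspinous_distance`` and ``pelvic_width`` apart.

Optional i.i.d. Gaussian vertex noise emulates surface measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .mesh import LandmarkMesh, mirror_mesh

__all__ = [
    "GeneratorParams",
    "ParameterDistributions",
    "default_distributions",
    "draw_params",
    "build_hip",
    "build_hip_pair",
    "generate_cohort",
    "PARAM_NAMES",
]

#: Parameter order used by distribution matrices and truth tables.
PARAM_NAMES = (
    "femoral_length", "femoral_offset", "neck_shaft_angle", "femoral_anteversion",
    "head_radius", "lt_retroversion", "pelvic_width", "interspinous_distance", "ifd_gap",
)

# Sex-specific parameter means and SDs (mm / degrees) for an adult
# western-European population.
_POPULATION = {
    "male": {
        "femoral_length": (427.68, 20.12),
        "femoral_offset": (38.05, 7.72),
        "neck_shaft_angle": (125.22, 5.48),
        "femoral_anteversion": (9.86, 7.07),
        "head_radius": (25.29, 1.06),
        "lt_retroversion": (27.17, 7.70),
        "pelvic_width": (174.30, 8.36),
        "interspinous_distance": (100.04, 7.01),
        "ifd_gap": (29.09, 4.12),
    },
    "female": {
        "femoral_length": (398.24, 19.99),
        "femoral_offset": (33.21, 6.80),
        "neck_shaft_angle": (126.44, 5.51),
        "femoral_anteversion": (10.82, 6.06),
        "head_radius": (22.37, 1.02),
        "lt_retroversion": (27.23, 8.31),
        "pelvic_width": (172.92, 8.23),
        "interspinous_distance": (114.68, 6.41),
        "ifd_gap": (22.24, 4.32),
    },
}

# Default correlation structure: femoral offset correlates positively and
# the interspinous distance negatively with the ischiofemoral gap,
# mirroring the signs reported for real hips.  Magnitudes are a design
# choice for sign-recovery demonstrations, not population estimates.
_DEFAULT_COUPLINGS = (("femoral_offset", "ifd_gap", 0.4),
                      ("interspinous_distance", "ifd_gap", -0.6))


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth anatomical parameter vector for one virtual subject."""

    femoral_length: float          # head center to mid-condylar point, mm
    femoral_offset: float          # head center to shaft axis, mm
    neck_shaft_angle: float        # neck axis vs shaft axis, degrees
    femoral_anteversion: float     # neck vs posterior condylar line, deg (+ anterior)
    head_radius: float             # mm
    lt_retroversion: float         # lesser trochanter vs condylar line, deg (+ posterior)
    pelvic_width: float            # between lateral-most iliac points, mm
    interspinous_distance: float   # between ischial spines, mm
    ifd_gap: float                 # neutral-pose minimal ischiofemoral distance, mm
    sex: str = "female"

    def is_valid(self) -> bool:
        p = self
        return (
            p.femoral_length > 0 and p.femoral_offset > 0 and p.head_radius > 0
            and p.pelvic_width > 0 and p.interspinous_distance > 0 and p.ifd_gap > 0
            and 90.0 < p.neck_shaft_angle < 160.0
            and abs(p.femoral_anteversion) < 45.0
            and -45.0 < p.lt_retroversion < 80.0
            and p.interspinous_distance < p.pelvic_width
            and p.femoral_length > 2.0 * p.femoral_offset
        )

    def validate(self) -> None:
        if not self.is_valid():
            raise ValueError(f"anatomically invalid generator parameters: {self}")

    def as_array(self) -> np.ndarray:
        d = asdict(self)
        return np.array([d[k] for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values, sex: str) -> "GeneratorParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))), sex=sex)


@dataclass(frozen=True)
class ParameterDistributions:
    """Multivariate-normal description of a sex's anatomical parameters."""

    means: np.ndarray          # length 9, PARAM_NAMES order
    sds: np.ndarray            # length 9
    correlation: np.ndarray    # 9 x 9, symmetric PSD, unit diagonal
    sex: str

    def __post_init__(self) -> None:
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        C = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)
        object.__setattr__(self, "correlation", C)
        k = len(PARAM_NAMES)
        if m.shape != (k,) or s.shape != (k,) or C.shape != (k, k):
            raise ValueError(f"expected {k} parameters in {PARAM_NAMES} order")
        if np.any(s <= 0):
            raise ValueError("standard deviations must be positive")
        if not np.allclose(C, C.T, atol=1e-10) or not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")

    @property
    def covariance(self) -> np.ndarray:
        return self.correlation * np.outer(self.sds, self.sds)

    def mean_params(self) -> GeneratorParams:
        return GeneratorParams.from_array(self.means, self.sex)


def default_distributions(sex: str, coupling_scale: float = 1.0) -> ParameterDistributions:
    """Sex-specific default parameter distributions.

    ``coupling_scale`` scales the default off-diagonal correlations
    (offset <-> gap +0.4, interspinous <-> gap -0.6); 0 gives independent
    parameters.
    """
    if sex not in _POPULATION:
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'")
    table = _POPULATION[sex]
    means = np.array([table[k][0] for k in PARAM_NAMES])
    sds = np.array([table[k][1] for k in PARAM_NAMES])
    C = np.eye(len(PARAM_NAMES))
    for a, b, r in _DEFAULT_COUPLINGS:
        i, j = PARAM_NAMES.index(a), PARAM_NAMES.index(b)
        C[i, j] = C[j, i] = r * coupling_scale
    return ParameterDistributions(means, sds, C, sex)


def draw_params(distributions: ParameterDistributions, n: int, seed) -> list[GeneratorParams]:
    """Draw ``n`` parameter vectors; anatomically invalid draws are redrawn."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(distributions.covariance + 1e-12 * np.eye(len(PARAM_NAMES)))
    out: list[GeneratorParams] = []
    while len(out) < n:
        z = rng.standard_normal((n - len(out), len(PARAM_NAMES)))
        draws = distributions.means + z @ L.T
        for row in draws:
            p = GeneratorParams.from_array(row, distributions.sex)
            if p.is_valid():
                out.append(p)
    return out


# ----------------------------------------------------------------------
# Patch primitives. All grids have fixed sizes so topology never changes.
# ----------------------------------------------------------------------

def _grid_faces(nr: int, nc: int, wrap: bool, base: int = 0) -> list[tuple[int, int, int]]:
    faces = []
    cols = nc if wrap else nc - 1
    for i in range(nr - 1):
        for j in range(cols):
            j2 = (j + 1) % nc
            a, b = base + i * nc + j, base + i * nc + j2
            c, d = base + (i + 1) * nc + j, base + (i + 1) * nc + j2
            faces.append((a, c, b))
            faces.append((b, c, d))
    return faces


def _orthonormal_pair(axis: np.ndarray, ref: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    if ref is None:
        ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.asarray(ref, float) - (np.asarray(ref, float) @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _uv_sphere(center, radius, n_lat=9, n_lon=12, axis=(0, 0, 1), ref=None):
    """Sphere grid with poles; ``ref`` fixes the azimuth-0 direction so a
    designated surface vertex lands exactly where needed. Returns
    (vertices, faces, equator_az0_index)."""
    axis = np.asarray(axis, float) / np.linalg.norm(np.asarray(axis, float))
    e1, e2 = _orthonormal_pair(axis, ref)
    lats = np.linspace(0.0, np.pi, n_lat + 2)[1:-1]          # exclude poles
    lons = np.linspace(0.0, 2 * np.pi, n_lon, endpoint=False)
    dirs = (np.sin(lats)[:, None, None] * (np.cos(lons)[None, :, None] * e1 +
                                           np.sin(lons)[None, :, None] * e2)
            + np.cos(lats)[:, None, None] * axis)
    ring_verts = center + radius * dirs.reshape(-1, 3)
    top = center + radius * axis
    bot = center - radius * axis
    verts = np.vstack([[top], ring_verts, [bot]])
    faces = _grid_faces(n_lat, n_lon, wrap=True, base=1)
    for j in range(n_lon):
        faces.append((0, 1 + j, 1 + (j + 1) % n_lon))
        last = 1 + (n_lat - 1) * n_lon
        faces.append((len(verts) - 1, last + (j + 1) % n_lon, last + j))
    # equatorial azimuth-0 vertex (n_lat odd puts a ring exactly at the equator)
    eq_ring = n_lat // 2
    eq_idx = 1 + eq_ring * n_lon
    return verts, faces, eq_idx


def _spherical_cap(center, radius, axis, max_angle_deg, n_rings=4, n_az=12, ref=None):
    """Cap of a sphere around ``axis``; vertex 0 is the apex."""
    axis = np.asarray(axis, float) / np.linalg.norm(np.asarray(axis, float))
    e1, e2 = _orthonormal_pair(axis, ref)
    angs = np.deg2rad(np.linspace(max_angle_deg / n_rings, max_angle_deg, n_rings))
    lons = np.linspace(0.0, 2 * np.pi, n_az, endpoint=False)
    dirs = (np.sin(angs)[:, None, None] * (np.cos(lons)[None, :, None] * e1 +
                                           np.sin(lons)[None, :, None] * e2)
            + np.cos(angs)[:, None, None] * axis)
    verts = np.vstack([[center + radius * axis], center + radius * dirs.reshape(-1, 3)])
    faces = _grid_faces(n_rings, n_az, wrap=True, base=1)
    for j in range(n_az):
        faces.append((0, 1 + j, 1 + (j + 1) % n_az))
    return verts, faces


def _cylinder(center_xy, radius, z_values, n_az=12, ref=None):
    """Full cylinder of horizontal rings around a vertical axis."""
    e1, e2 = _orthonormal_pair(np.array([0.0, 0.0, 1.0]), ref)
    lons = np.linspace(0.0, 2 * np.pi, n_az, endpoint=False)
    ring = np.cos(lons)[:, None] * e1 + np.sin(lons)[:, None] * e2
    z_values = np.asarray(z_values, float)
    verts = np.concatenate([
        np.c_[np.full(n_az, center_xy[0]), np.full(n_az, center_xy[1]), np.full(n_az, z)]
        + radius * ring for z in z_values])
    faces = _grid_faces(len(z_values), n_az, wrap=True)
    return verts, faces


def _cylinder_patch(axis_xy, radius, z_values, center_dir, half_angle_deg, n_az=15):
    """Angular sector of a vertical cylinder; returns the grid index of
    the (middle z, azimuth 0) vertex as the designated surface point."""
    center_dir = np.asarray(center_dir, float)
    center_dir = center_dir / np.linalg.norm(center_dir)
    e2 = np.array([-center_dir[1], center_dir[0], 0.0])
    angs = np.deg2rad(np.linspace(-half_angle_deg, half_angle_deg, n_az))
    ring = np.cos(angs)[:, None] * np.r_[center_dir[:2], 0.0] + np.sin(angs)[:, None] * e2
    z_values = np.asarray(z_values, float)
    verts = np.concatenate([
        np.c_[np.full(n_az, axis_xy[0]), np.full(n_az, axis_xy[1]), np.full(n_az, z)]
        + radius * ring for z in z_values])
    faces = _grid_faces(len(z_values), n_az, wrap=False)
    mid_row = len(z_values) // 2
    return verts, faces, mid_row * n_az + n_az // 2


def _pin(point, direction, size=0.8):
    """Tiny tetrahedron whose vertex 0 sits exactly at ``point``; used to
    anchor landmark vertices that are not part of a larger patch."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    e1, e2 = _orthonormal_pair(d, None)
    base = point + size * d
    verts = np.array([point, base + size * e1,
                      base + size * (-0.5 * e1 + 0.866 * e2),
                      base + size * (-0.5 * e1 - 0.866 * e2)])
    faces = [(0, 1, 2), (0, 2, 3), (0, 3, 1), (1, 3, 2)]
    return verts, faces


class _Builder:
    def __init__(self) -> None:
        self.verts: list[np.ndarray] = []
        self.faces: list[tuple[int, int, int]] = []
        self.regions: dict[str, list[int]] = {}
        self.landmarks: dict[str, int] = {}
        self._n = 0

    def add(self, verts, faces, region: str | None = None) -> int:
        base = self._n
        self.verts.append(np.asarray(verts, float))
        self.faces.extend((a + base, b + base, c + base) for a, b, c in faces)
        if region is not None:
            self.regions.setdefault(region, []).extend(range(base, base + len(verts)))
        self._n += len(verts)
        return base

    def mark(self, name: str, idx: int) -> None:
        self.landmarks[name] = idx

    def build(self, side: str, bone: str) -> LandmarkMesh:
        return LandmarkMesh(
            np.vstack(self.verts), np.asarray(self.faces, dtype=np.int64),
            self.landmarks, {k: np.asarray(v, dtype=np.int64) for k, v in self.regions.items()},
            side, bone,
        )


# fixed construction constants (mm / counts); part of the shared topology
_HALF_PELVIS = 85.0         # hip center to midline
_SHAFT_RADIUS = 13.0
_SHAFT_TOP_Z = -15.0
_LT_DIST = 21.0             # shaft axis to lesser-trochanter apex
_LT_Z = -12.0
_LT_RADIUS = 8.0
_CONDYLE_OFFSET = 25.0
_CONDYLE_RADIUS = 19.0
_ISCHIUM_RADIUS = 25.0
_SPINE_Y, _SPINE_Z, _SPINE_RADIUS = -40.0, 15.0, 3.0
_WING_Z, _WING_RADIUS = 95.0, 30.0
_ACETAB_CLEARANCE = 2.0


def _femur_frame(p: GeneratorParams):
    """Neck geometry in the femur-local frame (shaft axis = z through the
    neck base at the origin; medial = -x, anterior = +y for a right hip)."""
    eps = np.deg2rad(p.neck_shaft_angle - 90.0)
    alpha = np.deg2rad(p.femoral_anteversion)
    n = np.array([-np.cos(eps) * np.cos(alpha), np.cos(eps) * np.sin(alpha), np.sin(eps)])
    neck_len = p.femoral_offset / np.cos(eps)
    head_center = neck_len * n
    return n, neck_len, head_center


def build_hip(params: GeneratorParams, noise_sd: float = 0.0,
              rng: np.random.Generator | None = None) -> tuple[LandmarkMesh, LandmarkMesh]:
    """Build the (pelvis, femur) mesh pair for one parameter vector.

    Neutral pose, right hip, femoral head center at the origin.  With
    ``noise_sd`` = 0 every discrete measure equals its parameter exactly;
    positive ``noise_sd`` adds i.i.d. Gaussian vertex noise (mm).
    """
    params.validate()
    p = params
    n_dir, _neck_len, C = _femur_frame(p)
    rho = np.deg2rad(p.lt_retroversion)
    lt_dir = np.array([-np.cos(rho), -np.sin(rho), 0.0])   # posteromedial, right hip

    # ---- femur (local frame: neck base at origin, shaft axis = z) ----
    fb = _Builder()
    z_mid_condyle = C[2] - np.sqrt(p.femoral_length ** 2 - p.femoral_offset ** 2)

    head_v, head_f, _ = _uv_sphere(C, p.head_radius, n_lat=9, n_lon=14)
    fb.add(head_v, head_f, region="femoral_head")

    # neck sleeve, cosmetic (not used by any measure)
    tneck = np.linspace(0.15, 0.85, 6)[:, None]
    neck_centers = tneck * C
    neck_radii = 12.0 + tneck.ravel() * (0.75 * p.head_radius - 12.0)
    e1, e2 = _orthonormal_pair(n_dir, None)
    lons = np.linspace(0, 2 * np.pi, 10, endpoint=False)
    ring = np.cos(lons)[:, None] * e1 + np.sin(lons)[:, None] * e2
    neck_v = np.concatenate([c + r * ring for c, r in zip(neck_centers, neck_radii)])
    fb.add(neck_v, _grid_faces(6, 10, wrap=True))

    shaft_z = np.linspace(_SHAFT_TOP_Z, z_mid_condyle + 45.0, 26)
    shaft_v, shaft_f = _cylinder((0.0, 0.0), _SHAFT_RADIUS, shaft_z, n_az=12)
    fb.add(shaft_v, shaft_f, region="shaft")

    apex = np.array([_LT_DIST * lt_dir[0], _LT_DIST * lt_dir[1], _LT_Z])
    lt_center = apex - _LT_RADIUS * lt_dir
    lt_v, lt_f = _spherical_cap(lt_center, _LT_RADIUS, lt_dir, 55.0, n_rings=4, n_az=12)
    lt_base = fb.add(lt_v, lt_f, region="lesser_trochanter_area")
    fb.mark("lt_apex", lt_base)

    zc = z_mid_condyle + 12.0
    for sign, name in ((-1.0, "condyle_post_medial"), (+1.0, "condyle_post_lateral")):
        cv, cf, eq = _uv_sphere(np.array([sign * _CONDYLE_OFFSET, 0.0, zc]),
                                _CONDYLE_RADIUS, n_lat=7, n_lon=10,
                                ref=np.array([0.0, -1.0, 0.0]))
        base = fb.add(cv, cf, region="condyles")
        fb.mark(name, base + eq)           # posterior-most vertex, both at same y and z

    mid_v, mid_f = _pin(np.array([0.0, 0.0, z_mid_condyle]), np.array([0.0, 1.0, 0.0]))
    base = fb.add(mid_v, mid_f, region="condyles")
    fb.mark("condyle_mid", base)
    nb_v, nb_f = _pin(np.zeros(3), np.array([0.0, 1.0, 0.0]))
    base = fb.add(nb_v, nb_f)
    fb.mark("neck_base", base)

    femur = fb.build("right", "femur")
    femur.vertices -= C                      # head center -> origin (build frame)
    apex_build = apex - C

    # ---- pelvis (build frame) ----
    x_mid = -_HALF_PELVIS
    pb = _Builder()

    acet_axis = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0)    # superomedial
    av, af = _spherical_cap(np.zeros(3), p.head_radius + _ACETAB_CLEARANCE,
                            acet_axis, 55.0, n_rings=4, n_az=12)
    pb.add(av, af, region="acetabulum")

    # ischial surface: vertical cylinder patch whose nearest vertex to the
    # LT apex realizes the gap exactly
    axis_xy = apex_build[:2] + (p.ifd_gap + _ISCHIUM_RADIUS) * lt_dir[:2]
    z_vals = apex_build[2] + np.linspace(-35.0, 50.0, 18)    # includes the apex height
    iv, if_, closest = _cylinder_patch(axis_xy, _ISCHIUM_RADIUS, z_vals,
                                       -lt_dir, 55.0, n_az=15)
    base = pb.add(iv, if_, region="ischium")
    pb.mark("ischial_facing_point", base + closest)

    for sign, name in ((+1.0, "ischial_spine_right"), (-1.0, "ischial_spine_left")):
        cx = x_mid + sign * (p.interspinous_distance / 2.0 + _SPINE_RADIUS)
        sv, sf, eq = _uv_sphere(np.array([cx, _SPINE_Y, _SPINE_Z]), _SPINE_RADIUS,
                                n_lat=5, n_lon=8, ref=np.array([-sign, 0.0, 0.0]))
        base = pb.add(sv, sf, region="ischial_spines")
        pb.mark(name, base + eq)             # medial-most vertex of each spine bump

    for sign, name in ((+1.0, "iliac_lateral_right"), (-1.0, "iliac_lateral_left")):
        center = np.array([x_mid + sign * (p.pelvic_width / 2.0 - _WING_RADIUS), 0.0, _WING_Z])
        wv, wf = _spherical_cap(center, _WING_RADIUS, np.array([sign, 0.0, 0.0]),
                                45.0, n_rings=3, n_az=10)
        base = pb.add(wv, wf, region="iliac_wings")
        pb.mark(name, base)                  # cap apex = lateral-most point

    pelvis = pb.build("right", "pelvis")

    if noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        pelvis.vertices += rng.normal(0.0, noise_sd, pelvis.vertices.shape)
        femur.vertices += rng.normal(0.0, noise_sd, femur.vertices.shape)
    return pelvis, femur


def build_hip_pair(params: GeneratorParams, noise_sd: float = 0.0,
                   rng: np.random.Generator | None = None):
    """Mirrored left/right pair for symmetry studies.

    Returns ``((pelvis_right, femur_right), (pelvis_left, femur_left))``
    where the left pair is the exact sagittal mirror of the right.
    """
    pelvis, femur = build_hip(params, noise_sd=noise_sd, rng=rng)
    return (pelvis, femur), (mirror_mesh(pelvis), mirror_mesh(femur))


def generate_cohort(sex: str, n: int, seed, noise_sd: float = 0.05,
                    distributions: ParameterDistributions | None = None,
                    ) -> tuple[list[tuple[LandmarkMesh, LandmarkMesh]], pd.DataFrame]:
    """Generate ``n`` virtual hips of one sex plus the ground-truth table.

    Default vertex noise of 0.05 mm emulates residual surface measurement
    noise while staying well below the 0.5 mm geometric tolerance of the
    construction.
    """
    if distributions is None:
        distributions = default_distributions(sex)
    params = draw_params(distributions, n, seed)
    # separate stream for mesh noise so truth draws stay seed-stable
    noise_rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2 ** 31), 7919]))
    meshes = [build_hip(p, noise_sd=noise_sd, rng=noise_rng) for p in params]
    truth = pd.DataFrame([p.as_array() for p in params], columns=list(PARAM_NAMES))
    truth.insert(0, "sample_id", np.arange(n))
    truth["sex"] = sex
    return meshes, truth
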
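"""Gait imposition on a spherical hip joint and distance trajectories.

The hip is a ball joint: the femur rotates about the femoral head center
(three rotational degrees of freedom, no translation), the pelvis stays
fixed.  Rotations follow the intrinsic flexion / adduction / internal-
rotation Euler sequence about x, y', z'' with signs stated for a right
hip; an optional pelvic pre-tilt (anterior positive, about x) can be
applied before the sweep.

The packaged normative gait waveforms are an analytic stand-in for
subject-recorded walking kinematics: peak hip flexion of roughly 30
degrees around initial contact and terminal swing, peak extension of
roughly -10 degrees near 50% of the cycle, and small adduction and
axial-rotation excursions, with slightly larger flexion range for the
female curve.  User-recorded curves can be supplied as CSV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh import LandmarkMesh, fit_sphere, rotation_from_euler, apply_transform

__all__ = [
    "GaitCycle",
    "DistanceTrajectory",
    "load_gait",
    "normative_gait",
    "pose_femur",
    "ifd_trajectory",
    "extension_sweep",
]

GAIT_COLUMNS = ("phase_percent", "flexion_deg", "adduction_deg", "internal_rotation_deg")


@dataclass(frozen=True)
class GaitCycle:
    """Per-phase hip rotation angles over one gait cycle (0-100%)."""

    phase: np.ndarray
    flexion: np.ndarray
    adduction: np.ndarray
    internal_rotation: np.ndarray
    sex: str = "unspecified"
    source: str = "user"

    def __post_init__(self) -> None:
        for name in ("phase", "flexion", "adduction", "internal_rotation"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        ph = self.phase
        if ph.ndim != 1 or len(ph) < 2 or np.any(np.diff(ph) <= 0):
            raise ValueError("gait phase must be strictly increasing")
        if abs(ph[0]) > 1e-9 or abs(ph[-1] - 100.0) > 1e-9:
            raise ValueError("gait phase must start at 0 and end at 100")
        for name in ("flexion", "adduction", "internal_rotation"):
            a = getattr(self, name)
            if a.shape != ph.shape or not np.all(np.isfinite(a)):
                raise ValueError(f"gait angle column {name!r} malformed")
            if np.max(np.abs(a)) >= 90.0:
                raise ValueError(f"gait angle {name!r} out of the +-90 degree range")

    def resample(self, phase_step: float) -> "GaitCycle":
        if phase_step <= 0 or 100.0 % phase_step > 1e-9:
            raise ValueError("phase_step must be positive and divide the cycle")
        grid = np.arange(0.0, 100.0 + phase_step / 2, phase_step)
        return GaitCycle(
            grid,
            np.interp(grid, self.phase, self.flexion),
            np.interp(grid, self.phase, self.adduction),
            np.interp(grid, self.phase, self.internal_rotation),
            self.sex, self.source,
        )

    def angles(self) -> np.ndarray:
        return np.column_stack([self.flexion, self.adduction, self.internal_rotation])


@dataclass(frozen=True)
class DistanceTrajectory:
    """Ischiofemoral distance along the gait phase grid."""

    phase: np.ndarray
    ifd: np.ndarray

    @property
    def min_ifd(self) -> float:
        return float(np.min(self.ifd))

    @property
    def min_phase(self) -> float:
        return float(self.phase[int(np.argmin(self.ifd))])   # first occurrence on ties


def normative_gait(sex: str, phase_step: float = 2.0) -> GaitCycle:
    """Analytic normative walking waveform (documented stand-in)."""
    amp = {"male": (10.0, 20.0), "female": (10.5, 21.5)}
    if sex not in amp:
        raise ValueError(f"unknown sex {sex!r} for the normative gait curve")
    off, a = amp[sex]
    phase = np.arange(0.0, 100.0 + phase_step / 2, phase_step)
    th = 2 * np.pi * phase / 100.0
    flexion = off + a * np.cos(th) + 2.0 * np.sin(2 * th)
    adduction = (2.0 if sex == "male" else 3.0) + 3.0 * np.sin(th)
    internal = 1.0 + 4.0 * np.sin(th + 0.4)
    return GaitCycle(phase, flexion, adduction, internal, sex=sex, source=f"normative_{sex}")


def load_gait(path_or_builtin, sex: str | None = None) -> GaitCycle:
    """Load a gait cycle from CSV or by builtin name.

    Builtin names: ``"normative"`` (with ``sex``), ``"normative_male"``,
    ``"normative_female"``. CSV columns: phase_percent, flexion_deg,
    adduction_deg, internal_rotation_deg.
    """
    name = str(path_or_builtin)
    if name == "normative":
        if sex is None:
            raise ValueError("builtin 'normative' needs a sex")
        return normative_gait(sex)
    if name.startswith("normative_"):
        return normative_gait(name.removeprefix("normative_"))
    path = Path(name)
    if not path.exists():
        raise FileNotFoundError(f"gait source not found: {path}")
    df = pd.read_csv(io.StringIO(path.read_text()), comment="#")
    missing = [c for c in GAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gait CSV is missing columns {missing}")
    return GaitCycle(df["phase_percent"].to_numpy(), df["flexion_deg"].to_numpy(),
                     df["adduction_deg"].to_numpy(), df["internal_rotation_deg"].to_numpy(),
                     sex=sex or "unspecified", source=str(path))


def pose_femur(femur: LandmarkMesh, joint_center, angles,
               sequence: str = "XYZ") -> LandmarkMesh:
    """Rotate the femur about the joint center (ball joint, no translation)."""
    transform = rotation_from_euler(np.asarray(angles, dtype=float), sequence,
                                    center=np.asarray(joint_center, dtype=float))
    return apply_transform(femur, transform)


def _joint_center(femur: LandmarkMesh) -> np.ndarray:
    return fit_sphere(femur.region_points("femoral_head")).center


def ifd_trajectory(pelvis: LandmarkMesh, femur: LandmarkMesh, gait: GaitCycle,
                   phase_step: float = 2.0, joint_center=None,
                   sequence: str = "XYZ", pelvic_tilt: float = 0.0) -> DistanceTrajectory:
    """Ischiofemoral distance at every phase of the (resampled) gait cycle.

    Only the femur moves; ``pelvic_tilt`` (degrees, anterior positive)
    optionally pre-rotates the pelvis about the joint center.  The
    distance at each phase is the same nearest-neighbor measure as the
    static morphometry — only the lesser-trochanter vertices need to be
    rotated per phase, which keeps cohort-scale sweeps cheap.
    """
    center = np.asarray(joint_center, dtype=float) if joint_center is not None \
        else _joint_center(femur)
    if pelvic_tilt != 0.0:
        # anterior tilt (iliac crests forward) is the negative x rotation
        # in the flexion-positive convention
        tilt = rotation_from_euler([-pelvic_tilt, 0.0, 0.0], "XYZ", center=center)
        pelvis = apply_transform(pelvis, tilt)
    cycle = gait.resample(phase_step)
    tree = cKDTree(pelvis.vertices)
    src = femur.region_points("lesser_trochanter_area") - center
    dists = np.empty(len(cycle.phase))
    for i, ang in enumerate(cycle.angles()):
        R = rotation_from_euler(ang, sequence).rotation
        moved = src @ R.T + center
        d, _ = tree.query(moved)
        dists[i] = d.min()
    return DistanceTrajectory(cycle.phase, dists)


def extension_sweep(pelvis: LandmarkMesh, femur: LandmarkMesh,
                    angle_range: tuple[float, float] = (-15.0, 30.0),
                    step: float = 1.0, joint_center=None,
                    sequence: str = "XYZ") -> pd.DataFrame:
    """Ischiofemoral distance over a pure flexion(-)/extension sweep.

    Returns a table with columns ``flexion_deg`` and ``ifd_mm``; zero
    adduction and axial rotation throughout.
    """
    lo, hi = angle_range
    if hi < lo:
        raise ValueError("empty angle range")
    center = np.asarray(joint_center, dtype=float) if joint_center is not None \
        else _joint_center(femur)
    angles = np.arange(lo, hi + step / 2, step) if hi > lo else np.array([lo])
    tree = cKDTree(pelvis.vertices)
    src = femur.region_points("lesser_trochanter_area") - center
    out = np.empty(len(angles))
    for i, a in enumerate(angles):
        R = rotation_from_euler([a, 0.0, 0.0], sequence).rotation
        d, _ = tree.query(src @ R.T + center)
        out[i] = d.min()
    return pd.DataFrame({"flexion_deg": angles, "ifd_mm": out})
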
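"""Corresponded landmark meshes, file I/O and rigid geometry.

A :class:`LandmarkMesh` is a triangulated bone surface whose vertex order
is meaningful: two meshes are *corresponded* when vertex ``i`` denotes the
same anatomical location on both, so faces, named landmarks and region
index sets can be shared across a whole cohort.  All coordinates are in
millimetres, in a right-handed frame with x pointing left-to-right,
y posterior-to-anterior and z inferior-to-superior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

__all__ = [
    "LandmarkMesh",
    "RigidTransform",
    "SphereFit",
    "MeshFormatError",
    "DegenerateGeometryError",
    "read_mesh",
    "write_mesh",
    "fit_sphere",
    "apply_transform",
    "rotation_from_euler",
    "mirror_mesh",
]

#: Region names every femur mesh must carry.
FEMUR_REGIONS = ("lesser_trochanter_area", "femoral_head", "shaft", "condyles")
#: Region names every pelvis mesh must carry.
PELVIS_REGIONS = ("ischium", "ischial_spines", "iliac_wings", "acetabulum")


class MeshFormatError(ValueError):
    """Malformed mesh file or landmark sidecar."""


class DegenerateGeometryError(ValueError):
    """Geometric input without a well-defined solution (coplanar sphere
    fit, zero-length axis, coincident landmarks, ...)."""


@dataclass
class LandmarkMesh:
    """Triangulated bone surface with named landmarks and regions.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    landmarks : mapping of landmark name -> vertex index
    regions : mapping of region name -> integer array of vertex indices
    side : "left" or "right"
    bone : "femur" or "pelvis"
    """

    vertices: np.ndarray
    faces: np.ndarray
    landmarks: dict[str, int] = field(default_factory=dict)
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    side: str = "right"
    bone: str = "femur"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise MeshFormatError("faces must be an (m, 3) array")
        self.regions = {k: np.asarray(v, dtype=np.int64) for k, v in self.regions.items()}
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshFormatError("face index out of range")
        for name, idx in self.landmarks.items():
            if not 0 <= int(idx) < n:
                raise MeshFormatError(f"landmark {name!r} index {idx} out of range for {n} vertices")
        for name, idx in self.regions.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise MeshFormatError(f"region {name!r} has an index out of range for {n} vertices")

    # -- convenience -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def landmark_point(self, name: str) -> np.ndarray:
        return self.vertices[self.landmarks[name]]

    def region_points(self, name: str) -> np.ndarray:
        if name not in self.regions:
            raise KeyError(f"mesh has no region {name!r}")
        idx = self.regions[name]
        if idx.size == 0:
            raise DegenerateGeometryError(f"region {name!r} is empty")
        return self.vertices[idx]

    def copy(self) -> "LandmarkMesh":
        return LandmarkMesh(
            self.vertices.copy(), self.faces.copy(),
            dict(self.landmarks), {k: v.copy() for k, v in self.regions.items()},
            self.side, self.bone,
        )

    def same_topology(self, other: "LandmarkMesh") -> bool:
        """True when the two meshes are corresponded: identical faces,
        landmark names/indices and region index sets."""
        return (
            self.faces.shape == other.faces.shape
            and bool(np.array_equal(self.faces, other.faces))
            and self.landmarks == other.landmarks
            and self.regions.keys() == other.regions.keys()
            and all(np.array_equal(self.regions[k], other.regions[k]) for k in self.regions)
        )

    def topology_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.faces).tobytes())
        for name in sorted(self.landmarks):
            h.update(name.encode())
            h.update(str(self.landmarks[name]).encode())
        for name in sorted(self.regions):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.regions[name]).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map x -> R x + t (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper orthonormal (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equal to applying ``other`` first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass(frozen=True)
class SphereFit:
    center: np.ndarray
    radius: float
    rms_residual: float


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Least-squares sphere through a 3D point cloud.

    Uses the linear algebraic formulation: ``|x|^2 = 2 c.x + (r^2 - |c|^2)``
    solved by ordinary least squares. Exact on noise-free spherical input.

    Raises
    ------
    DegenerateGeometryError
        for fewer than 4 points or a (near-)coplanar configuration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise DegenerateGeometryError("sphere fit needs at least 4 three-dimensional points")
    A = np.c_[2.0 * pts, np.ones(len(pts))]
    b = (pts ** 2).sum(axis=1)
    # coplanarity check: rank of the centered cloud
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = max(svals[0], 1e-12)
    if svals[-1] / scale < 1e-9:
        raise DegenerateGeometryError("points are coplanar; sphere is not determined")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("sphere fit produced a non-positive radius")
    radius = float(np.sqrt(r2))
    resid = np.linalg.norm(pts - center, axis=1) - radius
    return SphereFit(center=center, radius=radius, rms_residual=float(np.sqrt(np.mean(resid ** 2))))


def apply_transform(mesh: LandmarkMesh, transform: RigidTransform) -> LandmarkMesh:
    """Rigidly map every vertex; connectivity, landmarks and regions are shared."""
    out = mesh.copy()
    out.vertices = transform.apply(mesh.vertices)
    return out


def mirror_mesh(mesh: LandmarkMesh) -> LandmarkMesh:
    """Reflect through the sagittal (x = 0) plane, producing the
    contralateral bone. Face winding is flipped so outward normals are
    preserved; landmark and region names are kept verbatim."""
    out = mesh.copy()
    out.vertices = mesh.vertices * np.array([-1.0, 1.0, 1.0])
    if out.faces.size:
        out.faces = out.faces[:, ::-1].copy()
    out.side = {"left": "right", "right": "left"}.get(mesh.side, mesh.side)
    return out


#: Supported intrinsic Euler sequences, keyed by config label.
_EULER_SEQUENCES = {"XYZ": "XYZ", "XZY": "XZY", "ZXY": "ZXY", "ZYX": "ZYX", "YXZ": "YXZ", "YZX": "YZX"}


def rotation_from_euler(angles, sequence: str = "XYZ",
                        center: np.ndarray | None = None) -> RigidTransform:
    """Rigid rotation from intrinsic Euler angles in degrees.

    The default ``"XYZ"`` sequence is the hip convention used throughout:
    flexion(+)/extension(-) about x, adduction(+)/abduction(-) about the
    rotated y, internal(+)/external(-) rotation about the twice-rotated z,
    signs stated for a right hip. ``center``, when given, makes the map a
    rotation about that fixed point instead of the origin.
    """
    seq = _EULER_SEQUENCES.get(str(sequence).upper())
    if seq is None:
        raise ValueError(f"unknown Euler sequence {sequence!r}; choose one of {sorted(_EULER_SEQUENCES)}")
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (3,):
        raise ValueError("expected three Euler angles")
    R = Rotation.from_euler(seq, angles, degrees=True).as_matrix()
    if center is None:
        t = np.zeros(3)
    else:
        center = np.asarray(center, dtype=float)
        t = center - R @ center
    return RigidTransform(R, t)


# ----------------------------------------------------------------------
# File I/O: PLY / OBJ geometry via trimesh, landmarks in a JSON sidecar.
# ----------------------------------------------------------------------

def _sidecar_path(mesh_path: Path) -> Path:
    return mesh_path.with_suffix(mesh_path.suffix + ".landmarks.json")


def _ply_double_bytes(mesh: LandmarkMesh) -> bytes:
    """Binary little-endian PLY with double-precision vertices.

    Correspondence analysis needs coordinates preserved well below the
    1e-6 mm round-trip contract at anatomical (hundreds of mm) scale,
    which single-precision PLY cannot guarantee.
    """
    header = (
        "ply\nformat binary_little_endian 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {len(mesh.faces)}\n"
        "property list uchar int vertex_indices\nend_header\n"
    ).encode("ascii")
    verts = np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes()
    faces = np.empty(len(mesh.faces), dtype=[("n", "u1"), ("idx", "<i4", (3,))])
    faces["n"] = 3
    faces["idx"] = mesh.faces
    return header + verts + faces.tobytes()


def write_mesh(mesh: LandmarkMesh, path, file_format: str | None = None) -> None:
    """Write geometry as PLY (binary, double precision) or OBJ plus a
    JSON landmark sidecar."""
    path = Path(path)
    if mesh.n_vertices == 0:
        raise MeshFormatError("refusing to write an empty mesh")
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "obj"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        path.write_bytes(_ply_double_bytes(mesh))
    else:
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        tm.export(path, file_type=fmt)
    sidecar = {
        "side": mesh.side,
        "bone": mesh.bone,
        "landmarks": {k: int(v) for k, v in mesh.landmarks.items()},
        "regions": {k: [int(i) for i in v] for k, v in mesh.regions.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True))


def read_mesh(path, file_format: str | None = None, landmark_file=None) -> LandmarkMesh:
    """Read a PLY/OBJ mesh and its landmark sidecar, preserving vertex order.

    Vertex order is the correspondence, so the loader never merges,
    reorders or drops vertices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "obj"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    try:
        tm = trimesh.load(path, file_type=fmt, process=False, maintain_order=True)
    except Exception as exc:  # pragma: no cover - trimesh error text varies
        raise MeshFormatError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.vertices) == 0:
        raise MeshFormatError(f"{path} does not contain a triangulated mesh")

    landmark_path = Path(landmark_file) if landmark_file is not None else _sidecar_path(path)
    meta: dict = {}
    if landmark_path.exists():
        try:
            meta = json.loads(landmark_path.read_text())
        except json.JSONDecodeError as exc:
            raise MeshFormatError(f"malformed landmark file {landmark_path}: {exc}") from exc
    elif landmark_file is not None:
        raise FileNotFoundError(f"landmark file not found: {landmark_path}")

    landmarks = {str(k): int(v) for k, v in meta.get("landmarks", {}).items()}
    regions = {str(k): np.asarray(v, dtype=np.int64) for k, v in meta.get("regions", {}).items()}
    n = len(tm.vertices)
    for name, idx in landmarks.items():
        if not 0 <= idx < n:
            raise MeshFormatError(f"landmark {name!r} index {idx} out of range for {n} vertices")
    for name, idx in regions.items():
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise MeshFormatError(f"region {name!r} index out of range for {n} vertices")
    return LandmarkMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        landmarks=landmarks,
        regions=regions,
        side=meta.get("side", "right"),
        bone=meta.get("bone", "femur"),
    )
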
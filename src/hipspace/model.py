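"""Point distribution models of corresponded bone surfaces.

A point distribution model (PDM) is the linear generative shape model

    S = S_mean + P^T b,        b_i ~ N(0, lambda_i)

where ``S`` is the 3n-vector of stacked landmark coordinates, the rows of
``P`` are orthonormal principal modes of variation from PCA of the
training shapes, and ``lambda_i`` are the mode variances (eigenvalues of
the training covariance, mm^2).  Dividing ``b_i`` by ``sqrt(lambda_i)``
gives the Mahalanobis-space score, approximately standard normal per mode
under the model, which is the subspace used by the downstream shape
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .mesh import LandmarkMesh, DegenerateGeometryError

__all__ = [
    "PointDistributionModel",
    "ShapeSample",
    "build_pdm",
    "sample_population",
    "reconstruct",
    "mahalanobis_scores",
    "save_model",
    "load_model",
    "stack_shape",
]


def stack_shape(*meshes: LandmarkMesh) -> np.ndarray:
    """Concatenate mesh vertices into a single 3n shape vector."""
    return np.concatenate([m.vertices.ravel() for m in meshes])


@dataclass
class ShapeSample:
    """One virtual subject drawn from a PDM: mode weights and the shape."""

    weights: np.ndarray          # b, length t (mm per unit mode)
    shape: np.ndarray            # 3n-vector, mm
    cohort_id: int = 0
    sex: str = "female"


class PointDistributionModel(BaseEstimator, TransformerMixin):
    """PCA shape model over corresponded meshes, sklearn-style.

    Parameters
    ----------
    n_modes : int or None, default 20
        Number of retained variation modes ``t``. The default mirrors the
        common 20-mode setting which captures >=99% of anatomical variance
        in dense lower-limb models; it is truncated to ``n_training - 1``
        when fewer training shapes are available.
    variance_fraction : float or None
        If given (and ``n_modes`` is None), retain the smallest number of
        modes whose cumulative explained variance reaches this fraction.
    clip_sd : float or None
        Optional +-clip (in per-mode standard deviations) applied when
        sampling. Off by default: sampling is untruncated normal.

    Attributes
    ----------
    mean_ : (3n,) array — mean shape, mm.
    components_ : (t, 3n) array — orthonormal modes (rows).
    explained_variance_ : (t,) array — eigenvalues, descending, mm^2.
    total_variance_ : float — total training variance (sum over all
        nonzero eigenvalues, not only the retained ones).
    n_training_ : int
    """

    def __init__(self, n_modes: int | None = 20, variance_fraction: float | None = None,
                 clip_sd: float | None = None):
        self.n_modes = n_modes
        self.variance_fraction = variance_fraction
        self.clip_sd = clip_sd

    # -- fitting -----------------------------------------------------
    def fit(self, X, y=None):
        """Fit the model to an (n_samples, 3n) matrix of shape vectors."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 3:
            raise ValueError("need at least 3 corresponded training shapes")
        n = len(X)
        self.mean_ = X.mean(axis=0)
        centered = X - self.mean_
        # economy SVD: eigenvalues of the covariance are s^2/(n-1)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        eig = s ** 2 / (n - 1)
        total = float(eig.sum())
        scale = float(np.mean(X ** 2))
        if total <= 1e-12 * max(scale, 1.0):
            raise DegenerateGeometryError("training shapes carry no variance; model is degenerate")
        nonzero = eig > max(1e-12 * eig[0], 1e-30)
        eig, vt = eig[nonzero], vt[nonzero]
        if self.n_modes is not None:
            t = int(min(self.n_modes, len(eig)))
        elif self.variance_fraction is not None:
            frac = np.cumsum(eig) / total
            t = int(np.searchsorted(frac, self.variance_fraction - 1e-12) + 1)
            t = min(t, len(eig))
        else:
            t = len(eig)
        self.components_ = vt[:t]
        self.explained_variance_ = eig[:t]
        self.total_variance_ = total
        self.n_training_ = n
        return self

    @property
    def n_modes_(self) -> int:
        return len(self.explained_variance_)

    def explained_variance_fraction(self) -> float:
        """Cumulative share of total training variance in the retained modes."""
        return float(self.explained_variance_.sum() / self.total_variance_)

    # -- projection / reconstruction ---------------------------------
    def transform(self, X) -> np.ndarray:
        """Project shape vectors onto the retained modes -> weights b."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, B) -> np.ndarray:
        """Reconstruct shape vectors from mode weights."""
        B = np.atleast_2d(np.asarray(B, dtype=float))
        return self.mean_ + B @ self.components_

    def scores(self, X_or_b, is_weights: bool = False) -> np.ndarray:
        """Mahalanobis-space scores b_i / sqrt(lambda_i)."""
        if np.any(self.explained_variance_ <= 0):
            raise DegenerateGeometryError("zero eigenvalue: Mahalanobis scores undefined")
        b = np.atleast_2d(np.asarray(X_or_b, dtype=float)) if is_weights else self.transform(X_or_b)
        return b / np.sqrt(self.explained_variance_)

    # -- sampling ----------------------------------------------------
    def sample_weights(self, n_samples: int, seed) -> np.ndarray:
        """Draw ``b`` with independent b_i ~ N(0, lambda_i); untruncated
        unless ``clip_sd`` was set."""
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        sd = np.sqrt(self.explained_variance_)
        b = rng.standard_normal((n_samples, self.n_modes_)) * sd
        if self.clip_sd is not None:
            b = np.clip(b, -self.clip_sd * sd, self.clip_sd * sd)
        return b


@dataclass
class _Topology:
    """Shared connectivity carried from the training meshes."""

    faces: list[np.ndarray]
    landmarks: list[dict]
    regions: list[dict]
    sides: list[str]
    bones: list[str]
    n_vertices: list[int]


class MeshPDM(PointDistributionModel):
    """A PDM fitted from :class:`LandmarkMesh` objects; reconstructs meshes.

    The training meshes of each sample (e.g. pelvis + femur) are stacked
    into one shape vector, so a single model captures joint variation of
    the articulated pair. Topology (faces, landmark and region maps) is
    taken from the first training sample and copied onto every
    reconstruction — this is the automatic landmark transfer of the
    virtual-population generation step.
    """

    def __init__(self, n_modes: int | None = 20, variance_fraction: float | None = None,
                 clip_sd: float | None = None, sex: str = "female"):
        super().__init__(n_modes=n_modes, variance_fraction=variance_fraction, clip_sd=clip_sd)
        self.sex = sex

    def fit_meshes(self, mesh_sets: list[tuple[LandmarkMesh, ...]]):
        if len(mesh_sets) < 3:
            raise ValueError("need at least 3 corresponded training samples")
        first = mesh_sets[0]
        if isinstance(first, LandmarkMesh):
            mesh_sets = [(m,) for m in mesh_sets]
            first = mesh_sets[0]
        for sample in mesh_sets[1:]:
            if len(sample) != len(first) or not all(
                    a.same_topology(b) for a, b in zip(sample, first)):
                raise ValueError("training meshes are not corresponded (topology mismatch)")
        self.topology_ = _Topology(
            faces=[m.faces.copy() for m in first],
            landmarks=[dict(m.landmarks) for m in first],
            regions=[{k: v.copy() for k, v in m.regions.items()} for m in first],
            sides=[m.side for m in first],
            bones=[m.bone for m in first],
            n_vertices=[m.n_vertices for m in first],
        )
        X = np.stack([stack_shape(*sample) for sample in mesh_sets])
        return self.fit(X)

    def shape_to_meshes(self, shape: np.ndarray) -> tuple[LandmarkMesh, ...]:
        out, offset = [], 0
        topo = self.topology_
        for i, nv in enumerate(topo.n_vertices):
            verts = np.asarray(shape[offset:offset + 3 * nv], dtype=float).reshape(nv, 3)
            offset += 3 * nv
            out.append(LandmarkMesh(verts, topo.faces[i], dict(topo.landmarks[i]),
                                    {k: v.copy() for k, v in topo.regions[i].items()},
                                    topo.sides[i], topo.bones[i]))
        return tuple(out)

    def reconstruct_meshes(self, weights: np.ndarray) -> tuple[LandmarkMesh, ...]:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (self.n_modes_,):
            raise ValueError(f"expected {self.n_modes_} mode weights, got shape {weights.shape}")
        return self.shape_to_meshes(self.inverse_transform(weights)[0])


# ----------------------------------------------------------------------
# Functional wrappers matching the operation-level interface.
# ----------------------------------------------------------------------

def build_pdm(mesh_sets, n_modes_or_variance_fraction=20, sex: str = "female") -> MeshPDM:
    """Build a PDM from corresponded mesh samples.

    ``n_modes_or_variance_fraction`` < 1 is read as a cumulative variance
    fraction, otherwise as an explicit mode count.
    """
    v = n_modes_or_variance_fraction
    if isinstance(v, float) and 0 < v < 1:
        model = MeshPDM(n_modes=None, variance_fraction=v, sex=sex)
    else:
        model = MeshPDM(n_modes=int(v), sex=sex)
    return model.fit_meshes(mesh_sets)


def sample_population(pdm: MeshPDM, n_samples: int, seed) -> list[ShapeSample]:
    """Monte-Carlo sample a virtual population: b_i ~ N(0, lambda_i)."""
    B = pdm.sample_weights(n_samples, seed)
    shapes = pdm.inverse_transform(B)
    sex = getattr(pdm, "sex", "female")
    return [ShapeSample(weights=B[i], shape=shapes[i], cohort_id=i, sex=sex)
            for i in range(n_samples)]


def reconstruct(pdm: MeshPDM, weights) -> tuple[LandmarkMesh, ...]:
    return pdm.reconstruct_meshes(np.asarray(weights, dtype=float))


def mahalanobis_scores(pdm: PointDistributionModel, shape_or_weights, is_weights=False) -> np.ndarray:
    return pdm.scores(shape_or_weights, is_weights=is_weights)


# ----------------------------------------------------------------------
# Serialization: a single .npz archive (layout version 1).
# ----------------------------------------------------------------------

def save_model(pdm: MeshPDM, path) -> None:
    topo = pdm.topology_
    meta = {
        "version": 1,
        "sex": pdm.sex,
        "n_training": pdm.n_training_,
        "total_variance": pdm.total_variance_,
        "landmarks": topo.landmarks,
        "regions": [{k: v.tolist() for k, v in r.items()} for r in topo.regions],
        "sides": topo.sides,
        "bones": topo.bones,
        "n_vertices": topo.n_vertices,
    }
    arrays = {
        "mean": pdm.mean_,
        "components": pdm.components_,
        "eigenvalues": pdm.explained_variance_,
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    for i, f in enumerate(topo.faces):
        arrays[f"faces_{i}"] = f
    np.savez_compressed(path, **arrays)


def load_model(path) -> MeshPDM:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("version") != 1:
            raise ValueError("unknown model archive version")
        pdm = MeshPDM(n_modes=len(data["eigenvalues"]), sex=meta["sex"])
        pdm.mean_ = data["mean"]
        pdm.components_ = data["components"]
        pdm.explained_variance_ = data["eigenvalues"]
        pdm.total_variance_ = float(meta["total_variance"])
        pdm.n_training_ = int(meta["n_training"])
        pdm.topology_ = _Topology(
            faces=[data[f"faces_{i}"] for i in range(len(meta["n_vertices"]))],
            landmarks=[{k: int(v) for k, v in lm.items()} for lm in meta["landmarks"]],
            regions=[{k: np.asarray(v, dtype=np.int64) for k, v in r.items()}
                     for r in meta["regions"]],
            sides=meta["sides"],
            bones=meta["bones"],
            n_vertices=[int(v) for v in meta["n_vertices"]],
        )
    return pdm
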
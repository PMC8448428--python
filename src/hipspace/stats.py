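"""Statistical battery relating hip shape and discrete measures to the
ischiofemoral distance.

Three views of the shape-distance relationship are provided:

* per-measure Pearson correlations with the ischiofemoral distance,
  computed per sex (the conventional metric approach);
* canonical correlation between the Mahalanobis-space shape scores and
  the distance.  With a single response variable the canonical
  correlation equals the multiple correlation of the distance on the
  scores, and Rao's F approximation reduces to the overall-regression F
  test — which is how it is computed here.  An sklearn-style estimator
  (:class:`ShapeDistanceCCA`) exposes the fit;
* partial least squares regression quantifying how much of the total
  shape variance the distance covariate explains, and the shape
  regression that renders consensus anatomies at the mean and at +-k SD
  of the distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "SexDifference",
    "CcaResult",
    "PlsrResult",
    "ShapeRegressionResult",
    "ShapeDistanceCCA",
    "sex_difference_test",
    "correlation_table",
    "cca_shape_ifd",
    "plsr_variance_explained",
    "shape_regression",
    "centroid_size",
]

_MEASURE_COLUMNS = [
    "neck_shaft_angle", "femoral_anteversion", "femoral_offset", "head_radius",
    "lt_retroversion", "femoral_length", "pelvic_width", "interspinous_distance",
    "ischial_spine_ratio",
]


@dataclass(frozen=True)
class SexDifference:
    mean_male: float
    sd_male: float
    mean_female: float
    sd_female: float
    statistic: float
    p_value: float


def sex_difference_test(values_male, values_female) -> SexDifference:
    """Welch two-sample t test (unequal variances), two-sided."""
    m = np.asarray(values_male, dtype=float)
    f = np.asarray(values_female, dtype=float)
    if len(m) < 2 or len(f) < 2:
        raise ValueError("need at least two observations per sex")
    if np.std(m, ddof=1) == 0 and np.std(f, ddof=1) == 0 and np.mean(m) == np.mean(f):
        return SexDifference(float(np.mean(m)), 0.0, float(np.mean(f)), 0.0, 0.0, 1.0)
    res = sps.ttest_ind(m, f, equal_var=False)
    return SexDifference(
        float(np.mean(m)), float(np.std(m, ddof=1)),
        float(np.mean(f)), float(np.std(f, ddof=1)),
        float(res.statistic), float(res.pvalue),
    )


def correlation_table(measures: pd.DataFrame, measure_columns=None) -> pd.DataFrame:
    """Per-measure Pearson correlation with the ischiofemoral distance.

    One row per (sex, measure) with ``r``, the raw two-sided ``p`` and a
    Bonferroni-adjusted column (an extension over raw reporting).
    Constant measures are flagged with ``r`` = NaN.
    """
    cols = [c for c in (measure_columns or _MEASURE_COLUMNS) if c in measures.columns]
    if "ischiofemoral_distance" not in measures.columns:
        raise ValueError("measures table lacks an 'ischiofemoral_distance' column")
    rows = []
    for sex, group in measures.groupby("sex", sort=True):
        if len(group) < 3:
            raise ValueError(f"need at least 3 complete records for sex {sex!r}")
        y = group["ischiofemoral_distance"].to_numpy(dtype=float)
        for col in cols:
            x = group[col].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"sex": sex, "measure": col, "r": np.nan, "p": np.nan,
                             "constant": True})
                continue
            r, p = sps.pearsonr(x, y)
            rows.append({"sex": sex, "measure": col, "r": float(r), "p": float(p),
                         "constant": False})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p"] * len(cols), 1.0)
    return df


def centroid_size(shapes: np.ndarray) -> np.ndarray:
    """Centroid size of each 3n shape vector: sqrt of the summed squared
    distances of the landmarks to their centroid."""
    X = np.atleast_2d(np.asarray(shapes, dtype=float))
    pts = X.reshape(len(X), -1, 3)
    centered = pts - pts.mean(axis=1, keepdims=True)
    return np.sqrt((centered ** 2).sum(axis=(1, 2)))


def _residualize(a: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    Z = np.column_stack([np.ones(len(covariate)), covariate])
    beta, *_ = np.linalg.lstsq(Z, a, rcond=None)
    return a - Z @ beta


@dataclass(frozen=True)
class CcaResult:
    r: float
    p_value: float
    loadings: np.ndarray
    n: int
    n_predictors: int


class ShapeDistanceCCA(BaseEstimator):
    """Canonical correlation of shape scores with a single distance response.

    ``fit(X, y)`` takes the (n, t) Mahalanobis score matrix and the
    length-n distance vector.  With one response the canonical variate on
    the shape side is the fitted regression combination, the canonical
    correlation is sqrt(R^2), and the p-value is the overall-regression F
    test (Rao's approximation is exact here).  ``n_permutations`` > 0
    switches to a seeded permutation p-value instead.

    Attributes
    ----------
    r_ : canonical correlation in [0, 1].
    p_value_ : significance of the association.
    coef_ : canonical weight vector over the score columns.
    loadings_ : structure correlations of each score with the canonical
        variate.
    """

    def __init__(self, size_correction: bool = False, n_permutations: int = 0,
                 random_state: int | None = 0):
        self.size_correction = size_correction
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y, sizes=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, t = X.shape
        if n <= t + 1:
            raise ValueError(f"rank deficiency: need n > t + 1 (n={n}, t={t})")
        if self.size_correction:
            if sizes is None:
                raise ValueError("size_correction=True requires centroid sizes")
            sizes = np.asarray(sizes, dtype=float).ravel()
            X = _residualize(X - X.mean(axis=0), sizes - sizes.mean())
            y = _residualize(y - y.mean(), sizes - sizes.mean())
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sst = float(yc @ yc)
        if sst <= 0:
            raise ValueError("distance response has zero variance")
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        fitted = Xc @ beta
        ssr = float(fitted @ fitted)
        r2 = min(ssr / sst, 1.0)
        self.coef_ = beta
        self.r_ = float(np.sqrt(r2))
        variate_sd = fitted.std()
        if variate_sd > 0:
            self.loadings_ = np.array([
                np.corrcoef(Xc[:, j], fitted)[0, 1] if Xc[:, j].std() > 0 else np.nan
                for j in range(t)])
        else:
            self.loadings_ = np.full(t, np.nan)
        df2 = n - t - 1
        if r2 >= 1.0:
            self.p_value_ = 0.0
        else:
            F = (r2 / t) / ((1.0 - r2) / df2)
            self.p_value_ = float(sps.f.sf(F, t, df2))
        if self.n_permutations:
            rng = np.random.default_rng(self.random_state)
            count = 0
            for _ in range(self.n_permutations):
                yp = rng.permutation(yc)
                bp, *_ = np.linalg.lstsq(Xc, yp, rcond=None)
                fp = Xc @ bp
                if (fp @ fp) / (yp @ yp) >= r2 - 1e-12:
                    count += 1
            self.p_value_ = float((count + 1) / (self.n_permutations + 1))
        self.n_, self.n_predictors_ = n, t
        return self

    def result(self) -> CcaResult:
        return CcaResult(self.r_, self.p_value_, self.loadings_, self.n_, self.n_predictors_)


def cca_shape_ifd(pdm, samples_or_scores, ifd_values, size_correction: bool = False,
                  n_permutations: int = 0, random_state: int = 0) -> CcaResult:
    """Canonical correlation between PDM Mahalanobis scores and the IFD.

    ``samples_or_scores`` may be an (n, t) score matrix or a list of
    population samples carrying mode weights; ``pdm`` (may be None for a
    raw score matrix) supplies the eigenvalue standardization.
    """
    arr = samples_or_scores
    if not isinstance(arr, np.ndarray):
        weights = np.stack([s.weights for s in arr])
        arr = pdm.scores(weights, is_weights=True)
    sizes = None
    if size_correction:
        if pdm is None:
            raise ValueError("size correction needs the model to reconstruct shapes")
        shapes = pdm.inverse_transform(arr * np.sqrt(pdm.explained_variance_))
        sizes = centroid_size(shapes)
    est = ShapeDistanceCCA(size_correction=size_correction,
                           n_permutations=n_permutations, random_state=random_state)
    est.fit(np.asarray(arr, dtype=float), ifd_values, sizes=sizes)
    return est.result()


@dataclass(frozen=True)
class PlsrResult:
    percent_variance_explained: float
    n_components: int
    n: int


def plsr_variance_explained(ifd_values, shapes_or_scores, n_components: int = 1) -> PlsrResult:
    """Percent of total shape variance explained by the distance covariate.

    Fits PLSR with the ischiofemoral distance as the single predictor and
    the shape coordinates (or mode scores) as the multivariate response;
    reports 100 x (1 - residual SS / total SS) of the centered response
    after reconstruction from the latent components.
    """
    y = np.asarray(ifd_values, dtype=float).reshape(-1, 1)
    Y = np.atleast_2d(np.asarray(shapes_or_scores, dtype=float))
    if len(Y) != len(y) or len(y) <= 2:
        raise ValueError("need matched shape/distance data with n > 2")
    Yc = Y - Y.mean(axis=0)
    sst = float((Yc ** 2).sum())
    if sst <= 0:
        raise ValueError("shape data carry no variance")
    n_components = min(n_components, y.shape[1])
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(y, Y)
    recon = pls.x_scores_ @ pls.y_loadings_.T
    explained = 100.0 * (1.0 - float(((Yc - recon) ** 2).sum()) / sst)
    return PlsrResult(float(np.clip(explained, 0.0, 100.0)), n_components, len(y))


@dataclass(frozen=True)
class ShapeRegressionResult:
    """Consensus shapes along the distance axis (linear shape regression)."""

    weights_mean: np.ndarray
    weights_low: np.ndarray      # at IFD = mean - k SD
    weights_high: np.ndarray     # at IFD = mean + k SD
    k_sd: float
    ifd_mean: float
    ifd_sd: float

    def meshes(self, pdm):
        """Reconstruct (low, mean, high) mesh tuples from a fitted model."""
        return (pdm.reconstruct_meshes(self.weights_low),
                pdm.reconstruct_meshes(self.weights_mean),
                pdm.reconstruct_meshes(self.weights_high))


def shape_regression(pdm, samples_or_weights, ifd_values, k_sd: float = 3.0) -> ShapeRegressionResult:
    """Consensus anatomies at the mean and +-k SD of ischiofemoral distance.

    A linear (single-covariate PLS) regression of the mode weights on the
    distance; by linearity the low/high shapes average exactly to the
    mean shape.
    """
    if k_sd < 0:
        raise ValueError("k_sd must be >= 0")
    W = samples_or_weights
    if not isinstance(W, np.ndarray):
        W = np.stack([s.weights for s in W])
    W = np.atleast_2d(np.asarray(W, dtype=float))
    y = np.asarray(ifd_values, dtype=float).ravel()
    y_sd = y.std(ddof=1)
    if y_sd <= 0:
        raise ValueError("distance values are constant")
    yc = y - y.mean()
    slope = (W - W.mean(axis=0)).T @ yc / (yc @ yc)        # per-mode OLS slope
    mean_w = W.mean(axis=0)
    delta = slope * k_sd * y_sd
    return ShapeRegressionResult(mean_w, mean_w - delta, mean_w + delta,
                                 float(k_sd), float(y.mean()), float(y_sd))
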
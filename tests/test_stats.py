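"""Statistical battery: Welch test, correlations, CCA, PLSR, shape regression."""

import numpy as np
import pandas as pd
import pytest

from hipspace.model import build_pdm
from hipspace.morphometry import measure_cohort, measure_pelvis
from hipspace.stats import (sex_difference_test, correlation_table, ShapeDistanceCCA,
                            cca_shape_ifd, plsr_variance_explained, shape_regression,
                            centroid_size)
from hipspace.synthetic import default_distributions, draw_params, PARAM_NAMES


@pytest.fixture(scope="module")
def female_fit(small_cohorts):
    """Fitted PDM + scores + measured distances for the female cohort."""
    meshes, _ = small_cohorts["female"]
    pdm = build_pdm(meshes, 15, sex="female")
    shapes = np.stack([np.concatenate([p.vertices.ravel(), f.vertices.ravel()])
                       for p, f in meshes])
    weights = pdm.transform(shapes)
    scores = pdm.scores(weights, is_weights=True)
    ifd = measure_cohort(meshes, sex="female")["ischiofemoral_distance"].to_numpy()
    return pdm, weights, scores, ifd


class TestSexDifference:
    def test_identical_samples_null(self):
        x = np.arange(10.0)
        res = sex_difference_test(x, x)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.99

    def test_argument_swap_negates_statistic(self, rng):
        a, b = rng.normal(29, 4, 200), rng.normal(22, 4, 200)
        r1 = sex_difference_test(a, b)
        r2 = sex_difference_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_population_distance_gap_significant(self):
        male = np.array([p.ifd_gap for p in
                         draw_params(default_distributions("male"), 1000, seed=8)])
        female = np.array([p.ifd_gap for p in
                           draw_params(default_distributions("female"), 1000, seed=9)])
        res = sex_difference_test(male, female)
        assert res.p_value < 0.001
        assert res.mean_male > res.mean_female

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            sex_difference_test([1.0], [1.0, 2.0])


class TestCorrelationTable:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 10, 50)
        df = pd.DataFrame({"sex": "female", "femoral_offset": x,
                           "ischiofemoral_distance": 2 * x})
        out = correlation_table(df, measure_columns=["femoral_offset"])
        assert out.loc[0, "r"] == pytest.approx(1.0, abs=1e-12)

    def test_null_bound_for_independent_normals(self, rng):
        df = pd.DataFrame({"sex": "male", "femoral_offset": rng.standard_normal(5000),
                           "ischiofemoral_distance": rng.standard_normal(5000)})
        out = correlation_table(df, measure_columns=["femoral_offset"])
        assert abs(out.loc[0, "r"]) < 0.05

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"sex": "female", "femoral_offset": np.ones(10),
                           "ischiofemoral_distance": np.arange(10.0)})
        out = correlation_table(df, measure_columns=["femoral_offset"])
        assert out.loc[0, "constant"] and np.isnan(out.loc[0, "r"])

    def test_generator_truth_recovery(self):
        """Configured +0.4 offset-gap correlation is recovered from draws."""
        draws = np.stack([p.as_array() for p in
                          draw_params(default_distributions("female"), 5000, seed=12)])
        df = pd.DataFrame(draws, columns=list(PARAM_NAMES))
        df["sex"] = "female"
        df = df.rename(columns={"ifd_gap": "ischiofemoral_distance"})
        out = correlation_table(df, measure_columns=["femoral_offset",
                                                     "interspinous_distance"])
        r_off = out.set_index("measure").loc["femoral_offset", "r"]
        r_isd = out.set_index("measure").loc["interspinous_distance", "r"]
        assert r_off == pytest.approx(0.4, abs=0.06)
        assert r_isd == pytest.approx(-0.6, abs=0.06)

    def test_sign_recovery_through_full_pipeline(self, small_cohorts):
        meshes, _ = small_cohorts["female"]
        df = measure_cohort(meshes, sex="female")
        out = correlation_table(df).set_index("measure")
        assert out.loc["femoral_offset", "r"] > 0
        assert out.loc["interspinous_distance", "r"] < 0


class TestCCA:
    def test_exact_linear_response(self, rng):
        X = rng.standard_normal((200, 5))
        y = X @ np.array([1.0, -2, 0.5, 0, 3])
        res = ShapeDistanceCCA().fit(X, y)
        assert res.r_ == pytest.approx(1.0, abs=1e-9)
        assert res.p_value_ < 1e-12

    def test_independent_response_not_significant(self, rng):
        X = rng.standard_normal((2000, 20))
        y = rng.standard_normal(2000)
        res = ShapeDistanceCCA().fit(X, y)
        assert res.r_ < 0.25
        assert res.p_value_ > 0.001

    def test_known_snr_closed_form(self, rng):
        """IFD = score_1 + noise at 3:1 SD ratio gives r = sqrt(9/10)."""
        X = rng.standard_normal((5000, 8))
        y = X[:, 0] + rng.standard_normal(5000) / 3.0
        res = ShapeDistanceCCA().fit(X, y)
        assert res.r_ == pytest.approx(np.sqrt(0.9), abs=0.05)

    def test_equivalence_with_sklearn_cca(self, female_fit):
        """Independent oracle: sklearn's CCA canonical correlation."""
        from sklearn.cross_decomposition import CCA

        _, _, scores, ifd = female_fit
        ours = ShapeDistanceCCA().fit(scores, ifd)
        cca = CCA(n_components=1).fit(scores, ifd.reshape(-1, 1))
        u, v = cca.transform(scores, ifd.reshape(-1, 1))
        r_oracle = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert ours.r_ == pytest.approx(r_oracle, abs=1e-6)
        # and the multiple-regression R^2 equivalence
        Xc = scores - scores.mean(axis=0)
        yc = ifd - ifd.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        r2 = 1 - ((yc - Xc @ beta) ** 2).sum() / (yc ** 2).sum()
        assert ours.r_ ** 2 == pytest.approx(r2, abs=1e-9)

    def test_rank_deficiency_rejected(self, rng):
        with pytest.raises(ValueError, match="rank"):
            ShapeDistanceCCA().fit(rng.standard_normal((10, 12)), rng.standard_normal(10))

    def test_type_i_error_controlled(self, rng):
        """At the 0.001 level the null CCA test rejects in <= 0.5% of
        1000 small replicates (n=200, t=5)."""
        rejections = 0
        for _ in range(1000):
            X = rng.standard_normal((200, 5))
            y = rng.standard_normal(200)
            if ShapeDistanceCCA().fit(X, y).p_value_ < 0.001:
                rejections += 1
        assert rejections <= 5

    def test_permutation_p_agrees_with_f(self, rng):
        X = rng.standard_normal((150, 4))
        y = X[:, 1] * 0.5 + rng.standard_normal(150)
        f_p = ShapeDistanceCCA().fit(X, y).p_value_
        perm_p = ShapeDistanceCCA(n_permutations=499, random_state=3).fit(X, y).p_value_
        assert (f_p < 0.01) == (perm_p < 0.01)

    def test_pipeline_cca_strong_on_synthetic_truth(self, female_fit):
        pdm, _, scores, ifd = female_fit
        res = cca_shape_ifd(pdm, scores, ifd)
        assert res.r > 0.9            # the gap is a generated shape feature
        assert res.p_value < 0.001

    def test_size_correction_runs_and_reduces_r(self, female_fit):
        pdm, _, scores, ifd = female_fit
        raw = cca_shape_ifd(pdm, scores, ifd)
        corrected = cca_shape_ifd(pdm, scores, ifd, size_correction=True)
        assert 0.0 <= corrected.r <= 1.0
        assert corrected.r <= raw.r + 0.05


class TestPLSR:
    def test_single_mode_variation_fully_explained(self, rng):
        v = rng.standard_normal(30)
        b = rng.standard_normal(500)
        Y = np.outer(b, v)
        res = plsr_variance_explained(b, Y)
        assert res.percent_variance_explained == pytest.approx(100.0, abs=1e-6)

    def test_independent_covariate_null_bound(self, rng):
        Y = rng.standard_normal((2000, 20))
        y = rng.standard_normal(2000)
        res = plsr_variance_explained(y, Y)
        assert res.percent_variance_explained < 2.0

    def test_explained_variance_monotone_in_coupling(self):
        """Stronger configured gap-shape coupling -> more shape variance
        explained by the distance. Common random numbers across the three
        coupling settings isolate the coupling effect from sampling noise."""
        from hipspace.synthetic import GeneratorParams, build_hip

        from hipspace.synthetic import PARAM_NAMES, ParameterDistributions

        z = np.random.default_rng(40).standard_normal((300, 9))
        i_isd, i_gap = PARAM_NAMES.index("interspinous_distance"), PARAM_NAMES.index("ifd_gap")
        base = default_distributions("female", coupling_scale=0.0)
        values = []
        for scale in (0.0, 0.6, 1.2):
            C = np.eye(9)
            # couple the gap only to the interspinous distance: its shape
            # footprint (spine landmarks) is geometrically independent of
            # the gap's own footprint, so covariance adds cleanly
            C[i_isd, i_gap] = C[i_gap, i_isd] = -0.6 * scale
            dist = ParameterDistributions(base.means, base.sds, C, "female")
            L = np.linalg.cholesky(dist.covariance + 1e-12 * np.eye(9))
            draws = dist.means + z @ L.T
            params = [GeneratorParams.from_array(row, "female") for row in draws]
            params = [p for p in params if p.is_valid()]
            meshes = [build_hip(p) for p in params]
            pdm = build_pdm(meshes, 10, sex="female")
            shapes = np.stack([np.concatenate([p.vertices.ravel(), f.vertices.ravel()])
                               for p, f in meshes])
            W = pdm.transform(shapes)
            gaps = np.array([p.ifd_gap for p in params])
            values.append(plsr_variance_explained(gaps, W).percent_variance_explained)
        assert values[0] < values[1] < values[2]

    def test_zero_variance_shapes_rejected(self):
        with pytest.raises(ValueError):
            plsr_variance_explained(np.arange(5.0), np.ones((5, 3)))


class TestShapeRegression:
    def test_k_zero_gives_mean(self, female_fit):
        pdm, weights, _, ifd = female_fit
        res = shape_regression(pdm, weights, ifd, k_sd=0.0)
        assert np.allclose(res.weights_low, res.weights_mean)
        assert np.allclose(res.weights_high, res.weights_mean)

    def test_linearity_of_consensus_shapes(self, female_fit):
        pdm, weights, _, ifd = female_fit
        res = shape_regression(pdm, weights, ifd, k_sd=3.0)
        assert np.allclose((res.weights_low + res.weights_high) / 2,
                           res.weights_mean, atol=1e-9)
        low, mean, high = res.meshes(pdm)
        assert np.allclose((low[0].vertices + high[0].vertices) / 2,
                           mean[0].vertices, atol=1e-9)

    def test_low_distance_consensus_has_wider_interspinous(self, female_fit):
        """The configured negative interspinous-gap coupling must show in
        the regressed anatomy: the narrow-gap consensus pelvis carries a
        larger interspinous distance."""
        pdm, weights, _, ifd = female_fit
        res = shape_regression(pdm, weights, ifd, k_sd=3.0)
        low, _, high = res.meshes(pdm)
        isd_low = measure_pelvis(low[0]).interspinous_distance
        isd_high = measure_pelvis(high[0]).interspinous_distance
        assert isd_low > isd_high


def test_centroid_size_scales_linearly(rng):
    shape = rng.standard_normal(90)
    s1 = centroid_size(shape)[0]
    s2 = centroid_size(2.0 * shape)[0]
    assert s2 == pytest.approx(2 * s1, rel=1e-9)
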